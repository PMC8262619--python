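"""Site and record selection for the anomaly analysis.

A site enters the trend analysis for a parameter only when its sampling
record is adequate: the samples fall inside the study window (years, months,
depth), every seasonal bin of a qualifying year contains at least one
sampling event, both halves of the record (the split windows) contain at
least one event, and the site has at least ``min_years_per_parameter``
qualifying years.  A sampling "event" is a unique (site, date) with at least
one retained measurement of the parameter.

Two shipped presets:

``uriww``
    1993-2016, May-October, bins May-Jun / Jul-Aug / Sep-Oct, split windows
    1993-2004 and 2005-2016, depth <= 2 m, >=10 years, >=3 sites/year.
``lagos_ne``
    same but 1993-2013 with split windows 1993-2002 and 2003-2013 and no
    depth filter (depth is not recorded; samples are surface/epilimnion).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Window = tuple[int, int]


@dataclass(frozen=True)
class EligibilityConfig:
    """Selection criteria for sites and site-years."""

    start_year: int = 1993
    end_year: int = 2016
    months: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    seasonal_bins: tuple[tuple[int, ...], ...] = ((5, 6), (7, 8), (9, 10))
    split_windows: tuple[Window, Window] = ((1993, 2004), (2005, 2016))
    max_depth_m: float | None = 2.0
    min_years_per_parameter: int = 10
    min_sites_per_year: int = 3

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")
        for lo, hi in self.split_windows:
            if lo < self.start_year or hi > self.end_year or lo > hi:
                raise ValueError("split windows must lie within the study window")
        if self.min_years_per_parameter < 1 or self.min_sites_per_year < 1:
            raise ValueError("minimum counts must be >= 1")
        bin_months = [m for b in self.seasonal_bins for m in b]
        if not set(bin_months) <= set(self.months):
            raise ValueError("seasonal bins must use months from the month set")

    @classmethod
    def from_dict(cls, d: Mapping) -> "EligibilityConfig":
        d = dict(d)
        if "months" in d:
            d["months"] = tuple(d["months"])
        if "seasonal_bins" in d:
            d["seasonal_bins"] = tuple(tuple(b) for b in d["seasonal_bins"])
        if "split_windows" in d:
            d["split_windows"] = tuple(tuple(w) for w in d["split_windows"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


_PRESETS = {
    "uriww": EligibilityConfig(),
    "lagos_ne": EligibilityConfig(
        end_year=2013,
        split_windows=((1993, 2002), (2003, 2013)),
        max_depth_m=None,
    ),
}


def preset(name: str) -> EligibilityConfig:
    """Return a shipped preset configuration (``uriww`` or ``lagos_ne``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")


@dataclass
class EligibilityReport:
    """Site accounting produced by :func:`apply_eligibility`."""

    sites_per_parameter: dict[str, int] = field(default_factory=dict)
    union_sites: int = 0
    intersection_sites: int = 0
    eligible_years: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    rejections: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Eligibility report", "=================="]
        for p, n in sorted(self.sites_per_parameter.items()):
            rej = self.rejections.get(p, {})
            lines.append(f"{p}: {n} eligible sites (rejected: {rej or 'none'})")
        lines.append(f"union of sites: {self.union_sites}")
        lines.append(f"sites with all parameters: {self.intersection_sites}")
        return "\n".join(lines)


def filter_window(samples: pd.DataFrame, config: EligibilityConfig) -> pd.DataFrame:
    """Keep samples inside the study window: years, months, and depth.

    Samples without a depth pass the depth filter (surface/epilimnion data
    with unrecorded depth, as in regional databases).
    """
    dates = pd.to_datetime(samples["sample_date"])
    keep = (
        dates.dt.year.between(config.start_year, config.end_year)
        & dates.dt.month.isin(config.months)
    )
    if config.max_depth_m is not None:
        keep &= samples["depth_m"].isna() | (samples["depth_m"] <= config.max_depth_m)
    return samples[keep].reset_index(drop=True)


def _event_months(samples: pd.DataFrame) -> pd.Series:
    """Months of the unique sampling events (site, date) in ``samples``."""
    dates = pd.to_datetime(samples["sample_date"]).drop_duplicates()
    return dates.dt.month


def seasonal_coverage(
    site_samples: pd.DataFrame,
    bins: Sequence[Sequence[int]],
) -> bool:
    """True iff every seasonal bin holds >=1 sampling event.

    ``site_samples`` are the window-filtered samples of one site, parameter,
    and year.
    """
    months = set(_event_months(site_samples))
    return all(any(m in months for m in b) for b in bins)


def split_window_presence(
    site_samples: pd.DataFrame,
    split_windows: Sequence[Window],
) -> bool:
    """True iff each split window contains >=1 sampling event for the site."""
    years = set(pd.to_datetime(site_samples["sample_date"]).dt.year)
    return all(any(lo <= y <= hi for y in years) for lo, hi in split_windows)


def _qualifying_years(
    param_site: pd.DataFrame, config: EligibilityConfig, coverage_mode: str
) -> list[int]:
    """Years of one site/parameter that count toward ``min_years_per_parameter``."""
    years = pd.to_datetime(param_site["sample_date"]).dt.year
    covered = [
        int(y)
        for y, grp in param_site.groupby(years)
        if seasonal_coverage(grp, config.seasonal_bins)
    ]
    if coverage_mode == "strict":
        return sorted(covered)
    if coverage_mode == "site":
        # site qualifies via >=1 fully covered year; all sampled years then count
        return sorted(set(int(y) for y in years)) if covered else []
    raise ValueError(f"unknown coverage_mode {coverage_mode!r}")


def apply_eligibility(
    samples: pd.DataFrame,
    config: EligibilityConfig | None = None,
    coverage_mode: str = "strict",
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply all selection criteria; return eligible samples and a report.

    Per parameter, a site is eligible iff (a) both split windows contain an
    event and (b) it has >= ``min_years_per_parameter`` qualifying years.
    Under the default ``"strict"`` coverage mode a year qualifies only when
    all three seasonal bins are covered for that parameter, and only
    qualifying years' samples flow downstream; under ``"site"`` mode one
    covered year qualifies the site and every sampled year then counts.

    Years with too few sites are *not* dropped here; that rule belongs to
    the yearly aggregation stage.
    """
    config = config or EligibilityConfig()
    win = filter_window(samples, config)
    report = EligibilityReport()
    kept_parts: list[pd.DataFrame] = []
    sites_by_param: dict[str, set[str]] = {}

    for param, psub in win.groupby("parameter"):
        eligible_sites: set[str] = set()
        years_map: dict[str, list[int]] = {}
        rejections = {"split_window": 0, "min_years": 0}
        for site, ssub in psub.groupby("site_id"):
            if not split_window_presence(ssub, config.split_windows):
                rejections["split_window"] += 1
                continue
            qual = _qualifying_years(ssub, config, coverage_mode)
            if len(qual) < config.min_years_per_parameter:
                rejections["min_years"] += 1
                continue
            eligible_sites.add(site)
            years_map[site] = qual
            yr = pd.to_datetime(ssub["sample_date"]).dt.year
            kept_parts.append(ssub[yr.isin(qual)])
        sites_by_param[param] = eligible_sites
        report.sites_per_parameter[param] = len(eligible_sites)
        report.eligible_years[param] = years_map
        report.rejections[param] = rejections

    if sites_by_param:
        report.union_sites = len(set.union(*sites_by_param.values()))
        report.intersection_sites = len(set.intersection(*sites_by_param.values()))
    eligible = (
        pd.concat(kept_parts, ignore_index=True) if kept_parts else win.iloc[0:0]
    )
    logger.info(
        "eligibility: %d/%d samples retained across %d parameter(s)",
        len(eligible), len(samples), len(sites_by_param),
    )
    return eligible, report
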