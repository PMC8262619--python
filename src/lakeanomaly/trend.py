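"""OLS trend fitting on yearly median anomalies and the trend rubric.

A parameter's trend over years is summarized by an ordinary least squares
fit of the yearly median anomaly on calendar year.  Whether that fit is
called a *trend* rests on three lines of evidence rather than a lone
significance cut:

1. statistical support — the two-sided p-value of the slope against a
   configurable alpha (default 0.10);
2. temporal pattern — whether above-reference years cluster in the late
   half of the record and below-reference years in the early half (or the
   mirror image for a decline);
3. ecological magnitude — whether |slope| reaches a per-parameter threshold
   representing a meaningful change accumulated over a century (e.g., an
   oligotrophic lake crossing into mesotrophy).

Meeting >=2 criteria is a trend, exactly 1 a weak trend, 0 no trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from lakeanomaly.anomaly import anomaly_pipeline

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.10
DEFAULT_PATTERN_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of yearly median anomaly on calendar year."""

    parameter: str
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_years: int
    df_resid: int
    stderr: float

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        t = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return self.slope - t * self.stderr, self.slope + t * self.stderr


@dataclass(frozen=True)
class ThresholdRegistry:
    """Ecologically meaningful |slope| thresholds, canonical units per year."""

    thresholds: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")

    def __getitem__(self, parameter: str) -> float:
        try:
            return self.thresholds[parameter]
        except KeyError:
            raise ValueError(f"no magnitude threshold for parameter {parameter!r}")


def threshold_derivations() -> ThresholdRegistry:
    """Derive the default per-year thresholds from their source quantities.

    Each threshold is a meaningful total change spread over a century:
    the 2 °C warming-limit policy goal for temperature; the
    oligotrophic→mesotrophic trophic-state limits for chlorophyll (3.5 µg/L),
    TN (350 µg/L) and TP (10 µg/L); and for the molar TN:TP ratio the gap
    between median ratios of nitrogen-limited (35) and non-nitrogen-limited
    (61) lakes from whole-lake enrichment experiments.
    """
    century = 100.0
    return ThresholdRegistry(
        thresholds={
            "temperature": 2.0 / century,
            "chla": 3.5 / century,
            "tn": 350.0 / century,
            "tp": 10.0 / century,
            "np_ratio": (61.0 - 35.0) / century,
        },
        provenance={
            "temperature": "2 degC warming limit over a century -> 0.02 degC/yr",
            "chla": "oligo-mesotrophic limit 3.5 ug/L over a century -> 0.035 ug/L/yr",
            "tn": "oligo-mesotrophic TN limit 350 ug/L over a century -> 3.5 ug/L/yr",
            "tp": "oligo-mesotrophic TP limit 10 ug/L over a century -> 0.1 ug/L/yr",
            "np_ratio": "N-limited (35) vs not-N-limited (61) median molar TN:TP "
                        "gap of 26 over a century -> 0.26 /yr",
        },
    )


@dataclass(frozen=True)
class TrendAssessment:
    """Three-criterion rubric outcome for one parameter."""

    parameter: str
    fit: TrendFit
    crit_statistical: bool
    crit_pattern: bool
    crit_magnitude: bool
    n_criteria_met: int
    classification: str  # trend | weak_trend | no_trend
    direction: str  # increasing | decreasing | none

    @property
    def symbol(self) -> str:
        """Report symbol: ++ / + / 0 / - / -- (strength x direction)."""
        if self.classification == "no_trend":
            return "0"
        s = "+" if self.direction == "increasing" else "-"
        return s * (2 if self.classification == "trend" else 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["symbol"] = self.symbol
        return d


def _subset_parameter(yearly: pd.DataFrame, parameter: str | None) -> pd.DataFrame:
    if parameter is not None:
        yearly = yearly[yearly["parameter"] == parameter]
    params = yearly["parameter"].unique()
    if len(params) != 1:
        raise ValueError(
            "year summaries must cover exactly one parameter; "
            f"got {sorted(params)} (pass parameter=...)"
        )
    return yearly


def fit_trend(yearly: pd.DataFrame, parameter: str | None = None) -> TrendFit:
    """OLS of yearly median anomaly on calendar year for one parameter.

    Requires >=3 retained years and non-constant years.  A constant anomaly
    series (zero residual and explained variance) is the null by
    construction and reports slope 0, p 1, r² 0.
    """
    yearly = _subset_parameter(yearly, parameter)
    param = yearly["parameter"].iloc[0]
    x = yearly["year"].to_numpy(float)
    y = yearly["median_anomaly"].to_numpy(float)
    if len(x) < 3:
        raise ValueError(f"need >=3 years to fit a trend, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("years are constant; cannot fit a trend")
    if np.ptp(y) == 0:
        return TrendFit(param, 0.0, float(y[0]), 1.0, 0.0, len(x), len(x) - 2, 0.0)
    res = stats.linregress(x, y)
    return TrendFit(
        parameter=param,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n_years=len(x),
        df_resid=len(x) - 2,
        stderr=float(res.stderr),
    )


def criterion_statistical(fit: TrendFit, alpha: float = DEFAULT_ALPHA) -> bool:
    """Criterion 1: two-sided p-value of the slope at or below alpha."""
    return fit.p_value <= alpha


def _pattern_direction(
    yearly: pd.DataFrame, pattern_fraction: float
) -> str | None:
    """Direction of the early/late high-low pattern, or None.

    Years are split at the midpoint of the observed year range (ties go to
    the early half).  Among years with nonzero median anomaly, an increasing
    pattern needs >= ``pattern_fraction`` of positive years late AND
    >= that fraction of negative years early (each vacuously true when
    empty); decreasing is the mirror image.  Exact-zero years are excluded —
    they are neither above nor below the reference.
    """
    years = yearly["year"].to_numpy(float)
    anom = yearly["median_anomaly"].to_numpy(float)
    mid = (years.min() + years.max()) / 2.0
    late = years > mid
    pos, neg = anom > 0, anom < 0
    if not (pos.any() or neg.any()):
        return None

    def frac(mask_sign, mask_half):
        n = mask_sign.sum()
        return (mask_sign & mask_half).sum() / n if n else 1.0

    inc = frac(pos, late) >= pattern_fraction and frac(neg, ~late) >= pattern_fraction
    dec = frac(neg, late) >= pattern_fraction and frac(pos, ~late) >= pattern_fraction
    if inc and not dec:
        return "increasing"
    if dec and not inc:
        return "decreasing"
    return None


def criterion_pattern(
    yearly: pd.DataFrame,
    parameter: str | None = None,
    pattern_fraction: float = DEFAULT_PATTERN_FRACTION,
) -> bool:
    """Criterion 2: high/low years cluster consistently early vs late."""
    yearly = _subset_parameter(yearly, parameter)
    if len(yearly) < 4:
        raise ValueError("pattern criterion needs >=4 retained years")
    return _pattern_direction(yearly, pattern_fraction) is not None


def criterion_magnitude(fit: TrendFit, registry: ThresholdRegistry) -> bool:
    """Criterion 3: |slope| at or above the parameter's threshold."""
    return abs(fit.slope) >= registry[fit.parameter]


def _classify(n_met: int) -> str:
    return "trend" if n_met >= 2 else ("weak_trend" if n_met == 1 else "no_trend")


def _assemble(
    fit: TrendFit, c_stat: bool, c_pat: bool, c_mag: bool
) -> TrendAssessment:
    n_met = int(c_stat) + int(c_pat) + int(c_mag)
    classification = _classify(n_met)
    if classification == "no_trend" or fit.slope == 0:
        direction = "none"
    else:
        direction = "increasing" if fit.slope > 0 else "decreasing"
    return TrendAssessment(
        parameter=fit.parameter,
        fit=fit,
        crit_statistical=c_stat,
        crit_pattern=c_pat,
        crit_magnitude=c_mag,
        n_criteria_met=n_met,
        classification=classification,
        direction=direction,
    )


def assess_trend(
    yearly: pd.DataFrame,
    parameter: str | None = None,
    registry: ThresholdRegistry | None = None,
    alpha: float = DEFAULT_ALPHA,
    pattern_fraction: float = DEFAULT_PATTERN_FRACTION,
) -> TrendAssessment:
    """Fit the trend and evaluate all three criteria for one parameter."""
    yearly = _subset_parameter(yearly, parameter)
    registry = registry or threshold_derivations()
    fit = fit_trend(yearly)
    c_stat = criterion_statistical(fit, alpha)
    c_pat = criterion_pattern(yearly, pattern_fraction=pattern_fraction)
    c_mag = criterion_magnitude(fit, registry)
    return _assemble(fit, c_stat, c_pat, c_mag)


def classify_trend(
    parameter: str,
    slope: float,
    p_value: float,
    pattern: bool,
    registry: ThresholdRegistry | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> TrendAssessment:
    """Apply the rubric to an externally supplied (slope, p, pattern) triple.

    Useful for re-assessing published fits without the underlying yearly
    series; the returned fit carries only the supplied numbers.
    """
    registry = registry or threshold_derivations()
    fit = TrendFit(parameter, slope, np.nan, p_value, np.nan, 0, 0, np.nan)
    return _assemble(
        fit,
        criterion_statistical(fit, alpha),
        bool(pattern),
        criterion_magnitude(fit, registry),
    )


def leave_year_out(
    yearly: pd.DataFrame, year: int, parameter: str | None = None
) -> tuple[TrendFit, TrendFit]:
    """Refit with one year removed; returns (full fit, leave-out fit).

    A sensitivity check for influential low-site years.  Removing a year
    that is not in the retained series warns and returns the full fit twice.
    """
    yearly = _subset_parameter(yearly, parameter)
    full = fit_trend(yearly)
    if year not in set(yearly["year"]):
        warnings.warn(f"year {year} not in the retained series; no-op")
        return full, full
    reduced = yearly[yearly["year"] != year]
    if len(reduced) < 3:
        raise ValueError("removing the year leaves <3 years")
    return full, fit_trend(reduced)


def detection_limit_sensitivity(
    samples: pd.DataFrame,
    min_sites_per_year: int = 3,
    registry: ThresholdRegistry | None = None,
    alpha: float = DEFAULT_ALPHA,
    pattern_fraction: float = DEFAULT_PATTERN_FRACTION,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Run the anomaly+trend pipeline with and without censored rows.

    Pass eligibility-filtered samples carrying ``below_detection`` flags.
    Returns one row per parameter with both classifications and an
    ``agree`` flag; disagreement under heavy censoring is reported, never
    suppressed.
    """
    registry = registry or threshold_derivations()
    rows = []
    for label, sub in [
        ("all", samples),
        ("above_detection", samples[~samples["below_detection"]]),
    ]:
        yearly = anomaly_pipeline(
            sub, min_sites_per_year=min_sites_per_year, **pipeline_kwargs
        )["yearly"]
        for param in yearly["parameter"].unique():
            a = assess_trend(
                yearly, parameter=param, registry=registry,
                alpha=alpha, pattern_fraction=pattern_fraction,
            )
            rows.append({"mode": label, "parameter": param,
                         "classification": a.classification,
                         "direction": a.direction, "slope": a.fit.slope,
                         "p_value": a.fit.p_value})
    long = pd.DataFrame(rows)
    wide = long.pivot(index="parameter", columns="mode",
                      values="classification").reset_index()
    wide["agree"] = wide["all"] == wide["above_detection"]
    return wide.merge(long[long["mode"] == "all"]
                      .drop(columns="mode"), on="parameter")


@dataclass(frozen=True)
class FirstExceedanceResult:
    mean_day_of_year: float
    n_site_years: int
    n_without_exceedance: int


def first_exceedance_day(
    samples: pd.DataFrame,
    threshold_c: float = 25.0,
    year_range: tuple[int, int] | None = None,
) -> FirstExceedanceResult:
    """Mean first day-of-year on which temperature exceeds a threshold.

    A growing-season indicator: per site-year, the earliest sample date with
    temperature strictly above ``threshold_c``; the mean day-of-year is
    taken across site-years in ``year_range``.  Site-years that never
    exceed the threshold are excluded and counted.
    """
    temp = samples[samples["parameter"] == "temperature"].copy()
    temp["sample_date"] = pd.to_datetime(temp["sample_date"])
    temp["year"] = temp["sample_date"].dt.year
    if year_range is not None:
        lo, hi = year_range
        temp = temp[temp["year"].between(lo, hi)]
    if temp.empty:
        raise ValueError("no temperature samples in range")
    n_site_years = temp.groupby(["site_id", "year"]).ngroups
    exceed = temp[temp["value"] > threshold_c]
    if exceed.empty:
        raise ValueError(
            f"no sample exceeds {threshold_c} degC in the requested range"
        )
    first = exceed.groupby(["site_id", "year"])["sample_date"].min()
    mean_doy = float(first.dt.dayofyear.mean())
    return FirstExceedanceResult(
        mean_day_of_year=mean_doy,
        n_site_years=len(first),
        n_without_exceedance=n_site_years - len(first),
    )
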