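"""Site-specific median anomalies and their yearly cross-site summaries.

The four-step aggregation:

1. collapse each (site, year, parameter) to its annual median — one value
   per site-year, which removes pseudoreplication from uneven within-year
   sampling effort;
2. collapse each site's annual medians to a single long-term reference
   median over the reference period;
3. anomaly = annual median − reference median, so every site is shifted to
   a common baseline in its own units;
4. summarize per year across sites: the median anomaly with quartiles,
   range, and site count; years with fewer than ``min_sites_per_year``
   sites are excluded.

All medians use the midpoint convention for even counts (numpy default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def annual_site_medians(samples: pd.DataFrame) -> pd.DataFrame:
    """Step 1: one median per (site, year, parameter).

    Returns columns ``site_id, year, parameter, annual_median, n_samples``.
    """
    df = samples.copy()
    df["year"] = pd.to_datetime(df["sample_date"]).dt.year
    out = (
        df.groupby(["site_id", "year", "parameter"], as_index=False)
        .agg(annual_median=("value", "median"), n_samples=("value", "size"))
    )
    return out


def site_reference_medians(
    site_year_medians: pd.DataFrame,
    basis: str = "annual_medians",
    samples: pd.DataFrame | None = None,
    reference_period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Step 2: one long-term reference median per (site, parameter).

    ``basis="annual_medians"`` (default) takes the median of the site's
    annual medians, making the reference insensitive to within-year sampling
    intensity.  ``basis="raw"`` takes the median of all raw measurements in
    the reference period and requires ``samples``.  ``reference_period``
    restricts the years used (default: the full record).

    Returns columns ``site_id, parameter, reference_median, n_years``.
    """
    if basis == "annual_medians":
        sym = site_year_medians
        if reference_period is not None:
            lo, hi = reference_period
            sym = sym[sym["year"].between(lo, hi)]
        out = (
            sym.groupby(["site_id", "parameter"], as_index=False)
            .agg(reference_median=("annual_median", "median"),
                 n_years=("year", "nunique"))
        )
    elif basis == "raw":
        if samples is None:
            raise ValueError("basis='raw' requires the raw samples")
        df = samples.copy()
        df["year"] = pd.to_datetime(df["sample_date"]).dt.year
        if reference_period is not None:
            lo, hi = reference_period
            df = df[df["year"].between(lo, hi)]
        out = (
            df.groupby(["site_id", "parameter"], as_index=False)
            .agg(reference_median=("value", "median"), n_years=("year", "nunique"))
        )
    else:
        raise ValueError(f"unknown reference basis {basis!r}")
    if (out["n_years"] < 1).any():
        raise ValueError("reference requires >=1 year per site/parameter")
    return out


def compute_anomalies(
    site_year_medians: pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    """Step 3: anomaly = annual median − site reference median.

    Every (site, parameter) in the annual medians must have a reference;
    a missing reference is a pipeline-ordering bug and raises.
    Returns columns ``site_id, year, parameter, anomaly``.
    """
    merged = site_year_medians.merge(
        references[["site_id", "parameter", "reference_median"]],
        on=["site_id", "parameter"],
        how="left",
    )
    missing = merged["reference_median"].isna()
    if missing.any():
        bad = merged.loc[missing, ["site_id", "parameter"]].drop_duplicates()
        raise ValueError(f"missing reference median for: {bad.to_dict('records')}")
    merged["anomaly"] = merged["annual_median"] - merged["reference_median"]
    return merged[["site_id", "year", "parameter", "anomaly"]]


def yearly_summaries(
    anomalies: pd.DataFrame, min_sites_per_year: int = 3
) -> pd.DataFrame:
    """Step 4: cross-site median anomaly per year, with spread and site count.

    Years with fewer than ``min_sites_per_year`` sites are excluded (and
    logged); ``low_n_flag`` marks retained years sitting exactly at the
    minimum, mirroring the asterisked low-confidence years in monitoring
    reports.  Rows are ordered by (parameter, year).
    """
    grp = anomalies.groupby(["parameter", "year"])
    out = grp["anomaly"].agg(
        median_anomaly="median",
        p25=lambda v: float(np.percentile(v, 25)),
        p75=lambda v: float(np.percentile(v, 75)),
        min="min",
        max="max",
    )
    out["n_sites"] = grp["site_id"].nunique()
    dropped = out[out["n_sites"] < min_sites_per_year]
    if len(dropped):
        logger.info(
            "yearly_summaries: excluded %d year(s) with < %d sites: %s",
            len(dropped), min_sites_per_year,
            [f"{p}:{y}" for p, y in dropped.index],
        )
    out = out[out["n_sites"] >= min_sites_per_year]
    if out.empty:
        raise ValueError(
            f"no year has >= {min_sites_per_year} sites; "
            "check eligibility filtering and site counts"
        )
    out["low_n_flag"] = out["n_sites"] == min_sites_per_year
    out = out.reset_index().sort_values(["parameter", "year"]).reset_index(drop=True)
    return out[
        ["year", "parameter", "median_anomaly", "p25", "p75",
         "min", "max", "n_sites", "low_n_flag"]
    ]


def anomaly_pipeline(
    samples: pd.DataFrame,
    min_sites_per_year: int = 3,
    reference_basis: str = "annual_medians",
    reference_period: tuple[int, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run steps 1-4 and return all intermediate tables.

    Returns a dict with keys ``site_year_medians``, ``references``,
    ``anomalies``, ``yearly``.
    """
    sym = annual_site_medians(samples)
    refs = site_reference_medians(
        sym, basis=reference_basis, samples=samples, reference_period=reference_period
    )
    anoms = compute_anomalies(sym, refs)
    yearly = yearly_summaries(anoms, min_sites_per_year=min_sites_per_year)
    return {
        "site_year_medians": sym,
        "references": refs,
        "anomalies": anoms,
        "yearly": yearly,
    }
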