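"""Brute-force reference implementations: explicit loops, sorting, and
statistics.median only — independent of the pandas-based pipeline."""

import statistics
from collections import defaultdict

import pandas as pd


def brute_site_year_medians(samples):
    """dict (site, year, parameter) -> (median, n_samples)"""
    buckets = defaultdict(list)
    for _, r in samples.iterrows():
        year = pd.Timestamp(r["sample_date"]).year
        buckets[(r["site_id"], year, r["parameter"])].append(r["value"])
    return {k: (statistics.median(sorted(v)), len(v)) for k, v in buckets.items()}


def brute_references(site_year_medians):
    """dict (site, parameter) -> median of the site's annual medians"""
    per_site = defaultdict(list)
    for (site, _year, param), (med, _n) in site_year_medians.items():
        per_site[(site, param)].append(med)
    return {k: statistics.median(sorted(v)) for k, v in per_site.items()}


def brute_anomalies(site_year_medians, references):
    """dict (site, year, parameter) -> annual median - reference median"""
    return {
        (site, year, param): med - references[(site, param)]
        for (site, year, param), (med, _n) in site_year_medians.items()
    }


def brute_quantile(sorted_vals, q):
    """Linear interpolation between order statistics (inclusive method)."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    h = (n - 1) * q
    lo = int(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def brute_yearly_summaries(anomalies, min_sites=3):
    """dict (parameter, year) -> dict of the yearly summary statistics"""
    buckets = defaultdict(list)
    for (site, year, param), a in anomalies.items():
        buckets[(param, year)].append(a)
    out = {}
    for key, vals in buckets.items():
        if len(vals) < min_sites:
            continue
        sv = sorted(vals)
        out[key] = {
            "median_anomaly": statistics.median(sv),
            "p25": brute_quantile(sv, 0.25),
            "p75": brute_quantile(sv, 0.75),
            "min": sv[0],
            "max": sv[-1],
            "n_sites": len(sv),
        }
    return out
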