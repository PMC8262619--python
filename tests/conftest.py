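import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("ci")


def build_samples(rows):
    """Canonical samples frame from (site, date, parameter, value[, depth]) tuples."""
    recs = []
    for row in rows:
        site, date, param, value = row[:4]
        depth = row[4] if len(row) > 4 else 1.0
        recs.append({
            "site_id": site,
            "sample_date": pd.Timestamp(date),
            "depth_m": depth,
            "parameter": param,
            "value": float(value),
            "below_detection": False,
            "detection_limit": np.nan,
        })
    return pd.DataFrame(recs)


@pytest.fixture
def make_samples():
    return build_samples


@pytest.fixture
def covered_site():
    """One site sampled May/Jul/Sep each year 1995-2010 (full seasonal coverage)."""
    rows = []
    for year in range(1995, 2011):
        for month in (5, 7, 9):
            rows.append(("site_a", f"{year}-{month:02d}-15", "temperature", 20.0))
    return build_samples(rows)


def random_cohort(rng, n_sites=5, n_years=6, parameter="chla"):
    """Small random cohort with full coverage, for oracle-equivalence checks."""
    rows = []
    years = range(2000, 2000 + n_years)
    for s in range(n_sites):
        for year in years:
            for month in (5, 7, 9):
                for _ in range(int(rng.integers(1, 4))):
                    rows.append((
                        f"s{s}", f"{year}-{month:02d}-{int(rng.integers(1, 28)):02d}",
                        parameter, float(rng.lognormal(1.0, 0.8)),
                    ))
    return build_samples(rows)
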