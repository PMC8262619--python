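"""Reading, validating, and harmonizing long-format lake monitoring records.

Samples live in a pandas DataFrame with the canonical columns

    site_id          str      opaque site identifier
    sample_date      datetime calendar date of the sampling event
    depth_m          float    sample depth in meters (NaN when unknown)
    parameter        str      one of ``PARAMETERS``
    value            float    magnitude in canonical units
    below_detection  bool     True when reported below the detection limit
    detection_limit  float    the limit in canonical units (NaN otherwise)

Canonical units are °C for temperature, µg/L for chlorophyll a (``chla``),
total nitrogen (``tn``) and total phosphorus (``tp``), and a dimensionless
molar ratio for ``np_ratio``.  Replicate measurements of the same
(site, date, depth, parameter) are legal; they are resolved by medians
downstream, never here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARAMETERS = ("temperature", "chla", "tn", "tp", "np_ratio")

CANONICAL_UNITS = {
    "temperature": "degC",
    "chla": "ug/L",
    "tn": "ug/L",
    "tp": "ug/L",
    "np_ratio": "molar",
}

#: molar conversion for a TN/TP mass ratio: atomic weight P over atomic weight N.
#: Kept at full floating precision (rounds to 2.21 at two decimals).
N_TO_P_MOLAR = 30.974 / 14.007

SAMPLE_COLUMNS = [
    "site_id",
    "sample_date",
    "depth_m",
    "parameter",
    "value",
    "below_detection",
    "detection_limit",
]

_DEFAULT_SCHEMA = {c: c for c in SAMPLE_COLUMNS}

#: temperature plausibility window, °C (config-overridable)
DEFAULT_TEMPERATURE_WINDOW = (-5.0, 45.0)


@dataclass
class LoadReport:
    """Row accounting for one ingestion pass."""

    rows_read: int = 0
    rows_kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + n

    @property
    def rows_rejected(self) -> int:
        return sum(self.rejected.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ParameterSummary:
    """Descriptive statistics for one parameter, in canonical units."""

    parameter: str
    units: str
    p25: float
    mean: float
    median: float
    p75: float
    max: float
    sd: float


@dataclass(frozen=True)
class TrophicDistribution:
    """Percentage of sites per chlorophyll-based trophic state class."""

    oligotrophic: float
    mesotrophic: float
    eutrophic: float
    hypereutrophic: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _empty_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": pd.Series(dtype=str),
            "sample_date": pd.Series(dtype="datetime64[ns]"),
            "depth_m": pd.Series(dtype=float),
            "parameter": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
            "below_detection": pd.Series(dtype=bool),
            "detection_limit": pd.Series(dtype=float),
        }
    )


def read_samples(
    path,
    schema_map: Mapping[str, str] | None = None,
    unit_map: Mapping[tuple[str, str], float] | None = None,
    parameter_map: Mapping[str, str] | None = None,
    sep: str = ",",
    date_format: str | None = None,
    temperature_window: tuple[float, float] = DEFAULT_TEMPERATURE_WINDOW,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read long-format monitoring records into canonical samples.

    Parameters
    ----------
    path
        Delimited text file (CSV by default) in long format.
    schema_map
        Maps canonical column names to the file's column names, e.g.
        ``{"site_id": "Station", "value": "Result"}``.  Unmapped canonical
        columns are looked up under their own names; ``below_detection`` and
        ``detection_limit`` and ``depth_m`` are optional in the file.
    unit_map
        ``{(parameter, unit): factor}`` multiplicative conversions to
        canonical units, applied when the file carries a ``units`` column.
        A row whose unit is neither canonical nor mapped is rejected.
    parameter_map
        Maps the file's parameter names to canonical names (e.g.
        ``{"Total Nitrogen": "tn"}``); canonical names always pass through.
    date_format
        Optional explicit date format; ISO 8601 is parsed by default.
    temperature_window
        Plausibility bounds for temperature values, °C.

    Returns
    -------
    (samples, report)
        Canonical samples plus a :class:`LoadReport` with per-reason
        rejection counts.  Rows are rejected (never silently fixed) for
        unparseable dates/values, unknown parameters or units, negative
        concentrations, implausible temperatures, or negative depths.
    """
    schema = dict(_DEFAULT_SCHEMA)
    if schema_map:
        schema.update(schema_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    report = LoadReport(rows_read=len(raw))

    required = ["site_id", "sample_date", "parameter", "value"]
    missing = [schema[c] for c in required if schema[c] not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    df["site_id"] = raw[schema["site_id"]].astype(str)
    df["parameter"] = raw[schema["parameter"]].astype(str).str.strip()
    if parameter_map:
        df["parameter"] = df["parameter"].replace(dict(parameter_map))

    dates = pd.to_datetime(
        raw[schema["sample_date"]], format=date_format, errors="coerce"
    )
    df["sample_date"] = dates

    values = pd.to_numeric(raw[schema["value"]], errors="coerce")
    df["value"] = values

    depth_col = schema.get("depth_m")
    if depth_col in raw.columns:
        df["depth_m"] = pd.to_numeric(raw[depth_col], errors="coerce")
    else:
        df["depth_m"] = np.nan

    bd_col = schema.get("below_detection")
    if bd_col in raw.columns:
        df["below_detection"] = (
            raw[bd_col].fillna("").str.strip().str.lower().isin(
                {"1", "true", "t", "yes", "y", "<"}
            )
        )
    else:
        df["below_detection"] = False

    dl_col = schema.get("detection_limit")
    if dl_col in raw.columns:
        df["detection_limit"] = pd.to_numeric(raw[dl_col], errors="coerce")
    else:
        df["detection_limit"] = np.nan

    # unit conversion: only when the file carries a units column
    units_col = schema.get("units", "units")
    bad_unit = pd.Series(False, index=df.index)
    if units_col in raw.columns:
        units = raw[units_col].fillna("").str.strip()
        factors = pd.Series(1.0, index=df.index)
        for i in df.index:
            p, u = df.at[i, "parameter"], units.at[i]
            if not u or u == CANONICAL_UNITS.get(p):
                continue
            f = (unit_map or {}).get((p, u))
            if f is None:
                bad_unit.at[i] = True
            else:
                factors.at[i] = f
        df["value"] = df["value"] * factors
        df.loc[df["below_detection"], "detection_limit"] = (
            df.loc[df["below_detection"], "detection_limit"]
            * factors[df["below_detection"]]
        )

    # row-level validation, counted by reason; first failing reason wins
    bad_date = df["sample_date"].isna()
    bad_value = df["value"].isna()
    unknown_param = ~df["parameter"].isin(PARAMETERS)
    conc = df["parameter"].isin(["chla", "tn", "tp", "np_ratio"])
    negative = conc & (df["value"] < 0)
    lo, hi = temperature_window
    bad_temp = (df["parameter"] == "temperature") & (
        (df["value"] < lo) | (df["value"] > hi)
    )
    bad_depth = df["depth_m"] < 0

    drop = pd.Series(False, index=df.index)
    for mask, reason in [
        (bad_date, "bad_date"),
        (bad_value, "bad_value"),
        (unknown_param, "unknown_parameter"),
        (bad_unit, "unknown_unit"),
        (negative, "negative_value"),
        (bad_temp, "temperature_out_of_range"),
        (bad_depth, "negative_depth"),
    ]:
        new = mask & ~drop
        if new.any():
            report.reject(reason, int(new.sum()))
        drop |= mask

    out = df.loc[~drop, SAMPLE_COLUMNS].reset_index(drop=True)
    out["below_detection"] = out["below_detection"].astype(bool)
    report.rows_kept = len(out)
    if report.rows_rejected:
        logger.info("ingest: rejected %d/%d rows: %s",
                    report.rows_rejected, report.rows_read, report.rejected)
    return out, report


def write_samples(samples: pd.DataFrame, path) -> None:
    """Write canonical samples as CSV (ISO dates, full float precision)."""
    out = samples.copy()
    out["sample_date"] = pd.to_datetime(out["sample_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def compute_np_ratio(
    samples: pd.DataFrame,
    pairing: Sequence[str] = ("site_id", "sample_date", "depth_m"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Derive molar TN:TP samples from paired TN and TP measurements.

    TN and TP rows sharing the pairing key (default: same site, date, and
    depth — event-level pairing) are matched; replicates within an event are
    collapsed to their medians before the ratio is formed.  The mass ratio
    tn/tp is converted to a molar ratio with :data:`N_TO_P_MOLAR`
    (30.974/14.007, full precision).  Events with tp == 0 or with only one
    nutrient present yield no ratio and are counted in the report.

    Returns ``(np_ratio samples, report)`` where report holds
    ``pairs_matched``, ``tn_unmatched``, ``tp_unmatched``, ``tp_zero``.
    """
    pairing = list(pairing)
    tn = samples[samples["parameter"] == "tn"]
    tp = samples[samples["parameter"] == "tp"]
    tn_events = tn.groupby(pairing, dropna=False)["value"].median().reset_index()
    tp_events = tp.groupby(pairing, dropna=False)["value"].median().reset_index()
    merged = tn_events.merge(
        tp_events, on=pairing, how="outer", suffixes=("_tn", "_tp"), indicator=True
    )
    matched = merged[merged["_merge"] == "both"]
    tp_zero = matched["value_tp"] == 0
    ok = matched[~tp_zero].copy()
    report = {
        "pairs_matched": int(len(ok)),
        "tn_unmatched": int((merged["_merge"] == "left_only").sum()),
        "tp_unmatched": int((merged["_merge"] == "right_only").sum()),
        "tp_zero": int(tp_zero.sum()),
    }
    out = pd.DataFrame(
        {
            "site_id": ok.get("site_id", pd.Series(dtype=str)),
            "sample_date": ok.get("sample_date", pd.Series(dtype="datetime64[ns]")),
            "depth_m": ok.get("depth_m", np.nan) if "depth_m" in ok else np.nan,
            "parameter": "np_ratio",
            "value": ok["value_tn"] / ok["value_tp"] * N_TO_P_MOLAR,
            "below_detection": False,
            "detection_limit": np.nan,
        }
    )
    if out.empty:
        out = _empty_samples()
    return out.reset_index(drop=True)[SAMPLE_COLUMNS], report


DEFAULT_TROPHIC_BOUNDARIES = (3.5, 9.0, 24.0)
TROPHIC_CLASSES = ("oligotrophic", "mesotrophic", "eutrophic", "hypereutrophic")


def classify_trophic_state(chl, boundaries=DEFAULT_TROPHIC_BOUNDARIES):
    """Assign a chlorophyll-based trophic state class.

    Intervals are left-closed: a value equal to a boundary belongs to the
    upper class (chl = 3.5 µg/L is mesotrophic).  Defaults 3.5 / 9 / 24 µg/L;
    3.5 is the oligotrophic–mesotrophic limit, 9 the meso–eutrophic limit,
    24 a conventional hypereutrophic boundary.  Accepts a scalar or array.
    """
    b = np.asarray(boundaries, dtype=float)
    if not np.all(np.diff(b) > 0):
        raise ValueError("boundaries must be strictly increasing")
    arr = np.asarray(chl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chlorophyll must be non-negative")
    idx = np.searchsorted(b, arr, side="right")
    classes = np.take(TROPHIC_CLASSES, idx)
    if np.isscalar(chl) or arr.ndim == 0:
        return str(classes)
    return classes


def summarize_parameter(samples: pd.DataFrame, parameter: str) -> ParameterSummary:
    """Descriptive summary (quartiles, mean, median, max, sd) of one parameter.

    Quartiles use linear interpolation between order statistics.  The sd is
    the sample standard deviation (ddof=1); a single observation reports 0.
    """
    v = samples.loc[samples["parameter"] == parameter, "value"].to_numpy(float)
    if v.size == 0:
        raise ValueError(f"no samples for parameter {parameter!r}")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ParameterSummary(
        parameter=parameter,
        units=CANONICAL_UNITS[parameter],
        p25=float(np.percentile(v, 25)),
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        p75=float(np.percentile(v, 75)),
        max=float(np.max(v)),
        sd=sd,
    )


def site_medians(samples: pd.DataFrame, parameter: str) -> pd.Series:
    """Long-term median of a parameter per site (over all retained samples)."""
    sub = samples[samples["parameter"] == parameter]
    return sub.groupby("site_id")["value"].median()


def trophic_distribution(
    site_chla_medians: pd.Series | Iterable[float],
    boundaries=DEFAULT_TROPHIC_BOUNDARIES,
) -> TrophicDistribution:
    """Percentage of sites in each trophic class, from per-site chl medians."""
    med = pd.Series(site_chla_medians, dtype=float)
    if med.empty:
        raise ValueError("no site medians supplied")
    classes = classify_trophic_state(med.to_numpy(), boundaries)
    counts = pd.Series(classes).value_counts()
    pct = {c: 100.0 * counts.get(c, 0) / len(med) for c in TROPHIC_CLASSES}
    return TrophicDistribution(**pct)
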