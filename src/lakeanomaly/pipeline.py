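"""End-to-end orchestration: ingest -> eligibility -> anomaly -> trend.

`run_pipeline` ties the stages together into one reproducible run that
writes every intermediate table, a serialized copy of the effective
configuration (with a hash, so any output file is regenerable from the
echoed config plus the input alone), and a trend report in CSV, JSON and a
plain-text summary-table form using ++ / + / 0 / - / -- symbols.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from lakeanomaly import ingest as ing
from lakeanomaly.eligibility import EligibilityConfig, apply_eligibility, preset
from lakeanomaly.anomaly import anomaly_pipeline
from lakeanomaly.trend import (
    DEFAULT_ALPHA,
    DEFAULT_PATTERN_FRACTION,
    ThresholdRegistry,
    assess_trend,
    threshold_derivations,
)

logger = logging.getLogger(__name__)

YEARLY_COLUMNS = [
    "year", "parameter", "median_anomaly", "p25", "p75",
    "min", "max", "n_sites", "low_n_flag",
]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable for provenance."""

    input_path: str | None = None
    schema_map: dict = field(default_factory=dict)
    unit_map: dict = field(default_factory=dict)
    parameter_map: dict = field(default_factory=dict)
    eligibility: EligibilityConfig | str = "uriww"
    coverage_mode: str = "strict"
    reference_basis: str = "annual_medians"
    reference_period: tuple[int, int] | None = None
    alpha: float = DEFAULT_ALPHA
    pattern_fraction: float = DEFAULT_PATTERN_FRACTION
    thresholds_override: dict = field(default_factory=dict)
    compute_ratio: bool = True
    out_dir: str | None = None
    seed: int = 0

    def resolved_eligibility(self) -> EligibilityConfig:
        if isinstance(self.eligibility, str):
            return preset(self.eligibility)
        return self.eligibility

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where artifacts land, not what is computed
        d["eligibility"] = (
            self.eligibility if isinstance(self.eligibility, str)
            else self.eligibility.to_dict()
        )
        # unit_map keys may be tuples; make them JSON-safe
        d["unit_map"] = {f"{k[0]}|{k[1]}": v for k, v in self.unit_map.items()} \
            if self.unit_map else {}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _registry(config: RunConfig) -> ThresholdRegistry:
    base = threshold_derivations()
    if not config.thresholds_override:
        return base
    merged = dict(base.thresholds)
    merged.update(config.thresholds_override)
    prov = dict(base.provenance)
    for k in config.thresholds_override:
        prov[k] = "user override"
    return ThresholdRegistry(thresholds=merged, provenance=prov)


def run_pipeline(
    config: RunConfig,
    samples: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and (optionally) write all artifacts.

    ``samples`` may be passed directly (already-canonical records, e.g. from
    the simulator); otherwise ``config.input_path`` is read.  Returns a dict
    with the load report, eligibility report, all anomaly tables, and the
    per-parameter :class:`~lakeanomaly.trend.TrendAssessment` objects.  When
    ``config.out_dir`` is set, artifacts are written there with a
    reproducibility header (config hash + seed) in the text report.
    """
    if samples is None:
        if config.input_path is None:
            raise ValueError("need either samples or config.input_path")
        samples, load_report = ing.read_samples(
            config.input_path,
            schema_map=config.schema_map or None,
            unit_map=config.unit_map or None,
            parameter_map=config.parameter_map or None,
        )
    else:
        load_report = ing.LoadReport(rows_read=len(samples), rows_kept=len(samples))
    logger.info("pipeline: %d canonical samples", len(samples))

    ratio_report = None
    if config.compute_ratio and (samples["parameter"] == "np_ratio").sum() == 0:
        ratios, ratio_report = ing.compute_np_ratio(samples)
        if len(ratios):
            samples = pd.concat([samples, ratios], ignore_index=True)
        logger.info("pipeline: derived %d np_ratio samples", len(ratios))

    elig_config = config.resolved_eligibility()
    eligible, elig_report = apply_eligibility(
        samples, elig_config, coverage_mode=config.coverage_mode
    )

    tables = anomaly_pipeline(
        eligible,
        min_sites_per_year=elig_config.min_sites_per_year,
        reference_basis=config.reference_basis,
        reference_period=config.reference_period,
    )
    yearly = tables["yearly"]

    registry = _registry(config)
    assessments = {}
    for param in sorted(yearly["parameter"].unique()):
        sub = yearly[yearly["parameter"] == param]
        if len(sub) < 4:
            logger.warning("pipeline: %s has <4 retained years; skipped", param)
            continue
        assessments[param] = assess_trend(
            sub, registry=registry,
            alpha=config.alpha, pattern_fraction=config.pattern_fraction,
        )

    results = {
        "load_report": load_report,
        "ratio_report": ratio_report,
        "eligibility_report": elig_report,
        **tables,
        "assessments": assessments,
    }
    if config.out_dir is not None:
        _write_artifacts(config, results)
    return results


def trend_table(assessments: Mapping) -> pd.DataFrame:
    """Flatten assessments to one row per parameter."""
    rows = []
    for param, a in sorted(assessments.items()):
        rows.append({
            "parameter": param,
            "slope": a.fit.slope,
            "p_value": a.fit.p_value,
            "r_squared": a.fit.r_squared,
            "n_years": a.fit.n_years,
            "crit_statistical": a.crit_statistical,
            "crit_pattern": a.crit_pattern,
            "crit_magnitude": a.crit_magnitude,
            "n_criteria_met": a.n_criteria_met,
            "classification": a.classification,
            "direction": a.direction,
            "symbol": a.symbol,
        })
    return pd.DataFrame(rows)


def summary_text(assessments: Mapping, header: str = "") -> str:
    """Plain-text trend summary table (++ / + / 0 / - / -- per parameter)."""
    lines = []
    if header:
        lines += [header, ""]
    lines.append("parameter    slope        p        classification  symbol")
    lines.append("-" * 60)
    for param, a in sorted(assessments.items()):
        lines.append(
            f"{param:<12} {a.fit.slope:<12.4g} {a.fit.p_value:<8.3g} "
            f"{a.classification:<15} {a.symbol}"
        )
    return "\n".join(lines) + "\n"


def _write_artifacts(config: RunConfig, results: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps({"config": config.to_dict(),
                    "config_hash": config.config_hash(),
                    "seed": config.seed}, indent=2, default=str)
    )
    (out / "load_report.json").write_text(results["load_report"].to_json())
    (out / "eligibility_report.json").write_text(
        results["eligibility_report"].to_json())
    (out / "eligibility_report.txt").write_text(
        results["eligibility_report"].to_text() + "\n")
    results["site_year_medians"].to_csv(out / "site_year_medians.csv", index=False)
    results["references"].to_csv(out / "site_reference_medians.csv", index=False)
    results["yearly"][YEARLY_COLUMNS].to_csv(
        out / "yearly_median_anomaly.csv", index=False)
    tt = trend_table(results["assessments"])
    tt.to_csv(out / "trend_report.csv", index=False)
    (out / "trend_report.json").write_text(
        json.dumps({p: a.to_dict() for p, a in results["assessments"].items()},
                   indent=2, default=str))
    header = (f"Trend summary (config {config.config_hash()}, "
              f"seed {config.seed})")
    (out / "trend_summary.txt").write_text(
        summary_text(results["assessments"], header=header))
    logger.info("pipeline: artifacts written to %s", out)


def render_figures(
    yearly: pd.DataFrame,
    fits: Mapping,
    out_dir,
    fmt: str = "png",
) -> list[Path]:
    """Render one anomaly-trend figure per parameter.

    Points are yearly median anomalies colored by sign (above / below /
    equal to the long-term reference), bars span the 25th–75th percentiles
    (the full range, plus an asterisk, for years at the minimum site
    count), and the fitted line is overlaid.  Parameters without rows are
    skipped with a warning.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for param, fit in fits.items():
        sub = yearly[yearly["parameter"] == param]
        if sub.empty:
            logger.warning("render_figures: no yearly rows for %s; skipped", param)
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        colors = sub["median_anomaly"].map(
            lambda v: "firebrick" if v > 0 else ("steelblue" if v < 0 else "gray"))
        lo = sub["median_anomaly"] - sub["p25"]
        hi = sub["p75"] - sub["median_anomaly"]
        low_n = sub["low_n_flag"].to_numpy(bool)
        lo[low_n] = (sub["median_anomaly"] - sub["min"])[low_n]
        hi[low_n] = (sub["max"] - sub["median_anomaly"])[low_n]
        ax.errorbar(sub["year"], sub["median_anomaly"], yerr=[lo, hi],
                    fmt="none", ecolor="0.6", elinewidth=1, capsize=2)
        ax.scatter(sub["year"], sub["median_anomaly"], c=colors, zorder=3)
        for _, row in sub[sub["low_n_flag"]].iterrows():
            ax.annotate("*", (row["year"], row["max"]),
                        ha="center", va="bottom", fontsize=12)
        xs = sub["year"].to_numpy(float)
        ax.plot(xs, fit.intercept + fit.slope * xs, color="black", lw=1.2)
        ax.axhline(0, color="0.8", lw=0.8, zorder=0)
        ax.set_xlabel("year")
        ax.set_ylabel(f"{param} median anomaly")
        ax.set_title(
            f"{param}: slope {fit.slope:.4g}/yr, p {fit.p_value:.3g}")
        path = out / f"{param}_anomaly_trend.{fmt}"
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
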