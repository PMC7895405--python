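"""End-to-end orchestration: simulate -> gate -> quantify -> score -> evaluate.

Stages communicate through plain CSV contracts so each is independently
testable and re-runnable:

* ``manifest.csv`` — sample_id, diagnosis_label, specimen_type, paths, seed;
* ``results.csv`` — long format, one row per (sample, marker):
  percent_positive, mfir, pattern, n_lymphocytes, n_b_cells;
* ``scores.csv`` — the three scores, classifications and point breakdown;
* ``accuracy.csv`` + report tables — per-system and per-marker accuracy,
  CD200 cohort summary and score cross-tabs.

A run is fully reproducible from (config, master seed); all randomness
flows from the single master seed via per-sample substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, gating, scoring, simulate
from .gating import GateParams, MarkerResult, MarkerResultSet
from .panel import CLASSICAL_MARKERS, PANEL_MARKERS, is_cll

logger = logging.getLogger(__name__)

_POINT_MARKERS = CLASSICAL_MARKERS + ("CD200",)

#: Continuous orientation used for per-marker rank AUC: +1 when higher
#: percent-positive indicates CLL, -1 when lower does.
_MARKER_ORIENTATION = {"CD5": 1, "CD23": 1, "CD200": 1, "FMC7": -1, "CD79b": -1}

_SIGM_ORDINAL = {"weak": 2, "moderate": 1, "strong": 0}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    composition: Mapping[str, int] = field(
        default_factory=lambda: dict(simulate.DEFAULT_COMPOSITION)
    )
    events_per_sample: int = simulate.DEFAULT_EVENTS_PER_SAMPLE
    master_seed: int = 0
    cd45_min: float = 300.0
    ssc_max: float = 250.0
    positivity_percentile: float = gating.DEFAULT_POSITIVITY_PERCENTILE
    cd200_mode: str = "percent"
    outdir: Path | None = None
    write_events: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cd200_mode not in ("percent", "mfir"):
            raise simulate.ConfigurationError(f"bad cd200_mode {self.cd200_mode!r}")
        self.master_seed = int(self.master_seed)

    def gate_params(self) -> GateParams:
        return GateParams(
            cd45_min=self.cd45_min,
            ssc_max=self.ssc_max,
            positivity_percentile=self.positivity_percentile,
        )

    def cohort_config(self) -> simulate.CohortConfig:
        return simulate.CohortConfig(
            composition=dict(self.composition),
            events_per_sample=self.events_per_sample,
            outdir=self.outdir,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" in raw and raw["outdir"] is not None:
            raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["composition"] = dict(raw["composition"])
        raw["outdir"] = None if self.outdir is None else str(self.outdir)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stage: analyze (gate + quantify)
# ---------------------------------------------------------------------------

def analyze_cohort(
    samples: Iterable[simulate.SimulatedSample],
    params: GateParams = GateParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate and quantify every sample; returns (manifest, long results)."""
    manifest_rows = []
    result_frames = []
    n = 0
    for sample in samples:
        res = gating.analyze_sample(
            sample.events.stained,
            sample.events.isotype,
            params,
            sample_id=sample.sample_id,
        )
        result_frames.append(res.to_frame())
        manifest_rows.append(
            {
                "sample_id": sample.sample_id,
                "diagnosis_label": sample.diagnosis_label,
                "specimen_type": sample.specimen_type,
                "events_path": "",
                "isotype_path": "",
                "seed_offset": sample.seed_offset,
                "low_yield_warning": sample.events.low_yield or res.low_yield,
            }
        )
        n += 1
    logger.info("analyze: %d samples quantified", n)
    manifest = pd.DataFrame(manifest_rows)
    results = (
        pd.concat(result_frames, ignore_index=True)
        if result_frames
        else pd.DataFrame()
    )
    return manifest, results


def results_from_frame(frame: pd.DataFrame, sample_id: str) -> MarkerResultSet:
    """Rebuild a MarkerResultSet from rows of the long results table."""
    sub = frame.loc[frame["sample_id"] == sample_id]
    if sub.empty:
        raise ValueError(f"no results for sample {sample_id}")
    markers = {
        row.marker: MarkerResult(
            percent_positive=float(row.percent_positive),
            mfir=float(row.mfir),
            pattern=str(row.pattern),
            threshold=float("nan"),
        )
        for row in sub.itertuples()
    }
    return MarkerResultSet(
        sample_id=sample_id,
        markers=markers,
        n_events=0,
        n_lymphocytes=int(sub["n_lymphocytes"].iloc[0]),
        n_b_cells=int(sub["n_b_cells"].iloc[0]),
        low_yield=bool(sub["n_b_cells"].iloc[0] < gating.MIN_B_CELLS),
    )


# ---------------------------------------------------------------------------
# stage: score
# ---------------------------------------------------------------------------

def score_cohort(results: pd.DataFrame, cd200_mode: str = "percent") -> pd.DataFrame:
    """Score every sample in the long results table."""
    rows = []
    for sample_id in results["sample_id"].unique():
        res = results_from_frame(results, sample_id)
        sr = scoring.score_sample(res, cd200_mode)
        row = {
            "sample_id": sample_id,
            "classical_score": sr.classical_score,
            "augmented_score": sr.augmented_score,
            "four_marker_score": sr.four_marker_score,
            "classical_class": sr.classical_class,
            "augmented_class": sr.augmented_class,
            "four_marker_class": sr.four_marker_class,
        }
        row.update({f"point_{m}": sr.points[m] for m in _POINT_MARKERS})
        rows.append(row)
    logger.info("score: %d samples scored", len(rows))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage: evaluate
# ---------------------------------------------------------------------------

def evaluate_cohort(
    scores: pd.DataFrame, manifest: pd.DataFrame, results: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Accuracy tables for the three systems and the individual markers.

    Raises if only one truth class is present (a cohort with no CLL or no
    non-CLL cannot be evaluated).
    """
    merged = scores.merge(
        manifest[["sample_id", "diagnosis_label"]], on="sample_id", validate="1:1"
    )
    truth = merged["diagnosis_label"].map(is_cll).to_numpy()
    if truth.all() or not truth.any():
        raise ValueError("evaluation requires both CLL and non-CLL samples")

    system_rows = []
    calls_by_system = {}
    for system in scoring.SYSTEMS:
        score_vals = merged[f"{system}_score"].to_numpy()
        calls = score_vals >= 4
        calls_by_system[system] = calls
        summ = diagnostics.evaluate_binary(calls, truth, scores=score_vals)
        system_rows.append(_summary_row(system, summ))
    system_table = pd.DataFrame(system_rows)

    pair_rows = []
    systems = list(scoring.SYSTEMS)
    for i, sys_a in enumerate(systems):
        for sys_b in systems[i + 1:]:
            p = diagnostics.mcnemar_test(
                calls_by_system[sys_a], calls_by_system[sys_b], truth
            )
            pair_rows.append({"system_a": sys_a, "system_b": sys_b, "mcnemar_p": p})
    mcnemar_table = pd.DataFrame(pair_rows)

    marker_table = _marker_accuracy(merged, results, truth)
    cutoff_table = _cd200_cutoffs(results, manifest)
    logger.info(
        "evaluate: %d systems, %d marker rows", len(system_table), len(marker_table)
    )
    return {
        "system_accuracy": system_table,
        "mcnemar": mcnemar_table,
        "marker_accuracy": marker_table,
        "cd200_cutoffs": cutoff_table,
    }


def _summary_row(name: str, summ: diagnostics.AccuracySummary) -> dict:
    return {
        "name": name,
        "sensitivity": summ.sensitivity[0],
        "sensitivity_lo": summ.sensitivity[1],
        "sensitivity_hi": summ.sensitivity[2],
        "specificity": summ.specificity[0],
        "specificity_lo": summ.specificity[1],
        "specificity_hi": summ.specificity[2],
        "accuracy": summ.accuracy[0],
        "accuracy_lo": summ.accuracy[1],
        "accuracy_hi": summ.accuracy[2],
        "auc": summ.auc[0],
        "auc_lo": summ.auc[1],
        "auc_hi": summ.auc[2],
        "tp": summ.confusion.tp,
        "fp": summ.confusion.fp,
        "fn": summ.confusion.fn,
        "tn": summ.confusion.tn,
    }


def _wide_results(results: pd.DataFrame, column: str) -> pd.DataFrame:
    return results.pivot(index="sample_id", columns="marker", values=column)


def _marker_accuracy(
    merged: pd.DataFrame, results: pd.DataFrame, truth: np.ndarray
) -> pd.DataFrame:
    pct = _wide_results(results, "percent_positive").loc[merged["sample_id"]]
    pattern = _wide_results(results, "pattern").loc[merged["sample_id"]]
    mfir = _wide_results(results, "mfir").loc[merged["sample_id"]]

    rows = []
    for marker in _POINT_MARKERS:
        calls = merged[f"point_{marker}"].to_numpy().astype(bool)
        if marker == "sIgM":
            cont = pattern["sIgM"].map(_SIGM_ORDINAL).to_numpy(dtype=float)
        else:
            cont = _MARKER_ORIENTATION[marker] * pct[marker].to_numpy(dtype=float)
        summ = diagnostics.evaluate_binary(calls, truth, scores=cont)
        u, p = diagnostics.mann_whitney(cont[truth], cont[~truth])
        row = _summary_row(marker, summ)
        row["mann_whitney_p"] = p
        rows.append(row)

    # CD200 scored by MFIR instead of percent
    calls = mfir["CD200"].to_numpy(dtype=float) >= 18.0
    summ = diagnostics.evaluate_binary(
        calls, truth, scores=mfir["CD200"].to_numpy(dtype=float)
    )
    u, p = diagnostics.mann_whitney(
        mfir["CD200"].to_numpy(dtype=float)[truth],
        mfir["CD200"].to_numpy(dtype=float)[~truth],
    )
    row = _summary_row("CD200_mfir", summ)
    row["mann_whitney_p"] = p
    rows.append(row)
    return pd.DataFrame(rows)


def _cd200_cutoffs(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    pct = _wide_results(results, "percent_positive")
    mfir = _wide_results(results, "mfir")
    diag = manifest.set_index("sample_id")["diagnosis_label"].loc[pct.index]
    truth = diag.map(is_cll).to_numpy()
    rows = []
    for name, vals in (
        ("CD200_percent", pct["CD200"].to_numpy(dtype=float)),
        ("CD200_mfir", mfir["CD200"].to_numpy(dtype=float)),
    ):
        cut, sens, spec = diagnostics.roc_optimal_cutoff(vals, truth)
        rows.append(
            {"measure": name, "optimal_cutoff": cut, "sensitivity": sens, "specificity": spec}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage: report tables
# ---------------------------------------------------------------------------

def summarize_cohort_tables(
    scores: pd.DataFrame, results: pd.DataFrame, manifest: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Cohort-level report tables.

    * ``cd200_summary`` — per-diagnosis median/range of CD200
      percent-positive and MFIR, with counts at the 30% and MFIR-18 cuts;
    * ``score_distribution`` — per-system score-by-group cross-tab;
    * plus the accuracy tables from :func:`evaluate_cohort`.
    """
    if scores.empty or results.empty or manifest.empty:
        raise ValueError("summarize_cohort_tables requires non-empty inputs")
    merged = scores.merge(
        manifest[["sample_id", "diagnosis_label"]], on="sample_id", validate="1:1"
    )
    pct = _wide_results(results, "percent_positive")
    mfir = _wide_results(results, "mfir")
    diag = manifest.set_index("sample_id")["diagnosis_label"]

    cd200 = pd.DataFrame(
        {
            "diagnosis_label": diag.loc[pct.index],
            "percent": pct["CD200"],
            "mfir": mfir["CD200"],
        }
    )
    summary_rows = []
    for label, grp in cd200.groupby("diagnosis_label", sort=False):
        summary_rows.append(
            {
                "diagnosis_label": label,
                "n": len(grp),
                "percent_median": grp["percent"].median(),
                "percent_min": grp["percent"].min(),
                "percent_max": grp["percent"].max(),
                "n_percent_ge30": int((grp["percent"] >= 30.0).sum()),
                "mfir_median": grp["mfir"].median(),
                "mfir_min": grp["mfir"].min(),
                "mfir_max": grp["mfir"].max(),
                "n_mfir_ge18": int((grp["mfir"] >= 18.0).sum()),
            }
        )
    cd200_summary = pd.DataFrame(summary_rows)

    dist_rows = []
    group = np.where(merged["diagnosis_label"].map(is_cll), "CLL", "non_CLL")
    for system in scoring.SYSTEMS:
        tab = (
            pd.crosstab(merged[f"{system}_score"], group)
            .reindex(columns=["CLL", "non_CLL"], fill_value=0)
            .sort_index(ascending=False)
        )
        for score_val, row in tab.iterrows():
            dist_rows.append(
                {
                    "system": system,
                    "score": int(score_val),
                    "CLL": int(row["CLL"]),
                    "non_CLL": int(row["non_CLL"]),
                }
            )
    score_distribution = pd.DataFrame(dist_rows)
    return {"cd200_summary": cd200_summary, "score_distribution": score_distribution}


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class CohortRun:
    """All artifacts of one in-memory pipeline run."""

    config: RunConfig
    manifest: pd.DataFrame
    results: pd.DataFrame
    scores: pd.DataFrame
    accuracy: dict[str, pd.DataFrame]
    tables: dict[str, pd.DataFrame]


def run_cohort(config: RunConfig) -> CohortRun:
    """Simulate, gate, quantify, score and evaluate one cohort in memory."""
    samples = simulate.iter_cohort(config.cohort_config(), config.master_seed)
    manifest, results = analyze_cohort(samples, config.gate_params())
    if manifest.empty:
        raise ValueError("empty cohort: nothing to analyze")
    scores = score_cohort(results, config.cd200_mode)
    if not (len(manifest) == scores["sample_id"].nunique() == results["sample_id"].nunique()):
        raise RuntimeError("row counts not conserved across stages")
    accuracy = evaluate_cohort(scores, manifest, results)
    tables = summarize_cohort_tables(scores, results, manifest)
    return CohortRun(
        config=config,
        manifest=manifest,
        results=results,
        scores=scores,
        accuracy=accuracy,
        tables=tables,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline and write every artifact to config.outdir."""
    if config.outdir is None:
        raise simulate.ConfigurationError("run_pipeline requires config.outdir")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.write_events:
        manifest = simulate.generate_cohort(config.cohort_config(), config.master_seed)

    run = run_cohort(config)
    fmt = "%.6g"
    run.manifest.to_csv(outdir / "manifest.csv", index=False)
    run.results.to_csv(outdir / "results.csv", index=False, float_format=fmt)
    run.scores.to_csv(outdir / "scores.csv", index=False)
    run.accuracy["system_accuracy"].to_csv(
        outdir / "accuracy.csv", index=False, float_format=fmt
    )
    run.accuracy["mcnemar"].to_csv(outdir / "mcnemar.csv", index=False, float_format=fmt)
    run.accuracy["marker_accuracy"].to_csv(
        outdir / "marker_accuracy.csv", index=False, float_format=fmt
    )
    run.accuracy["cd200_cutoffs"].to_csv(
        outdir / "cd200_cutoffs.csv", index=False, float_format=fmt
    )
    run.tables["cd200_summary"].to_csv(
        outdir / "report_cd200_summary.csv", index=False, float_format=fmt
    )
    run.tables["score_distribution"].to_csv(
        outdir / "report_score_distribution.csv", index=False
    )

    summary = {
        "n_samples": int(len(run.manifest)),
        "n_results_rows": int(len(run.results)),
        "n_scores_rows": int(len(run.scores)),
        "master_seed": config.master_seed,
        "events_per_sample": config.events_per_sample,
        "cd200_mode": config.cd200_mode,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config_used.yaml")
    logger.info("pipeline complete: %d samples -> %s", summary["n_samples"], outdir)
    return outdir
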