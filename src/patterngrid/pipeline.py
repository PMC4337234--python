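"""End-to-end analysis: codings + outcomes -> report tables.

Mirrors the study's results layout: a per-patient summary table, the
intercorrelation/means/SD table over the ten analysis variables, paired
pre/post tests, and the two sets of hierarchical regressions (phase-1 and
phase-2 process variables predicting each outcome, pretreatment score
entered at step 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import outcome_stats, pattern_engine, phase_analysis
from .coding_io import average_coders, export_trajectories
from .errors import ContractError

logger = logging.getLogger(__name__)

#: the ten analysis variables of the intercorrelation table, in print order
TABLE1_VARIABLES = [
    "dispersion1",
    "dispersion2",
    "peak_processing1",
    "peak_processing2",
    "scid_pre",
    "scid_post",
    "neg_strength_pre",
    "neg_strength_post",
    "pos_strength_pre",
    "pos_strength_post",
]

OUTCOME_MODELS = {
    # outcome -> (step-1 pretreatment predictor, phase-k process predictors)
    "scid_post": ("scid_pre", ["dispersion{k}", "peak_processing{k}"]),
    "neg_strength_post": ("neg_strength_pre", ["dispersion{k}", "peak_processing{k}"]),
    "pos_strength_post": ("pos_strength_pre", ["dispersion{k}", "peak_processing{k}"]),
}

PAIRED_CONTRASTS = [
    # label, minuend, subtrahend  (positive mean diff = first larger)
    ("negative_strength_pre_minus_post", "neg_strength_pre", "neg_strength_post"),
    ("positive_strength_pre_minus_post", "pos_strength_pre", "pos_strength_post"),
    ("processing_phase1_minus_phase2", "peak_processing1", "peak_processing2"),
    ("dispersion_phase1_minus_phase2", "dispersion1", "dispersion2"),
    ("scid_pre_minus_post", "scid_pre", "scid_post"),
]


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    dropped: pd.DataFrame
    correlations: outcome_stats.CorrelationMatrix
    paired_tests: pd.DataFrame
    regressions: dict  # (outcome, phase) -> list[RegressionStep]
    regression_tables: pd.DataFrame
    config_hash: str = ""


def analyze(
    codings: pd.DataFrame,
    outcomes: pd.DataFrame,
    schedule: phase_analysis.PhaseSchedule | None = None,
    threshold: float = pattern_engine.DEFAULT_THRESHOLD,
    cognitive_mode: str = "node-mean",
) -> AnalysisResult:
    """Run the full analysis on an in-memory dataset."""
    schedule = schedule or phase_analysis.PhaseSchedule()
    summaries, dropped = phase_analysis.build_summaries(
        codings, outcomes, schedule, threshold=threshold,
        cognitive_mode=cognitive_mode,
    )
    if summaries.empty:
        raise ContractError("no analyzable patients after coverage rules")
    corr = outcome_stats.correlation_matrix(summaries, TABLE1_VARIABLES)

    paired_rows = []
    for label, a, b in PAIRED_CONTRASTS:
        pair = summaries[[a, b]].dropna()
        try:
            res = outcome_stats.paired_t(pair[a], pair[b])
        except Exception as exc:  # degenerate contrast: report, don't fail
            logger.warning("paired test %s skipped: %s", label, exc)
            continue
        paired_rows.append(
            {
                "contrast": label,
                "mean_diff": res.mean_diff,
                "sd_diff": res.sd_diff,
                "n": res.n,
                "df": res.df,
                "t": res.t,
                "p": res.p,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "cohen_d": res.cohen_d,
            }
        )
    paired = pd.DataFrame(paired_rows)

    regressions = {}
    tables = []
    for outcome, (pre, process) in OUTCOME_MODELS.items():
        for k in (1, 2):
            steps = [[pre], [p.format(k=k) for p in process]]
            result = outcome_stats.hierarchical_regression(summaries, outcome, steps)
            regressions[(outcome, k)] = result
            tbl = outcome_stats.regression_table(result, outcome)
            tbl.insert(1, "phase", k)
            tables.append(tbl)
    return AnalysisResult(
        summaries=summaries,
        dropped=dropped,
        correlations=corr,
        paired_tests=paired,
        regressions=regressions,
        regression_tables=pd.concat(tables, ignore_index=True),
    )


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed float formatting so repeated runs are byte-identical."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.10g}"
            )
    return out


def write_report(
    result: AnalysisResult,
    directory: str | Path,
    config: dict | None = None,
) -> dict:
    """Persist all report tables; returns the file manifest.

    Every table carries the config hash (in the manifest and run log) for
    provenance; output is deterministic given inputs + config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = config or {}
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    config_hash = hashlib.sha256(blob).hexdigest()[:16]
    result.config_hash = config_hash

    manifest = {"config_hash": config_hash, "files": []}

    def save(df: pd.DataFrame, name: str, index=False) -> None:
        path = directory / name
        _format_frame(df).to_csv(path, index=index, encoding="utf-8")
        manifest["files"].append(name)

    save(result.summaries, "summaries.csv")
    save(result.dropped, "dropped_patients.csv")
    corr = result.correlations
    table1 = corr.r.copy()
    table1.loc["mean"] = corr.means
    table1.loc["sd"] = corr.sds
    save(table1.reset_index(names="variable"), "table1_correlations.csv")
    save(corr.n.reset_index(names="variable"), "table1_pair_n.csv")
    save(corr.p.reset_index(names="variable"), "table1_p_values.csv")
    save(result.paired_tests, "paired_tests.csv")
    for k in (1, 2):
        tbl = result.regression_tables
        save(
            tbl[tbl["phase"] == k].drop(columns="phase"),
            f"regressions_phase{k}.csv",
        )
    with open(directory / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"config_hash": config_hash, "config": config},
            fh, indent=1, sort_keys=True, default=str,
        )
    manifest["files"].append("run_metadata.json")
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def export_grid_trajectories(
    codings: pd.DataFrame,
    directory: str | Path,
    schedule: phase_analysis.PhaseSchedule | None = None,
    threshold: float = pattern_engine.DEFAULT_THRESHOLD,
    cognitive_mode: str = "node-mean",
) -> list[Path]:
    """GridWare-style trajectory files for every patient-phase."""
    profiles = pattern_engine.profiles_frame(
        average_coders(codings), threshold=threshold, cognitive_mode=cognitive_mode
    )
    trajs = phase_analysis.trajectories_from_profiles(profiles, schedule)
    return export_trajectories(trajs, directory)
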