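"""Phase assignment and the per-patient analysis row.

Treatment is split into a symptom-reduction phase (sessions 1-10, with
session 1 as baseline) and a schema-focused phase (sessions 11-34).  Per
patient the analysis row holds: per-phase grid dispersion (baseline and
the post-assessment session excluded from their phases' grids), per-phase
peak emotional processing, pattern strengths at baseline and at the coded
session closest to the post-assessment target, and the SCID-II pre/post
symptom sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pattern_engine, state_space
from .coding_io import average_coders
from .errors import ContractError

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "patient_id",
    "dispersion1",
    "dispersion2",
    "peak_processing1",
    "peak_processing2",
    "neg_strength_pre",
    "neg_strength_post",
    "pos_strength_pre",
    "pos_strength_post",
    "scid_pre",
    "scid_post",
    "post_session",
)


@dataclass(frozen=True)
class PhaseSchedule:
    """Session ranges for the two treatment phases.

    ``post_target`` is the nominal post-assessment session; the actual post
    measurement uses the coded session closest to it (earlier on ties).
    """

    phase1: tuple[int, int] = (1, 10)
    phase2: tuple[int, int] = (11, 34)
    baseline_session: int = 1
    post_target: int = 34

    def __post_init__(self) -> None:
        if not (self.phase1[0] <= self.phase1[1] < self.phase2[0] <= self.phase2[1]):
            raise ContractError("phase ranges must be ordered and disjoint")
        if not self.phase1[0] <= self.baseline_session <= self.phase1[1]:
            raise ContractError("baseline session must lie in phase 1")
        if self.post_target <= self.phase1[1]:
            raise ContractError("post target must lie beyond phase 1")


def assign_phase(
    session_number: int,
    schedule: PhaseSchedule | None = None,
    post_session: int | None = None,
) -> str:
    """Label a session: baseline / phase1 / phase2 / post / outside.

    ``post_session`` is the patient-specific coded session used for the
    posttreatment measurement; when given, it is labelled ``post`` (and so
    excluded from phase-2 dispersion by callers).
    """
    schedule = schedule or PhaseSchedule()
    if session_number < 1:
        raise ContractError("session numbers are 1-based")
    if session_number == schedule.baseline_session:
        return "baseline"
    if post_session is not None and session_number == post_session:
        return "post"
    if schedule.phase1[0] <= session_number <= schedule.phase1[1]:
        return "phase1"
    if schedule.phase2[0] <= session_number <= schedule.phase2[1]:
        return "phase2"
    return "outside"


def peak_processing(
    sessions: pd.Series | dict,
) -> tuple[float, int]:
    """Maximum averaged processing rating in a phase and its session.

    ``sessions`` maps session number -> averaged processing rating.
    Returns ``(peak, session_at_peak)`` with the earliest session on ties.
    NaN ratings are ignored; an all-NaN or empty phase yields
    ``(nan, -1)``.
    """
    if isinstance(sessions, dict):
        sessions = pd.Series(sessions, dtype=float)
    sessions = sessions.dropna()
    if sessions.empty:
        return float("nan"), -1
    peak = float(sessions.max())
    at = int(min(s for s, v in sessions.items() if v == peak))
    return peak, at


def select_post_session(coded_sessions, schedule: PhaseSchedule) -> int | None:
    """Coded session minimizing |session - post_target| (earlier on ties).

    Only sessions at or after the start of phase 2 qualify; returns None if
    no such session was coded.
    """
    candidates = [s for s in coded_sessions if s >= schedule.phase2[0]]
    if not candidates:
        return None
    return min(candidates, key=lambda s: (abs(s - schedule.post_target), s))


def endpoint_strengths(
    profiles: pd.DataFrame,
    schedule: PhaseSchedule,
) -> dict:
    """Baseline and posttreatment pattern strengths for one patient.

    ``profiles`` is one patient's slice of
    :func:`patterngrid.pattern_engine.profiles_frame`.  Returns a dict with
    ``neg/pos_strength_pre/post`` (NaN when the required session is not
    coded) and ``post_session``.
    """
    by_session = profiles.set_index("session_number")
    out = {
        "neg_strength_pre": np.nan,
        "pos_strength_pre": np.nan,
        "neg_strength_post": np.nan,
        "pos_strength_post": np.nan,
        "post_session": None,
    }
    if schedule.baseline_session in by_session.index:
        row = by_session.loc[schedule.baseline_session]
        out["neg_strength_pre"] = float(row["neg_strength"])
        out["pos_strength_pre"] = float(row["pos_strength"])
    post = select_post_session(by_session.index, schedule)
    if post is not None:
        row = by_session.loc[post]
        out["neg_strength_post"] = float(row["neg_strength"])
        out["pos_strength_post"] = float(row["pos_strength"])
        out["post_session"] = post
    return out


def phase_points(
    profiles: pd.DataFrame,
    schedule: PhaseSchedule,
    post_session: int | None,
) -> dict:
    """Grid points and processing ratings per phase for one patient.

    Phase-1 dispersion points exclude the baseline session; phase-2 points
    exclude the patient's post-assessment session.  Peak processing for
    phase 1 is taken over the full first-10-sessions window (baseline
    included); for phase 2 it excludes the post session so the peak always
    precedes the posttreatment measurement.  Sessions with incomputable
    activation are dropped from grids with a log entry.
    """
    pts: dict = {"phase1": [], "phase2": [], "proc1": {}, "proc2": {}}
    for row in profiles.itertuples(index=False):
        s = int(row.session_number)
        label = assign_phase(s, schedule, post_session)
        if label in ("baseline", "phase1"):
            pts["proc1"][s] = row.processing
        elif label == "phase2":
            pts["proc2"][s] = row.processing
        if label in ("phase1", "phase2"):
            if np.isnan(row.pos_activation) or np.isnan(row.neg_activation):
                logger.info(
                    "patient %s session %s dropped from %s grid: "
                    "incomputable activation",
                    row.patient_id, s, label,
                )
                continue
            pts[label].append((s, int(row.pos_activation), int(row.neg_activation)))
    return pts


def _phase_dispersion(points: list[tuple[int, int, int]]) -> float:
    if not points:
        return float("nan")
    grid = state_space.build_grid([(x, y) for _, x, y in points])
    return state_space.dispersion(grid).value


def build_summaries(
    codings: pd.DataFrame,
    outcomes: pd.DataFrame,
    schedule: PhaseSchedule | None = None,
    threshold: float = pattern_engine.DEFAULT_THRESHOLD,
    cognitive_mode: str = "node-mean",
    averaged: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-patient analysis table.

    Returns ``(summaries, dropped)``: one summary row per patient passing
    the coverage rules, and a table of dropped patients with reasons.
    Patients with some missing summary fields are retained (their NaNs are
    handled pairwise/listwise by the statistics layer); a patient is
    dropped outright only without a baseline coding, a post-window coding,
    or an outcome record.  The result is a pure function of its inputs.
    """
    schedule = schedule or PhaseSchedule()
    if averaged is None:
        averaged = average_coders(codings)
    profiles = pattern_engine.profiles_frame(
        averaged, threshold=threshold, cognitive_mode=cognitive_mode
    )
    outcome_by_id = outcomes.set_index("patient_id")

    rows, dropped = [], []
    for pid, grp in profiles.groupby("patient_id", sort=True):
        if pid not in outcome_by_id.index:
            dropped.append({"patient_id": pid, "reason": "no outcome record"})
            continue
        ends = endpoint_strengths(grp, schedule)
        if np.isnan(ends["neg_strength_pre"]) and np.isnan(ends["pos_strength_pre"]):
            dropped.append({"patient_id": pid, "reason": "no baseline coding"})
            continue
        if ends["post_session"] is None:
            dropped.append({"patient_id": pid, "reason": "no post-window coding"})
            continue
        pts = phase_points(grp, schedule, ends["post_session"])
        peak1, _ = peak_processing(pts["proc1"])
        peak2, _ = peak_processing(pts["proc2"])
        rows.append(
            {
                "patient_id": pid,
                "dispersion1": _phase_dispersion(pts["phase1"]),
                "dispersion2": _phase_dispersion(pts["phase2"]),
                "peak_processing1": peak1,
                "peak_processing2": peak2,
                "neg_strength_pre": ends["neg_strength_pre"],
                "neg_strength_post": ends["neg_strength_post"],
                "pos_strength_pre": ends["pos_strength_pre"],
                "pos_strength_post": ends["pos_strength_post"],
                "scid_pre": float(outcome_by_id.loc[pid, "scid_pre"]),
                "scid_post": float(outcome_by_id.loc[pid, "scid_post"]),
                "post_session": ends["post_session"],
            }
        )
        if not pts["phase2"]:
            logger.info(
                "patient %s: phase-2 dispersion missing "
                "(only the post session was coded in phase 2)", pid,
            )
    summaries = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    dropped_df = pd.DataFrame(dropped, columns=["patient_id", "reason"])
    for rec in dropped:
        logger.info("patient %s dropped: %s", rec["patient_id"], rec["reason"])
    return summaries, dropped_df


def trajectories_from_profiles(
    profiles: pd.DataFrame,
    schedule: PhaseSchedule | None = None,
) -> dict:
    """Per patient-phase ordered (onset, x, y) points for GridWare export."""
    schedule = schedule or PhaseSchedule()
    out = {}
    for pid, grp in profiles.groupby("patient_id", sort=True):
        post = select_post_session(grp["session_number"], schedule)
        pts = phase_points(grp, schedule, post)
        out[(pid, "phase1")] = pts["phase1"]
        out[(pid, "phase2")] = pts["phase2"]
    return out
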