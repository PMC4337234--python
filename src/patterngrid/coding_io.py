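"""Read, validate and normalize coded-session tables.

The canonical on-disk format is a long CSV with one row per
(patient, session, coder) and one column per CHANGE variable.  Ratings are
ordinal integers 0-3; a missing rating is an empty cell (parsed to NaN) and
propagates downstream as "node missing" rather than being imputed.

In memory a dataset is a :class:`pandas.DataFrame` with the canonical
columns; :class:`SessionCoding` / :class:`AveragedCoding` are light typed
views used at API boundaries and in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CodingFormatError,
    CodingParseError,
    ContractError,
    IntegrityError,
)

logger = logging.getLogger(__name__)

#: The six CHANGE content variables, coded separately for each valence.
CONTENT_VARIABLES = (
    "view_self",
    "hope",
    "relationships",
    "emotion",
    "behavior",
    "somatic",
)

#: Cognitive-triad variables averaged into the cognitive node.
COGNITIVE_VARIABLES = ("view_self", "hope", "relationships")

VALENCES = ("pos", "neg")

#: All 13 rating columns: {pos,neg} x 6 content variables, plus processing.
VARIABLE_KEYS = tuple(
    f"{v}_{c}" for v in VALENCES for c in CONTENT_VARIABLES
) + ("processing",)

KEY_COLUMNS = ("patient_id", "session_number", "coder_id")
CODING_COLUMNS = KEY_COLUMNS + VARIABLE_KEYS
OUTCOME_COLUMNS = ("patient_id", "scid_pre", "scid_post", "assessment_session")

VALID_RATINGS = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class SessionCoding:
    """One coder's ordinal ratings for one patient-session."""

    patient_id: str
    session_number: int
    coder_id: str
    ratings: Mapping[str, float]  # variable key -> {0,1,2,3} or NaN

    def __post_init__(self) -> None:
        missing = set(VARIABLE_KEYS) - set(self.ratings)
        if missing:
            raise ContractError(f"ratings missing keys: {sorted(missing)}")
        for key, value in self.ratings.items():
            if not np.isnan(value) and value not in VALID_RATINGS:
                raise ContractError(f"rating {key}={value} not in {{0,1,2,3}}")


@dataclass(frozen=True)
class AveragedCoding:
    """Coder-averaged ratings for one patient-session."""

    patient_id: str
    session_number: int
    ratings: Mapping[str, float]  # variable key -> [0, 3] or NaN
    n_coders: int = 1


@dataclass(frozen=True)
class OutcomeRecord:
    """Pre/post personality-disorder symptom sums for one patient."""

    patient_id: str
    scid_pre: int
    scid_post: int
    assessment_session: int = 34

    def __post_init__(self) -> None:
        if self.scid_pre < 0 or self.scid_post < 0:
            raise ContractError("SCID-II dimensional scores must be >= 0")
        if self.assessment_session < 1:
            raise ContractError("assessment_session must be >= 1")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; callers decide how to react."""

    violations: list[dict] = field(default_factory=list)
    coverage: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, patient_id, kind: str, detail: str) -> None:
        self.violations.append(
            {"patient_id": patient_id, "kind": kind, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.violations, columns=["patient_id", "kind", "detail"]
        )


# ---------------------------------------------------------------------------
# readers / writers


def _parse_rating_column(series: pd.Series, column: str) -> pd.Series:
    """Parse one rating column to float with NaN for missing cells."""
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    bad |= out.notna() & ~out.isin(list(VALID_RATINGS))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CodingParseError(
            f"non-ordinal value {series.iloc[row]!r} in column {column!r}, "
            f"data row {row}"
        )
    return out.astype(float)


def read_codings(path: str | Path, dialect: Mapping | None = None) -> pd.DataFrame:
    """Read a long-format coded-session CSV.

    Parameters
    ----------
    path
        CSV file with header columns ``patient_id, session_number, coder_id``
        plus the 13 CHANGE variable columns.
    dialect
        Optional overrides passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).

    Returns
    -------
    DataFrame with the canonical columns, one row per input row, row order
    preserved.  Missing ratings are NaN.
    """
    kwargs = {"sep": ",", "encoding": "utf-8"}
    if dialect:
        kwargs.update(dialect)
    df = pd.read_csv(path, dtype={"patient_id": str, "coder_id": str}, **kwargs)
    missing = [c for c in CODING_COLUMNS if c not in df.columns]
    if missing:
        raise CodingFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(CODING_COLUMNS)].copy()
    sess = pd.to_numeric(df["session_number"], errors="coerce")
    if sess.isna().any() or (sess < 1).any() or (sess != sess.round()).any():
        raise CodingParseError(f"{path}: session_number must be a positive integer")
    df["session_number"] = sess.astype(int)
    for col in VARIABLE_KEYS:
        df[col] = _parse_rating_column(df[col], col)
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        full_dup = df.duplicated(keep=False)
        if (dup & ~full_dup).any():
            keys = df.loc[dup & ~full_dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise IntegrityError(
                f"conflicting duplicate rows for (patient, session, coder) = {keys}"
            )
        df = df.drop_duplicates(subset=list(KEY_COLUMNS)).reset_index(drop=True)
    return df


def write_codings(df: pd.DataFrame, path: str | Path) -> None:
    """Write a codings table in the canonical CSV dialect (UTF-8, '.')."""
    out = df.loc[:, list(CODING_COLUMNS)].copy()
    for col in VARIABLE_KEYS:
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, index=False, encoding="utf-8")


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read the patient outcome CSV (SCID-II pre/post dimensional sums)."""
    df = pd.read_csv(path, dtype={"patient_id": str}, encoding="utf-8")
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise CodingFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(OUTCOME_COLUMNS)].copy()
    for col in ("scid_pre", "scid_post", "assessment_session"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise CodingParseError(f"{path}: non-numeric value in {col}")
        df[col] = vals.astype(int)
    if (df[["scid_pre", "scid_post"]].to_numpy() < 0).any():
        raise CodingParseError(f"{path}: negative SCID-II score")
    return df


def write_outcomes(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(OUTCOME_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# records <-> frame


def codings_to_records(df: pd.DataFrame) -> list[SessionCoding]:
    return [
        SessionCoding(
            patient_id=row.patient_id,
            session_number=int(row.session_number),
            coder_id=row.coder_id,
            ratings={k: getattr(row, k) for k in VARIABLE_KEYS},
        )
        for row in df.itertuples(index=False)
    ]


def records_to_frame(records: Iterable[SessionCoding]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "session_number": r.session_number,
            "coder_id": r.coder_id,
            **{k: r.ratings[k] for k in VARIABLE_KEYS},
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CODING_COLUMNS))


# ---------------------------------------------------------------------------
# coder averaging


def average_coders(codings: pd.DataFrame | Iterable[SessionCoding]) -> pd.DataFrame:
    """Average ratings across coders for each (patient, session).

    Per variable the arithmetic mean of the coders that rated it; a value is
    NaN only if no coder rated it.  Sessions with a single coder pass
    through unchanged.  The result carries ``n_coders`` per session.

    Raises
    ------
    IntegrityError
        if the same (patient, session, coder) appears with conflicting
        ratings.
    """
    if not isinstance(codings, pd.DataFrame):
        codings = records_to_frame(codings)
    dup = codings.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any() and (dup & ~codings.duplicated(keep=False)).any():
        raise IntegrityError("conflicting duplicate coder rows")
    df = codings.drop_duplicates(subset=list(KEY_COLUMNS))
    grouped = df.groupby(["patient_id", "session_number"], sort=True)
    out = grouped[list(VARIABLE_KEYS)].mean()
    out["n_coders"] = grouped["coder_id"].nunique()
    return out.reset_index()


def averaged_to_records(df: pd.DataFrame) -> list[AveragedCoding]:
    return [
        AveragedCoding(
            patient_id=row.patient_id,
            session_number=int(row.session_number),
            ratings={k: getattr(row, k) for k in VARIABLE_KEYS},
            n_coders=int(row.n_coders),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# validation


def validate_dataset(
    codings: pd.DataFrame,
    outcomes: pd.DataFrame,
    schedule=None,
) -> ValidationReport:
    """Check coverage and value ranges; never mutates its inputs.

    A patient is analyzable only with >= 1 coded session per phase, a
    baseline coding, a post-window coding and pre/post outcome values.
    """
    from .phase_analysis import PhaseSchedule

    schedule = schedule or PhaseSchedule()
    report = ValidationReport()

    ratings = codings.loc[:, list(VARIABLE_KEYS)]
    valid = ratings.isna() | ratings.isin(list(VALID_RATINGS))
    if not valid.all().all():
        bad = np.argwhere(~valid.to_numpy())
        for i, j in bad:
            report.add(
                codings["patient_id"].iloc[i],
                "out_of_range",
                f"{valid.columns[j]}={ratings.iat[i, j]} at data row {i}",
            )

    cov_rows = []
    outcome_ids = set(outcomes["patient_id"])
    for pid, grp in codings.groupby("patient_id"):
        sessions = set(grp["session_number"])
        p1 = {s for s in sessions if schedule.phase1[0] <= s <= schedule.phase1[1]}
        p2 = {s for s in sessions if schedule.phase2[0] <= s <= schedule.phase2[1]}
        cov_rows.append(
            {
                "patient_id": pid,
                "n_sessions": len(sessions),
                "n_phase1": len(p1),
                "n_phase2": len(p2),
                "has_baseline": schedule.baseline_session in sessions,
            }
        )
        if schedule.baseline_session not in sessions:
            report.add(pid, "missing_baseline", "no baseline session coded")
        if not p1 - {schedule.baseline_session}:
            report.add(pid, "insufficient_phase_coverage", "no phase-1 sessions")
        if not p2:
            report.add(pid, "insufficient_phase_coverage", "no phase-2 sessions")
        if pid not in outcome_ids:
            report.add(pid, "missing_outcome", "no pre/post outcome record")
    for pid in outcome_ids - set(codings["patient_id"]):
        report.add(pid, "missing_codings", "outcome record without coded sessions")
    report.coverage = pd.DataFrame(
        cov_rows,
        columns=["patient_id", "n_sessions", "n_phase1", "n_phase2", "has_baseline"],
    )
    return report


# ---------------------------------------------------------------------------
# GridWare-style trajectory export


def export_trajectories(
    trajectories: Mapping[tuple, Sequence[tuple]],
    directory: str | Path,
) -> list[Path]:
    """Write tab-delimited trajectory files, one per patient-phase.

    ``trajectories`` maps ``(patient_id, phase_label)`` to an ordered list of
    ``(onset, x, y)`` tuples where onset is the session number, x the
    positive and y the negative activation score (both in 0..4).  The layout
    (an Onset column followed by one column per grid dimension) follows the
    GridWare trajectory dialect.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (patient_id, phase), points in trajectories.items():
        for onset, x, y in points:
            if not (0 <= x <= 4 and 0 <= y <= 4):
                raise ContractError(
                    f"activation point ({x}, {y}) outside the 5x5 grid "
                    f"for patient {patient_id!r} phase {phase!r}"
                )
        path = directory / f"{patient_id}_{phase}.trj"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Onset\tpos_activation\tneg_activation\n")
            for onset, x, y in points:
                fh.write(f"{onset}\t{int(x)}\t{int(y)}\n")
        if not points:
            logger.warning(
                "empty trajectory for patient %s phase %s", patient_id, phase
            )
        written.append(path)
    return sorted(written)


def read_trajectory(path: str | Path) -> list[tuple[int, int, int]]:
    """Read back one exported trajectory file (round-trip of the export)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["Onset", "pos_activation", "neg_activation"]:
            raise CodingFormatError(f"{path}: unexpected trajectory header {header}")
        for line in fh:
            onset, x, y = line.rstrip("\n").split("\t")
            out.append((int(onset), int(x), int(y)))
    return out
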