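"""Pattern scoring: node construction, strength (0-12), activation (0-4).

Each valence (positive / negative) of a session is summarized by four node
scores: a *cognitive* node (mean of View of Self, Hope, Relationships),
plus the Emotion, Behavior and Somatic ratings taken directly.  From the
nodes two independent summaries are derived:

* **pattern strength** — the sum of the four node scores, range 0-12; an
  overall intensity measure used at baseline and posttreatment.
* **pattern activation** — the number of nodes rated at a moderate-to-high
  level (>= 2 by default), range 0-4; a breadth measure, and the session's
  coordinate on the state-space grid.

By default the activation threshold is applied to the node score after
coder averaging (and, for the cognitive node, after the three-variable
mean); ``cognitive_mode="per-variable"`` instead declares the cognitive
node activated when a majority (>= 2 of 3) of its source variables reach
the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding_io import (
    COGNITIVE_VARIABLES,
    CONTENT_VARIABLES,
    AveragedCoding,
)
from .errors import ContractError, MissingNodeError

NODES = ("cognitive", "emotion", "behavior", "somatic")

#: moderate-to-high floor on the 0-3 rating scale
DEFAULT_THRESHOLD = 2.0

COGNITIVE_MODES = ("node-mean", "per-variable")


@dataclass(frozen=True)
class NodeScores:
    """The four node values for one valence of one session.

    A node is ``None`` when it could not be computed from the coded data
    (missing ratings); downstream summaries refuse to silently rescale.
    """

    valence: str
    cognitive: float | None
    emotion: float | None
    behavior: float | None
    somatic: float | None

    def __post_init__(self) -> None:
        for node in NODES:
            value = getattr(self, node)
            if value is not None and not 0.0 <= value <= 3.0:
                raise ContractError(f"node {node}={value} outside [0, 3]")

    @property
    def values(self) -> tuple:
        return tuple(getattr(self, n) for n in NODES)

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values)


@dataclass(frozen=True)
class PatternProfile:
    """Strength and activation for one valence of one session."""

    valence: str
    strength: float | None
    activation: int | None
    threshold: float = DEFAULT_THRESHOLD

    @property
    def complete(self) -> bool:
        return self.strength is not None and self.activation is not None


def node_scores(coding: AveragedCoding, valence: str) -> NodeScores:
    """Build the four node scores for one valence from averaged ratings.

    The cognitive node is the mean of the available cognitive-triad
    variables and is missing only when all three are missing; the other
    nodes copy their single source rating.
    """
    if valence not in ("pos", "neg"):
        raise ContractError(f"valence must be 'pos' or 'neg', got {valence!r}")
    r = coding.ratings
    cog_vals = [
        r[f"{valence}_{v}"]
        for v in COGNITIVE_VARIABLES
        if not _isnan(r[f"{valence}_{v}"])
    ]
    cognitive = float(np.mean(cog_vals)) if cog_vals else None

    def direct(name: str) -> float | None:
        v = r[f"{valence}_{name}"]
        return None if _isnan(v) else float(v)

    return NodeScores(
        valence=valence,
        cognitive=cognitive,
        emotion=direct("emotion"),
        behavior=direct("behavior"),
        somatic=direct("somatic"),
    )


def pattern_strength(nodes: NodeScores) -> float:
    """Sum of the four node scores (range 0-12)."""
    if not nodes.complete:
        missing = [n for n in NODES if getattr(nodes, n) is None]
        raise MissingNodeError(
            f"strength incomputable: missing node(s) {missing} "
            f"({nodes.valence} pattern)"
        )
    return float(sum(nodes.values))


def activation_score(nodes: NodeScores, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Count of nodes at or above the moderate-to-high threshold (0-4)."""
    if not nodes.complete:
        missing = [n for n in NODES if getattr(nodes, n) is None]
        raise MissingNodeError(
            f"activation incomputable: missing node(s) {missing} "
            f"({nodes.valence} pattern)"
        )
    return int(sum(v >= threshold for v in nodes.values))


def session_profiles(
    coding: AveragedCoding,
    threshold: float = DEFAULT_THRESHOLD,
    cognitive_mode: str = "node-mean",
) -> tuple[PatternProfile, PatternProfile]:
    """Positive and negative :class:`PatternProfile` for one session.

    Incomputable components are returned as ``None`` fields rather than
    raising, so callers can apply their own missing-data policy.
    """
    if cognitive_mode not in COGNITIVE_MODES:
        raise ContractError(f"cognitive_mode must be one of {COGNITIVE_MODES}")
    profiles = []
    for valence in ("pos", "neg"):
        nodes = node_scores(coding, valence)
        strength = float(sum(nodes.values)) if nodes.complete else None
        activation = None
        if nodes.complete:
            if cognitive_mode == "node-mean":
                activation = activation_score(nodes, threshold)
            else:
                cog_hits = sum(
                    not _isnan(coding.ratings[f"{valence}_{v}"])
                    and coding.ratings[f"{valence}_{v}"] >= threshold
                    for v in COGNITIVE_VARIABLES
                )
                activation = int(cog_hits >= 2) + sum(
                    getattr(nodes, n) >= threshold
                    for n in ("emotion", "behavior", "somatic")
                )
        profiles.append(
            PatternProfile(
                valence=valence,
                strength=strength,
                activation=activation,
                threshold=threshold,
            )
        )
    return profiles[0], profiles[1]


def profiles_frame(
    averaged: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    cognitive_mode: str = "node-mean",
) -> pd.DataFrame:
    """Vectorized per-session profiles for a whole averaged dataset.

    Returns one row per (patient, session) with columns
    ``pos_strength, pos_activation, neg_strength, neg_activation,
    processing``.  Activation columns are floats with NaN where a node is
    missing (so the frame can represent incomputable sessions).
    """
    if cognitive_mode not in COGNITIVE_MODES:
        raise ContractError(f"cognitive_mode must be one of {COGNITIVE_MODES}")
    out = averaged.loc[:, ["patient_id", "session_number"]].copy()
    for valence in ("pos", "neg"):
        cog_src = averaged[[f"{valence}_{v}" for v in COGNITIVE_VARIABLES]]
        cognitive = cog_src.mean(axis=1)  # mean of available sources
        nodes = pd.DataFrame(
            {
                "cognitive": cognitive,
                "emotion": averaged[f"{valence}_emotion"],
                "behavior": averaged[f"{valence}_behavior"],
                "somatic": averaged[f"{valence}_somatic"],
            }
        )
        complete = nodes.notna().all(axis=1)
        strength = nodes.sum(axis=1).where(complete)
        if cognitive_mode == "node-mean":
            activation = (nodes >= threshold).sum(axis=1).where(complete)
        else:
            cog_active = (cog_src >= threshold).sum(axis=1) >= 2
            rest = (
                nodes[["emotion", "behavior", "somatic"]] >= threshold
            ).sum(axis=1)
            activation = (cog_active.astype(int) + rest).where(complete)
        out[f"{valence}_strength"] = strength
        out[f"{valence}_activation"] = activation
    out["processing"] = averaged["processing"].to_numpy()
    return out


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))
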