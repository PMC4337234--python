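"""Synthetic coded-session cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised (and its parameter recovery
checked) without any real session tapes:

* per patient, a latent two-state Markov chain flickers between a
  negative-dominant and a positive-dominant pattern (attractor), with a
  patient- and phase-specific switching rate;
* each coded session emits the 13 ordinal CHANGE ratings by adding noise
  around the active state's per-valence means, then two coders add
  independent noise and re-discretize to {0..3};
* emotional processing rises toward a patient-specific phase-2 peak;
* outcomes follow a planted linear model on the *realized* (measured)
  predictors: standardized post score = b1*z(pre) + b2*z(dispersion 2)
  + b3*z(peak processing 2) + residual.  SCID-II post is drawn directly;
  the pattern-strength outcomes are encoded into the post session's
  ratings so the pipeline measures them the same way it measures real
  data.

Because the planted coefficients act on the measured predictors, recovery
error in the analysis reflects only the planted residual plus ordinal
discretization - which is exactly what a pipeline-correctness check needs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pattern_engine, phase_analysis
from .coding_io import (
    CODING_COLUMNS,
    COGNITIVE_VARIABLES,
    CONTENT_VARIABLES,
    average_coders,
)
from .errors import ContractError

CODER_POOL = ("A", "B", "C", "D")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and generative parameters; defaults mirror the trial.

    Sessions are coded every other session in 1-10 and every fourth in
    11-34, with session 1 (baseline) and session 34 (posttreatment) always
    coded; other tapes are independently unavailable with probability
    ``tape_missing_prob`` (at least one non-anchor tape per phase is kept
    so every patient is analyzable).
    """

    n_patients: int = 27
    seed: int = 0
    #: switching-rate ranges (min, max) for the two-state chain, per phase
    switch_rate1_range: tuple[float, float] = (0.10, 0.60)
    switch_rate2_range: tuple[float, float] = (0.10, 0.60)
    tape_missing_prob: float = 0.18
    #: emission means on the 0-3 rating scale, per (state, valence):
    #: in the negative-dominant state negative variables run moderate-high
    neg_state_means: tuple[float, float] = (2.2, 0.6)  # (neg vars, pos vars)
    pos_state_means: tuple[float, float] = (0.8, 2.1)
    emission_sd: float = 0.40
    #: per-coder rating noise; the default is calibrated so the two-coder
    #: ICC on the discretized ratings lands near icc_target
    coder_noise_sd: float = 0.33
    icc_target: float = 0.80
    #: processing ramp: phase-1 level and phase-2 peak (patient-specific)
    proc_phase1_mean: float = 1.2
    proc_phase1_sd: float = 0.4
    proc_peak_mean: float = 2.2
    proc_peak_sd: float = 0.45
    proc_emission_sd: float = 0.35
    #: planted standardized coefficients (pre, dispersion 2, processing 2)
    scid_betas: tuple[float, float, float] = (0.24, -0.35, -0.45)
    pos_betas: tuple[float, float, float] = (0.25, 0.39, 0.46)
    neg_betas: tuple[float, float, float] = (0.16, -0.27, -0.10)
    #: outcome score mappings: post = center + scale * z, clipped to range.
    #: Centers sit mid-range so the clip is rarely active and the planted
    #: model stays effectively linear on the score scale.
    scid_pre_mean: float = 10.82
    scid_pre_sd: float = 2.18
    scid_range: tuple[int, int] = (0, 16)
    scid_post_center: float = 8.0
    scid_post_scale: float = 3.0
    strength_post_center: float = 5.5
    strength_post_scale: float = 2.5

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ContractError("n_patients must be >= 2")
        for lo, hi in (self.switch_rate1_range, self.switch_rate2_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ContractError("switching-rate ranges must lie in [0, 1]")
        if not 0.0 <= self.tape_missing_prob < 1.0:
            raise ContractError("tape_missing_prob must lie in [0, 1)")
        for m in (*self.neg_state_means, *self.pos_state_means):
            if not 0.0 <= m <= 3.0:
                raise ContractError(f"emission mean {m} outside the 0-3 scale")
        for sd in (self.emission_sd, self.coder_noise_sd, self.proc_emission_sd):
            if sd < 0:
                raise ContractError("noise SDs must be non-negative")

    def with_null_effects(self) -> "SyntheticConfig":
        """Copy with zero planted process effects (pre coupling retained)."""
        return dataclasses.replace(
            self,
            scid_betas=(self.scid_betas[0], 0.0, 0.0),
            pos_betas=(self.pos_betas[0], 0.0, 0.0),
            neg_betas=(self.neg_betas[0], 0.0, 0.0),
        )

    def coded_sessions(self) -> tuple[list[int], list[int], int, int]:
        """(phase-1 non-anchor, phase-2 non-anchor, baseline, post)."""
        return [3, 5, 7, 9], [11, 15, 19, 23, 27, 31], 1, 34


@dataclass
class GroundTruth:
    """Latent quantities emitted alongside the data, never consumed by it."""

    config: SyntheticConfig
    planted: dict
    switch_rates: pd.DataFrame  # patient_id, rate1, rate2
    states: dict  # patient_id -> {session: "N"|"P"}
    measured: pd.DataFrame  # realized predictors the outcomes were built on
    residuals: pd.DataFrame  # standardized residual draws per outcome

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "planted": self.planted,
            "switch_rates": self.switch_rates.to_dict(orient="records"),
            "states": self.states,
            "measured": self.measured.to_dict(orient="records"),
            "residuals": self.residuals.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _discretize(values: np.ndarray) -> np.ndarray:
    """Round to the nearest ordinal rating in {0..3} after truncation."""
    return np.clip(np.rint(values), 0, 3)


def _emit_ratings(rng, true_values: np.ndarray, coder_sd: float) -> np.ndarray:
    """Two coders' discretized ratings for a vector of true values."""
    noise = rng.normal(0.0, coder_sd, size=(2,) + true_values.shape)
    return _discretize(true_values[None, :] + noise)


def _proc_mean(session: int, level1: float, peak: float, peak_session: int) -> float:
    """Processing ramp: flat in phase 1, rising to the phase-2 peak, easing off."""
    if session <= 10:
        return level1
    if session <= peak_session:
        frac = (session - 10) / max(peak_session - 10, 1)
        return level1 + frac * (peak - level1)
    return peak - 0.05 * (session - peak_session)


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (codings, outcomes, ground truth) for one cohort.

    Bit-identical for a fixed config (a per-patient seed sequence is spawned
    from the global seed, so patient i's data does not depend on
    ``n_patients``).
    """
    config = config or SyntheticConfig()
    config.validate()
    p1_extra, p2_extra, baseline, post = config.coded_sessions()
    neg_mean = {"N": config.neg_state_means[0], "P": config.pos_state_means[0]}
    pos_mean = {"N": config.neg_state_means[1], "P": config.pos_state_means[1]}

    rows: list[dict] = []
    truth_states: dict = {}
    rates, resid_rows, patient_meta = [], [], []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i + 1:04d}"
        # correlated per-phase switching rates (shared patient propensity)
        u = rng.uniform()
        u1 = float(np.clip(0.7 * u + 0.3 * rng.uniform(), 0.0, 1.0))
        u2 = float(np.clip(0.7 * u + 0.3 * rng.uniform(), 0.0, 1.0))
        lo1, hi1 = config.switch_rate1_range
        lo2, hi2 = config.switch_rate2_range
        rate1 = lo1 + u1 * (hi1 - lo1)
        rate2 = lo2 + u2 * (hi2 - lo2)

        # tape availability (anchors always audible; >=1 extra per phase)
        def keep(extras: list[int]) -> list[int]:
            kept = [s for s in extras if rng.uniform() >= config.tape_missing_prob]
            if not kept:
                kept = [extras[int(rng.integers(len(extras)))]]
            return kept

        sessions = sorted([baseline] + keep(p1_extra) + keep(p2_extra))

        # latent chain over the coded sessions (post session handled later)
        state = "N"
        states = {baseline: state}
        for s in sessions[1:]:
            rate = rate1 if s <= 10 else rate2
            if rng.uniform() < rate:
                state = "P" if state == "N" else "N"
            states[s] = state
        truth_states[pid] = states

        level1 = float(np.clip(
            rng.normal(config.proc_phase1_mean, config.proc_phase1_sd), 0.0, 3.0
        ))
        peak = float(np.clip(
            rng.normal(config.proc_peak_mean, config.proc_peak_sd), 0.0, 3.0
        ))
        peak_session = int(rng.choice([15, 19, 23], p=[0.5, 0.3, 0.2]))

        coders = [
            sorted(rng.choice(CODER_POOL, size=2, replace=False))
            for _ in range(len(sessions) + 1)
        ]
        for k, s in enumerate(sessions):
            st = states[s]
            true_neg = np.clip(
                neg_mean[st] + rng.normal(0.0, config.emission_sd, 6), 0.0, 3.0
            )
            true_pos = np.clip(
                pos_mean[st] + rng.normal(0.0, config.emission_sd, 6), 0.0, 3.0
            )
            true_proc = np.clip(
                _proc_mean(s, level1, peak, peak_session)
                + rng.normal(0.0, config.proc_emission_sd),
                0.0, 3.0,
            )
            true = np.concatenate([true_pos, true_neg, [true_proc]])
            ratings = _emit_ratings(rng, true, config.coder_noise_sd)
            for c in range(2):
                rows.append(
                    _coding_row(pid, s, coders[k][c], ratings[c])
                )

        # pre-drawn randomness for the outcome pass (keeps per-patient
        # reproducibility independent of cohort-level measurement)
        resid_rows.append(
            {
                "patient_id": pid,
                "eps_scid": rng.normal(),
                "eps_pos": rng.normal(),
                "eps_neg": rng.normal(),
            }
        )
        scid_pre = int(np.clip(
            np.rint(rng.normal(config.scid_pre_mean, config.scid_pre_sd)),
            *config.scid_range,
        ))
        post_jitter = rng.normal(0.0, 0.15, size=12)
        post_coder_noise = rng.normal(
            0.0, config.coder_noise_sd, size=(2, 13)
        )
        patient_meta.append(
            {
                "patient_id": pid,
                "scid_pre": scid_pre,
                "post_coders": coders[-1],
                "post_jitter": post_jitter,
                "post_coder_noise": post_coder_noise,
                "proc_at_post": _proc_mean(post, level1, peak, peak_session),
            }
        )
        rates.append({"patient_id": pid, "rate1": rate1, "rate2": rate2})

    codings = pd.DataFrame(rows, columns=list(CODING_COLUMNS))

    # ---- pass B: measure realized predictors, plant the outcome models ----
    schedule = phase_analysis.PhaseSchedule()
    averaged = average_coders(codings)
    profiles = pattern_engine.profiles_frame(averaged)
    measured_rows = []
    for pid, grp in profiles.groupby("patient_id", sort=True):
        ends = phase_analysis.endpoint_strengths(grp, schedule)
        pts = phase_analysis.phase_points(grp, schedule, post_session=post)
        peak1, _ = phase_analysis.peak_processing(pts["proc1"])
        peak2, _ = phase_analysis.peak_processing(pts["proc2"])
        measured_rows.append(
            {
                "patient_id": pid,
                "pos_pre": ends["pos_strength_pre"],
                "neg_pre": ends["neg_strength_pre"],
                "dispersion1": phase_analysis._phase_dispersion(pts["phase1"]),
                "dispersion2": phase_analysis._phase_dispersion(pts["phase2"]),
                "peak_processing1": peak1,
                "peak_processing2": peak2,
            }
        )
    measured = pd.DataFrame(measured_rows).sort_values("patient_id")
    meta = pd.DataFrame(patient_meta).sort_values("patient_id")
    resid = pd.DataFrame(resid_rows).sort_values("patient_id")
    measured = measured.merge(
        meta[["patient_id", "scid_pre"]], on="patient_id"
    )

    def zscore(x: pd.Series) -> np.ndarray:
        x = x.to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_disp = zscore(measured["dispersion2"])
    z_proc = zscore(measured["peak_processing2"])
    planted = {
        "scid": list(config.scid_betas),
        "pos": list(config.pos_betas),
        "neg": list(config.neg_betas),
    }

    def plant(betas, z_pre, eps) -> np.ndarray:
        b = np.asarray(betas, dtype=float)
        Z = np.column_stack([z_pre, z_disp, z_proc])
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(Z, rowvar=False)
        R = np.nan_to_num(R)  # constant predictors contribute no variance
        np.fill_diagonal(R, 1.0)
        r2 = float(b @ R @ b)
        s = np.sqrt(max(1.0 - r2, 0.05))
        return Z @ b + s * eps

    zy_scid = plant(config.scid_betas, zscore(measured["scid_pre"]),
                    resid["eps_scid"].to_numpy())
    zy_pos = plant(config.pos_betas, zscore(measured["pos_pre"]),
                   resid["eps_pos"].to_numpy())
    zy_neg = plant(config.neg_betas, zscore(measured["neg_pre"]),
                   resid["eps_neg"].to_numpy())

    scid_post = np.clip(
        np.rint(config.scid_post_center + config.scid_post_scale * zy_scid),
        *config.scid_range,
    ).astype(int)
    pos_target = np.clip(
        config.strength_post_center + config.strength_post_scale * zy_pos, 0.0, 12.0
    )
    neg_target = np.clip(
        config.strength_post_center + config.strength_post_scale * zy_neg, 0.0, 12.0
    )

    # post-session codings encode the target strengths
    for idx, rec in enumerate(meta.itertuples(index=False)):
        true_pos = np.clip(
            pos_target[idx] / 4.0 + rec.post_jitter[:6], 0.0, 3.0
        )
        true_neg = np.clip(
            neg_target[idx] / 4.0 + rec.post_jitter[6:], 0.0, 3.0
        )
        true_proc = np.clip(rec.proc_at_post, 0.0, 3.0)
        true = np.concatenate([true_pos, true_neg, [true_proc]])
        ratings = _discretize(true[None, :] + rec.post_coder_noise)
        for c in range(2):
            rows.append(_coding_row(rec.patient_id, post, rec.post_coders[c],
                                    ratings[c]))

    codings = (
        pd.DataFrame(rows, columns=list(CODING_COLUMNS))
        .sort_values(["patient_id", "session_number", "coder_id"], kind="stable")
        .reset_index(drop=True)
    )
    outcomes = pd.DataFrame(
        {
            "patient_id": measured["patient_id"],
            "scid_pre": measured["scid_pre"].astype(int),
            "scid_post": scid_post,
            "assessment_session": post,
        }
    ).reset_index(drop=True)
    measured = measured.assign(
        scid_post=scid_post,
        pos_post_target=pos_target,
        neg_post_target=neg_target,
    ).reset_index(drop=True)
    truth = GroundTruth(
        config=config,
        planted=planted,
        switch_rates=pd.DataFrame(rates),
        states=truth_states,
        measured=measured,
        residuals=resid.reset_index(drop=True),
    )
    return codings, outcomes, truth


def _coding_row(pid: str, session: int, coder: str, ratings: np.ndarray) -> dict:
    row = {"patient_id": pid, "session_number": session, "coder_id": str(coder)}
    keys = (
        [f"pos_{c}" for c in CONTENT_VARIABLES]
        + [f"neg_{c}" for c in CONTENT_VARIABLES]
        + ["processing"]
    )
    row.update({k: float(v) for k, v in zip(keys, ratings)})
    return row


def sweep_switching_rate(
    config: SyntheticConfig,
    rates: Sequence[float],
    n_patients: int = 200,
) -> pd.DataFrame:
    """Mean phase-2 dispersion as a function of the switching rate.

    For each rate a cohort is generated with both phases' switching rates
    pinned to it; output is sorted by rate.  Operationalizes "flickering":
    faster alternation between the two attractors spreads sessions over
    more grid cells.
    """
    out = []
    for rate in sorted(rates):
        if not 0.0 <= rate <= 1.0:
            raise ContractError(f"switching rate {rate} outside [0, 1]")
        cfg = dataclasses.replace(
            config,
            n_patients=n_patients,
            switch_rate1_range=(rate, rate),
            switch_rate2_range=(rate, rate),
        )
        _, _, truth = generate_cohort(cfg)
        out.append(
            {
                "rate": rate,
                "mean_dispersion2": float(truth.measured["dispersion2"].mean()),
            }
        )
    return pd.DataFrame(out)
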