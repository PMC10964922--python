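"""Synthetic headturn-preference looking-time data.

The generator mirrors the analysis model: for each test trial of a
participant, log looking time is a nested sum-contrast linear predictor
(grand intercept; a between-participant language effect; and, within each
language group, phonotactics, pronunciation, block, phonotactics ×
pronunciation and phonotactics × block effects) plus a participant random
intercept, a participant random slope on the pronunciation code, and a
residual. Looking time is the exponential of that value, clipped to the
trial mechanics' bounds (a floor for the shortest codable look and the 18 s
list length as ceiling). Warm-up trials draw from a separate nuisance
distribution; an optional per-trial stopping hazard after a protected
prefix truncates participants' trial sequences, emulating dropout.

Default fixed effects are the published estimates of the study the
simulator emulates; default variance components are calibration constants
(the study does not report them) chosen so raw condition summaries land in
a realistic range.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contrasts import DEFAULT_CODEBOOK, Codebook, code
from .errors import SimulationError
from .stimuli import ExperimentVersion, default_versions

LANGUAGES = ("French", "German")


@dataclass
class FixedEffects:
    """Generating coefficients on the ±1 contrast scale (log-seconds)."""

    intercept: float = 1.75
    language: float = 0.03
    phonotactics: dict[str, float] = field(
        default_factory=lambda: {"French": -0.07, "German": -0.03}
    )
    pronunciation: dict[str, float] = field(
        default_factory=lambda: {"French": 0.02, "German": 0.02}
    )
    block: dict[str, float] = field(default_factory=lambda: {"French": -0.23, "German": -0.09})
    phonotactics_x_pronunciation: dict[str, float] = field(
        default_factory=lambda: {"French": -0.04, "German": -0.04}
    )
    phonotactics_x_block: dict[str, float] = field(
        default_factory=lambda: {"French": -0.01, "German": 0.02}
    )


@dataclass
class RandomEffects:
    """Participant-level variance components on the log-LT scale.

    Calibration constants, not published values: intercept and
    pronunciation-slope standard deviations, their correlation, and the
    residual standard deviation.
    """

    intercept_sd: float = 0.15
    pronunciation_slope_sd: float = 0.05
    correlation: float = 0.0
    residual_sd: float = 0.35


@dataclass
class DropoutModel:
    """Geometric stopping: after each completed trial past ``start_after``,
    the participant quits with probability ``hazard``."""

    hazard: float = 0.013
    start_after: int = 14


@dataclass
class SimParams:
    n_per_group: int = 24
    fixed: FixedEffects = field(default_factory=FixedEffects)
    random: RandomEffects = field(default_factory=RandomEffects)
    lt_bounds: tuple[float, float] = (0.5, 18.0)
    dropout: DropoutModel = field(default_factory=DropoutModel)
    warmup_log_mean: float = 1.9
    warmup_log_sd: float = 0.4
    seed: int | None = 0

    def validate(self) -> None:
        r = self.random
        if self.n_per_group <= 0:
            raise SimulationError("n_per_group must be positive")
        if min(r.intercept_sd, r.pronunciation_slope_sd, r.residual_sd) < 0:
            raise SimulationError("standard deviations must be non-negative")
        if abs(r.correlation) > 1:
            raise SimulationError("|re correlation| must be <= 1")
        lo, hi = self.lt_bounds
        if not (0 < lo < hi):
            raise SimulationError("lt_bounds must satisfy 0 < floor < ceiling")
        if not 0 <= self.dropout.hazard <= 1:
            raise SimulationError("dropout hazard must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_dropout(
    trial_sequence: Sequence,
    hazard: float,
    seed: int | None = None,
    start_after: int = 14,
    rng: np.random.Generator | None = None,
) -> list:
    """Truncate a trial sequence by geometric stopping after a protected prefix.

    After each completed trial with 1-based position >= ``start_after`` the
    sequence stops with probability ``hazard`` (never mid-trial). With
    ``hazard`` 0 the sequence is returned whole; with ``hazard`` 1 it stops
    at exactly ``start_after`` trials.
    """
    if not 0 <= hazard <= 1:
        raise SimulationError("hazard must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for pos, trial in enumerate(trial_sequence, start=1):
        out.append(trial)
        if pos >= start_after and pos < len(trial_sequence):
            if rng.random() < hazard:
                break
    return out


def expected_completed_trials(hazard: float, total: int = 28, start_after: int = 14) -> float:
    """Closed-form expectation of the truncated sequence length."""
    if hazard == 0:
        return float(total)
    e = float(start_after)
    surv = 1.0
    for k in range(start_after, total):
        surv *= 1 - hazard
        e += surv
    return e


def _linear_predictor(
    fx: FixedEffects, language: str, lang_code: float, phon: float, pron: float, block: float
) -> float:
    return (
        fx.intercept
        + fx.language * lang_code
        + fx.phonotactics[language] * phon
        + fx.pronunciation[language] * pron
        + fx.block[language] * block
        + fx.phonotactics_x_pronunciation[language] * phon * pron
        + fx.phonotactics_x_block[language] * phon * block
    )


def simulate_dataset(
    params: SimParams,
    versions: Sequence[ExperimentVersion] | None = None,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> pd.DataFrame:
    """Simulate a trial-level looking-time table.

    Participants (``n_per_group`` per language) are assigned to the eight
    experiment versions round-robin within each language group. The output
    has one row per completed trial with columns: participant, language,
    block, trial_index, trial_type, pronunciation, phonotactics, side,
    looking_time (seconds). Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if versions is None:
        versions = default_versions(seed=int(rng.integers(2**31)))
    if len(versions) == 0:
        raise SimulationError("no experiment versions supplied")
    r = params.random
    cov = np.array(
        [
            [r.intercept_sd**2, r.correlation * r.intercept_sd * r.pronunciation_slope_sd],
            [r.correlation * r.intercept_sd * r.pronunciation_slope_sd, r.pronunciation_slope_sd**2],
        ]
    )
    lo, hi = params.lt_bounds
    rows = []
    for language in LANGUAGES:
        prefix = "F" if language == "French" else "G"
        for i in range(params.n_per_group):
            pid = f"{prefix}{i + 1:03d}"
            version = versions[i % len(versions)]
            u0, u1 = rng.multivariate_normal([0.0, 0.0], cov)
            trials = simulate_dropout(
                version.trials,
                params.dropout.hazard,
                start_after=params.dropout.start_after,
                rng=rng,
            )
            for t in trials:
                if t.trial_type == "warmup":
                    log_lt = rng.normal(params.warmup_log_mean, params.warmup_log_sd)
                    phon_label = None
                    pron_label = None
                else:
                    phon = code(codebook, "phonotactics", t.condition)
                    pron = code(codebook, "pronunciation", t.pronunciation)
                    blk = code(codebook, "block", t.block)
                    lang = code(codebook, "language", language)
                    log_lt = (
                        _linear_predictor(params.fixed, language, lang, phon, pron, blk)
                        + u0
                        + u1 * pron
                        + rng.normal(0.0, r.residual_sd)
                    )
                    phon_label = t.condition
                    pron_label = t.pronunciation
                lt = float(min(max(math.exp(log_lt), lo), hi))
                rows.append(
                    {
                        "participant": pid,
                        "language": language,
                        "version": version.version_id,
                        "block": t.block,
                        "trial_index": t.trial_index,
                        "trial_type": t.trial_type,
                        "pronunciation": pron_label,
                        "phonotactics": phon_label,
                        "side": t.side,
                        "looking_time": lt,
                    }
                )
    return pd.DataFrame(rows)
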