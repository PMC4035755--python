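"""Parameter recovery and power analysis for the synthetic model.

Closes the loop on the simulator: learning rates are estimated back from
trial data by least-squares regression through the origin of the update
on the absolute estimation error within each valence class (the
generative update rule has no intercept, so the origin-constrained slope
is the model-matched estimator).  Repeated generate-score-estimate cycles
quantify estimator bias and RMSE; repeated generate-score-test cycles
estimate power (or type-I error, under a null configuration) of the
valence x age interaction test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import mixed_anova_2x2
from .scoring import classify_trials, summarize_participants, VALENCE_DESIRABLE, VALENCE_UNDESIRABLE
from .simulate import SimulationConfig, generate_cohort
from dataclasses import replace

__all__ = [
    "RecoveryReport",
    "PowerReport",
    "estimate_learning_rates",
    "estimate_learning_rates_table",
    "recovery_experiment",
    "interaction_power",
]


@dataclass
class RecoveryReport:
    """Bias/RMSE of the learning-rate estimator, per valence x group."""

    parameters: dict  # name -> {"true", "mean_estimate", "bias", "rmse"}
    n_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {"n_reps": self.n_reps, "seed": self.seed, "parameters": self.parameters}


@dataclass
class PowerReport:
    """Monte-Carlo rejection rate of the interaction test."""

    rejection_rate: float
    alpha_level: float
    n_reps: int
    seed: int
    config_digest: str
    mcse: float

    def to_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "alpha_level": self.alpha_level,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "mcse": self.mcse,
        }


def _origin_slope(err_abs: np.ndarray, upd: np.ndarray) -> float:
    """Least-squares slope through the origin of update on |error|."""
    denom = float(np.sum(err_abs * err_abs))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(err_abs * upd) / denom)


def estimate_learning_rates(trials: pd.DataFrame) -> tuple[float, float]:
    """(alpha_desirable, alpha_undesirable) for ONE participant's
    classified trials; slopes are unbounded and reported as-is.

    A valence class with fewer than two nonzero-error trials yields NaN
    for its rate (the slope is not identifiable there).
    """
    out = []
    for valence in (VALENCE_DESIRABLE, VALENCE_UNDESIRABLE):
        sub = trials[trials["valence"] == valence]
        e = np.abs(sub["estimation_error"].to_numpy(float))
        u = sub["update"].to_numpy(float)
        keep = e > 0
        if keep.sum() < 2:
            out.append(float("nan"))
        else:
            out.append(_origin_slope(e[keep], u[keep]))
    return out[0], out[1]


def estimate_learning_rates_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-participant learning-rate estimates over a classified cohort."""
    rows = []
    for pid, sub in classified.groupby("participant_id", sort=True):
        a_des, a_und = estimate_learning_rates(sub)
        rows.append(
            {"participant_id": pid, "alpha_desirable": a_des, "alpha_undesirable": a_und}
        )
    return pd.DataFrame(rows)


_PARAM_NAMES = (
    "alpha_desirable_young",
    "alpha_undesirable_young",
    "alpha_desirable_older",
    "alpha_undesirable_older",
)


def recovery_experiment(
    config: SimulationConfig, n_reps: int = 200, seed: int = 0
) -> RecoveryReport:
    """Repeated generate -> score -> estimate; per-parameter bias/RMSE.

    Each replicate's estimate of a group-level learning rate is the mean
    of the per-participant origin-constrained slopes within that group
    (NaN participants excluded).
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps) % (2**31 - 1)
    estimates = {name: [] for name in _PARAM_NAMES}
    for r in range(n_reps):
        cfg = replace(config, seed=int(rep_seeds[r]))
        participants, trials = generate_cohort(cfg)
        classified = classify_trials(trials)
        est = estimate_learning_rates_table(classified).merge(
            participants[["participant_id", "age_group"]], on="participant_id"
        )
        for grp in ("young", "older"):
            sub = est[est["age_group"] == grp]
            estimates[f"alpha_desirable_{grp}"].append(
                float(np.nanmean(sub["alpha_desirable"]))
            )
            estimates[f"alpha_undesirable_{grp}"].append(
                float(np.nanmean(sub["alpha_undesirable"]))
            )
    parameters = {}
    for name in _PARAM_NAMES:
        true = getattr(config, name)
        arr = np.asarray(estimates[name])
        bias = float(arr.mean() - true)
        rmse = float(np.sqrt(np.mean((arr - true) ** 2)))
        parameters[name] = {
            "true": true,
            "mean_estimate": float(arr.mean()),
            "bias": bias,
            "rmse": rmse,
        }
    return RecoveryReport(parameters=parameters, n_reps=n_reps, seed=seed)


def _config_digest(config: SimulationConfig) -> str:
    import hashlib
    import json

    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def interaction_power(
    config: SimulationConfig,
    n_reps: int = 500,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> PowerReport:
    """Fraction of simulated cohorts where the valence x age interaction
    of the 2x2 mixed ANOVA rejects at ``alpha_level``.

    Under a null configuration (all four learning rates equal, groups
    exchangeable) this estimates the test's type-I error.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not 0.0 < alpha_level <= 1.0:
        raise ValueError("alpha_level must be in (0, 1]")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps) % (2**31 - 1)
    rejections = 0
    for r in range(n_reps):
        cfg = replace(config, seed=int(rep_seeds[r]))
        participants, trials = generate_cohort(cfg)
        summaries = summarize_participants(classify_trials(trials))
        table = summaries[summaries["valid"]].merge(
            participants[["participant_id", "age_group"]], on="participant_id"
        )
        anova = mixed_anova_2x2(table)
        if anova.interaction.p < alpha_level:
            rejections += 1
    rate = rejections / n_reps
    mcse = math.sqrt(rate * (1.0 - rate) / n_reps)
    return PowerReport(
        rejection_rate=rate,
        alpha_level=alpha_level,
        n_reps=n_reps,
        seed=seed,
        config_digest=_config_digest(config),
        mcse=mcse,
    )
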