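"""Synthetic cohorts for the belief-updating task.

The belief-updating paradigm presents a participant with an adverse life
event, collects a first probability estimate for the next five years,
shows the population base rate, and later collects a second estimate.
Trials where the first estimate exceeded the base rate deliver *desirable*
(better than expected) information; trials where it fell short deliver
*undesirable* information.  The simulator generates cohorts whose trial
data carry the statistical structure the downstream analysis assumes:
belief revision follows an asymmetric delta rule,

    update = alpha_valence * |first estimate - base rate| + noise,

with the learning rate ``alpha`` depending on the trial's valence and the
participant's age group.  A reduced undesirable-information learning rate
in the older group produces the age-modulated optimistic update bias; a
subtractive optimism shift on first estimates (larger in the older group)
produces the groups' more negative first estimation errors; and a
volume--bias slope couples dorsal anterior cingulate grey-matter volume
to the update bias in the older group only.

Nothing here fits real data: the generator exists so that scoring,
inference, ROI correlation and recovery stages are exercisable end to end
with no external download, under a seed that fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "SimulationConfig",
    "ConfigError",
    "generate_events",
    "generate_cohort",
    "paper_like_config",
    "null_config",
    "RATING_SCALES",
]

#: The five Likert rating scales collected for every event (1..6).
RATING_SCALES = ("vividness", "familiarity", "experience", "arousal", "negativity")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass(frozen=True)
class Event:
    """One adverse life event with its population base rate (percent)."""

    event_id: str
    label: str
    base_rate: float


@dataclass
class SimulationConfig:
    """Generative parameters for a simulated two-group cohort.

    All probabilities/estimates are in percent.  Learning rates are the
    slopes of the asymmetric delta rule, one per valence x age-group cell.
    The optimism shift is subtracted from the base rate when forming first
    estimates, so positive shifts mean initial *under*-estimation of the
    events' likelihood; the older group's larger default shift reproduces
    the more negative first estimation error seen in older adults.
    """

    n_young: int = 18
    n_older: int = 18
    n_events: int = 45
    base_rate_range: tuple[float, float] = (10.0, 70.0)

    # asymmetric delta-rule learning rates, by valence x age group
    alpha_desirable_young: float = 0.65
    alpha_undesirable_young: float = 0.35
    alpha_desirable_older: float = 0.65
    alpha_undesirable_older: float = 0.05

    # first-estimate bias below the base rate, per participant
    optimism_shift_mean_young: float = 4.71
    optimism_shift_mean_older: float = 12.24
    optimism_shift_sd: float = 6.0

    # trial-level noise (percent)
    estimate_noise_sd: float = 15.0
    update_noise_sd: float = 3.0
    memory_noise_sd_young: float = 8.0
    memory_noise_sd_older: float = 13.0

    # participant-level traits
    age_mean_young: float = 22.0
    age_sd_young: float = 2.29
    age_mean_older: float = 66.0
    age_sd_older: float = 5.62
    iq_mean: float = 115.0
    iq_sd: float = 10.0
    lotr_mean_young: float = 16.56
    lotr_sd_young: float = 3.26
    lotr_mean_older: float = 20.17
    lotr_sd_older: float = 2.88

    # ROI grey-matter volumes (arbitrary but consistent units)
    dorsal_volume_mean_young: float = 0.45
    dorsal_volume_sd_young: float = 0.032
    dorsal_volume_mean_older: float = 0.42
    dorsal_volume_sd_older: float = 0.036
    ventral_volume_mean_young: float = 0.54
    ventral_volume_sd_young: float = 0.037
    ventral_volume_mean_older: float = 0.49
    ventral_volume_sd_older: float = 0.036
    tiv_mean_young: float = 1.50
    tiv_mean_older: float = 1.40
    tiv_sd: float = 0.12

    #: dorsal volume units per percent of update bias, older group only
    volume_bias_slope_older: float = 0.02
    volume_bias_slope_young: float = 0.0

    #: desirable-minus-undesirable mean shift per rating scale
    rating_valence_effects: dict = field(
        default_factory=lambda: {
            "vividness": 0.8,
            "familiarity": 0.6,
            "experience": 0.8,
            "arousal": -0.5,
            "negativity": -0.6,
        }
    )
    rating_noise_sd: float = 1.0

    # reaction times: lognormal, no group or valence effect by default
    rt_log_mean: float = 0.92  # exp(0.92) ~ 2.5 s
    rt_log_sd: float = 0.30

    #: round estimates/recalls to whole percents (participants type integers)
    integer_estimates: bool = True

    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_young < 2:
            raise ConfigError("n_young must be >= 2")
        if self.n_older < 2:
            raise ConfigError("n_older must be >= 2")
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        low, high = self.base_rate_range
        if not (0.0 < low <= high < 100.0):
            raise ConfigError(
                "base_rate_range must satisfy 0 < low <= high < 100, "
                f"got {self.base_rate_range!r}"
            )
        for name in (
            "alpha_desirable_young",
            "alpha_undesirable_young",
            "alpha_desirable_older",
            "alpha_undesirable_older",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        for name in (
            "optimism_shift_sd",
            "estimate_noise_sd",
            "update_noise_sd",
            "memory_noise_sd_young",
            "memory_noise_sd_older",
            "rating_noise_sd",
            "rt_log_sd",
            "tiv_sd",
            "dorsal_volume_sd_young",
            "dorsal_volume_sd_older",
            "ventral_volume_sd_young",
            "ventral_volume_sd_older",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        missing = set(RATING_SCALES) - set(self.rating_valence_effects)
        if missing:
            raise ConfigError(
                f"rating_valence_effects missing scales: {sorted(missing)}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_rate_range"] = list(self.base_rate_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "base_rate_range" in d:
            d["base_rate_range"] = tuple(d["base_rate_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default cohort: equal desirable rates, reduced older undesirable
    rate, larger older optimism shift — the age-modulated bias pattern."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def null_config(seed: int = 0, alpha: float = 0.40, **overrides) -> SimulationConfig:
    """Cohort with no group differences in updating: all four learning
    rates equal and both groups sharing the same optimism shift.

    Under this configuration the valence x age interaction test should
    reject at its nominal level; used for type-I calibration.
    """
    cfg = SimulationConfig(
        alpha_desirable_young=alpha,
        alpha_undesirable_young=alpha,
        alpha_desirable_older=alpha,
        alpha_undesirable_older=alpha,
        optimism_shift_mean_young=8.0,
        optimism_shift_mean_older=8.0,
        volume_bias_slope_older=0.0,
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def generate_events(
    n_events: int,
    base_rate_range: Sequence[float] = (10.0, 70.0),
    seed: int = 0,
) -> list[Event]:
    """Draw ``n_events`` adverse life events with integer base rates
    uniform on ``base_rate_range`` (percent, closed interval)."""
    if n_events < 1:
        raise ConfigError(f"n_events must be >= 1, got {n_events}")
    low, high = float(base_rate_range[0]), float(base_rate_range[1])
    if not (0.0 < low <= high < 100.0):
        raise ConfigError(
            f"base_rate_range must satisfy 0 < low <= high < 100, got {base_rate_range!r}"
        )
    rng = np.random.default_rng(seed)
    rates = np.round(rng.uniform(low, high, size=n_events))
    rates = np.clip(rates, low, high)
    return [
        Event(event_id=f"ev{i:03d}", label=f"adverse event {i}", base_rate=float(r))
        for i, r in enumerate(rates)
    ]


def _alpha_matrix(cfg: SimulationConfig, is_older: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant (alpha_desirable, alpha_undesirable) vectors."""
    a_des = np.where(is_older, cfg.alpha_desirable_older, cfg.alpha_desirable_young)
    a_und = np.where(is_older, cfg.alpha_undesirable_older, cfg.alpha_undesirable_young)
    return a_des, a_und


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort.

    Returns ``(participants, trials)`` as DataFrames.  ``participants``
    has one row per participant (group, demographics, LOT-R, ROI volumes,
    TIV); ``trials`` has one row per participant x event with both
    estimates, the shown base rate, the recalled base rate, reaction
    times and the five Likert ratings.

    Generative rules: first estimate ``E1 = base - shift_i + noise``
    clipped to [1, 99]; second estimate ``E2 = E1 - alpha_v (E1 - base)
    + noise`` clipped likewise, with ``alpha_v`` the group's rate for the
    trial's valence; recall ``= base + memory noise`` clipped to [0,
    100].  In the older group dorsal volume couples linearly to the
    participant's realised update bias.  Identical config (including
    seed) gives identical output.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # deterministic sub-seed so event sets are reproducible in isolation
    event_seed = int(rng.integers(0, 2**31 - 1))
    events = generate_events(cfg.n_events, cfg.base_rate_range, seed=event_seed)
    base = np.array([e.base_rate for e in events])

    n = cfg.n_young + cfg.n_older
    is_older = np.arange(n) >= cfg.n_young
    pid = np.array([f"p{i:03d}" for i in range(n)])
    group = np.where(is_older, "older", "young")

    age = np.where(
        is_older,
        rng.normal(cfg.age_mean_older, cfg.age_sd_older, n),
        rng.normal(cfg.age_mean_young, cfg.age_sd_young, n),
    ).round(1)
    gender = np.where(rng.random(n) < 0.5, "F", "M")
    iq = rng.normal(cfg.iq_mean, cfg.iq_sd, n).round(1)
    lotr = np.where(
        is_older,
        rng.normal(cfg.lotr_mean_older, cfg.lotr_sd_older, n),
        rng.normal(cfg.lotr_mean_young, cfg.lotr_sd_young, n),
    )
    lotr = np.clip(np.round(lotr), 0, 24).astype(int)

    shift = np.where(
        is_older,
        rng.normal(cfg.optimism_shift_mean_older, cfg.optimism_shift_sd, n),
        rng.normal(cfg.optimism_shift_mean_young, cfg.optimism_shift_sd, n),
    )

    # --- trials: (n participants) x (n_events) matrices -----------------
    shape = (n, cfg.n_events)
    e1 = base[None, :] - shift[:, None] + rng.normal(0.0, cfg.estimate_noise_sd, shape)
    e1 = np.clip(e1, 1.0, 99.0)
    if cfg.integer_estimates:
        e1 = np.round(e1)

    err = e1 - base[None, :]  # signed estimation error
    a_des, a_und = _alpha_matrix(cfg, is_older)
    alpha = np.where(err > 0, a_des[:, None], np.where(err < 0, a_und[:, None], 0.0))
    e2 = e1 - alpha * err + rng.normal(0.0, cfg.update_noise_sd, shape)
    e2 = np.clip(e2, 1.0, 99.0)
    if cfg.integer_estimates:
        e2 = np.round(e2)

    mem_sd = np.where(is_older, cfg.memory_noise_sd_older, cfg.memory_noise_sd_young)
    recall = base[None, :] + rng.normal(0.0, 1.0, shape) * mem_sd[:, None]
    recall = np.clip(recall, 0.0, 100.0)
    if cfg.integer_estimates:
        recall = np.round(recall)

    rt1 = np.exp(rng.normal(cfg.rt_log_mean, cfg.rt_log_sd, shape))
    rt2 = np.exp(rng.normal(cfg.rt_log_mean, cfg.rt_log_sd, shape))

    valence_sign = np.sign(err)  # +1 desirable, -1 undesirable, 0 tie
    ratings = {}
    for scale in RATING_SCALES:
        effect = cfg.rating_valence_effects[scale]
        r = 3.5 + 0.5 * effect * valence_sign + rng.normal(0.0, cfg.rating_noise_sd, shape)
        ratings[scale] = np.clip(np.round(r), 1, 6).astype(int)

    # realised update bias per participant, used for the volume coupling
    upd = np.where(valence_sign > 0, e1 - e2, np.where(valence_sign < 0, e2 - e1, 0.0))
    n_des = (valence_sign > 0).sum(axis=1)
    n_und = (valence_sign < 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_des = np.where(valence_sign > 0, upd, 0.0).sum(axis=1) / n_des
        mean_und = np.where(valence_sign < 0, upd, 0.0).sum(axis=1) / n_und
    bias = np.where((n_des == 0) | (n_und == 0), 0.0, mean_des - mean_und)

    # --- ROI volumes ----------------------------------------------------
    slope = np.where(is_older, cfg.volume_bias_slope_older, cfg.volume_bias_slope_young)
    d_mean = np.where(is_older, cfg.dorsal_volume_mean_older, cfg.dorsal_volume_mean_young)
    d_sd = np.where(is_older, cfg.dorsal_volume_sd_older, cfg.dorsal_volume_sd_young)
    centred_bias = np.zeros(n)
    for grp_mask in (is_older, ~is_older):
        centred_bias[grp_mask] = bias[grp_mask] - bias[grp_mask].mean()
    dorsal = d_mean + slope * centred_bias + rng.normal(0.0, 1.0, n) * d_sd
    v_mean = np.where(is_older, cfg.ventral_volume_mean_older, cfg.ventral_volume_mean_young)
    v_sd = np.where(is_older, cfg.ventral_volume_sd_older, cfg.ventral_volume_sd_young)
    ventral = v_mean + rng.normal(0.0, 1.0, n) * v_sd
    dorsal = np.maximum(dorsal, 1e-3)
    ventral = np.maximum(ventral, 1e-3)
    tiv = np.where(is_older, cfg.tiv_mean_older, cfg.tiv_mean_young) + rng.normal(
        0.0, cfg.tiv_sd, n
    )
    tiv = np.maximum(tiv, np.maximum(dorsal, ventral) + 0.1)

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "age_group": group,
            "age": age,
            "gender": gender,
            "iq": iq,
            "lot_r": lotr,
            "dorsal_acc_volume": np.round(dorsal, 6),
            "ventral_acc_volume": np.round(ventral, 6),
            "tiv": np.round(tiv, 6),
        }
    )

    ev_ids = np.array([e.event_id for e in events])
    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, cfg.n_events),
            "event_id": np.tile(ev_ids, n),
            "first_estimate": e1.ravel(),
            "base_rate_shown": np.tile(base, n),
            "second_estimate": e2.ravel(),
            "recalled_base_rate": recall.ravel(),
            "rt_first": np.round(rt1.ravel(), 4),
            "rt_second": np.round(rt2.ravel(), 4),
        }
    )
    for scale in RATING_SCALES:
        trials[f"rating_{scale}"] = ratings[scale].ravel()
    return participants, trials
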