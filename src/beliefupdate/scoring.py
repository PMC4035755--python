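"""Trial scoring and per-participant bias summaries.

A trial is *desirable* when the participant's first estimate exceeded the
presented average probability (the information was better than expected)
and *undesirable* when it fell short.  The update is signed so that
positive values mean movement toward the presented probability:

    desirable:   update = first estimate - second estimate
    undesirable: update = second estimate - first estimate

The update bias — mean desirable update minus mean undesirable update —
is the headline optimism measure.  Ties (first estimate exactly equal to
the shown probability) belong to neither class and are excluded from both
valence means.  Negative updates (belief moved away from the evidence)
are retained unmodified.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import RATING_SCALES

__all__ = [
    "classify_trial",
    "compute_update",
    "memory_error",
    "classify_trials",
    "summarize_participants",
    "build_analysis_table",
    "COVARIATE_COLUMNS",
    "VALENCE_DESIRABLE",
    "VALENCE_UNDESIRABLE",
    "VALENCE_TIE",
]

logger = logging.getLogger(__name__)

VALENCE_DESIRABLE = "desirable"
VALENCE_UNDESIRABLE = "undesirable"
VALENCE_TIE = "tie"

#: The 13 covariate columns of the fully adjusted group comparison:
#: IQ, trait optimism, mean first estimation error, the five Likert-scale
#: difference measures, two reaction-time difference measures (one per
#: estimation session), mean memory error, and the two trial counts.
COVARIATE_COLUMNS = (
    "iq",
    "lot_r",
    "mean_first_estimation_error",
    "rating_diff_vividness",
    "rating_diff_familiarity",
    "rating_diff_experience",
    "rating_diff_arousal",
    "rating_diff_negativity",
    "rt_diff_first",
    "rt_diff_second",
    "mean_memory_error",
    "n_desirable",
    "n_undesirable",
)


def _check_percent(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be in [0, 100], got {value}")


def classify_trial(first_estimate: float, base_rate: float) -> str:
    """Classify one trial by the sign of first estimate minus base rate."""
    _check_percent("first_estimate", first_estimate)
    _check_percent("base_rate", base_rate)
    if first_estimate > base_rate:
        return VALENCE_DESIRABLE
    if first_estimate < base_rate:
        return VALENCE_UNDESIRABLE
    return VALENCE_TIE


def compute_update(first_estimate: float, second_estimate: float, valence: str) -> float:
    """Signed update, positive toward the presented probability."""
    if valence == VALENCE_DESIRABLE:
        return first_estimate - second_estimate
    if valence == VALENCE_UNDESIRABLE:
        return second_estimate - first_estimate
    raise ValueError(f"update undefined for valence {valence!r}")


def memory_error(presented: float, recalled: float) -> float:
    """Absolute difference between shown and recalled base rate."""
    _check_percent("presented", presented)
    _check_percent("recalled", recalled)
    return abs(presented - recalled)


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a trial table.

    Adds ``valence``, ``estimation_error`` (signed, estimate minus shown
    probability, so underestimation is negative), ``update`` (NaN on
    ties) and ``memory_error`` (NaN when recall is missing).
    """
    out = trials.copy()
    e1 = out["first_estimate"].to_numpy(float)
    base = out["base_rate_shown"].to_numpy(float)
    e2 = out["second_estimate"].to_numpy(float)
    for name, arr in (("first_estimate", e1), ("base_rate_shown", base), ("second_estimate", e2)):
        bad = (arr < 0) | (arr > 100)
        if bad.any():
            raise ValueError(f"{name} outside [0, 100] in {int(bad.sum())} rows")

    err = e1 - base
    out["estimation_error"] = err
    out["valence"] = np.where(
        err > 0, VALENCE_DESIRABLE, np.where(err < 0, VALENCE_UNDESIRABLE, VALENCE_TIE)
    )
    out["update"] = np.where(err > 0, e1 - e2, np.where(err < 0, e2 - e1, np.nan))
    if "recalled_base_rate" in out.columns:
        recall = out["recalled_base_rate"].to_numpy(float)
        out["memory_error"] = np.abs(base - recall)
        n_missing = int(np.isnan(recall).sum())
        if n_missing:
            logger.info("%d trials lack a recall value; excluded from memory averaging", n_missing)
    else:
        out["memory_error"] = np.nan
    return out


def summarize_participants(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-participant summaries of updating behaviour.

    One row per participant: valence class counts, mean update per class,
    the update bias (desirable minus undesirable mean update — an exact
    identity), mean signed first estimation error, mean memory error, the
    five rating difference measures and the two reaction-time difference
    measures (desirable minus undesirable in every case).

    Participants lacking trials in either valence class get ``valid =
    False`` (a between-valence contrast is undefined for them) and a
    warning; they should be excluded from group tests.
    """
    counts = (
        classified.groupby(["participant_id", "valence"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    for v in (VALENCE_DESIRABLE, VALENCE_UNDESIRABLE, VALENCE_TIE):
        if v not in counts.columns:
            counts[v] = 0

    diff_cols = ["update"]
    for scale in RATING_SCALES:
        if f"rating_{scale}" in classified.columns:
            diff_cols.append(f"rating_{scale}")
    for rt in ("rt_first", "rt_second"):
        if rt in classified.columns:
            diff_cols.append(rt)
    by_valence = (
        classified.groupby(["participant_id", "valence"], sort=True)[diff_cols]
        .mean()
        .unstack()
    )

    def _per_valence(col: str, valence: str) -> pd.Series:
        if (col, valence) in by_valence.columns:
            return by_valence[(col, valence)]
        return pd.Series(np.nan, index=counts.index)

    overall = classified.groupby("participant_id", sort=True).agg(
        mean_first_estimation_error=("estimation_error", "mean"),
        mean_memory_error=("memory_error", "mean"),
    )

    out = pd.DataFrame(index=counts.index)
    out["n_desirable"] = counts[VALENCE_DESIRABLE]
    out["n_undesirable"] = counts[VALENCE_UNDESIRABLE]
    out["n_tie"] = counts[VALENCE_TIE]
    mean_des = _per_valence("update", VALENCE_DESIRABLE)
    mean_und = _per_valence("update", VALENCE_UNDESIRABLE)
    out["mean_update_desirable"] = mean_des
    out["mean_update_undesirable"] = mean_und
    out["update_bias"] = mean_des - mean_und
    out["mean_first_estimation_error"] = overall["mean_first_estimation_error"]
    out["mean_memory_error"] = overall["mean_memory_error"]
    for rt in ("rt_first", "rt_second"):
        suffix = rt.split("_")[1]
        out[f"rt_diff_{suffix}"] = (
            _per_valence(rt, VALENCE_DESIRABLE) - _per_valence(rt, VALENCE_UNDESIRABLE)
        )
    for scale in RATING_SCALES:
        col = f"rating_{scale}"
        out[f"rating_diff_{scale}"] = (
            _per_valence(col, VALENCE_DESIRABLE) - _per_valence(col, VALENCE_UNDESIRABLE)
        )
    out["valid"] = (out["n_desirable"] > 0) & (out["n_undesirable"] > 0)
    for pid in out.index[~out["valid"]]:
        logger.warning(
            "participant %s has an empty valence class (desirable=%d, undesirable=%d); "
            "summary flagged invalid",
            pid,
            out.loc[pid, "n_desirable"],
            out.loc[pid, "n_undesirable"],
        )
    return out.reset_index()


def build_analysis_table(
    summaries: pd.DataFrame,
    participants: pd.DataFrame,
    covariates: Iterable[str] = COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """One row per valid participant: group, bias, component updates and
    the covariate columns, ready for the group-comparison models.

    Rows with missing covariate values stay in the table (usable for
    unadjusted tests) but carry ``covariates_complete = False`` so the
    covariate-adjusted analysis can drop them; drops are logged.
    """
    covariates = list(covariates)
    unknown = set(covariates) - set(COVARIATE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown covariate columns: {sorted(unknown)}")

    merged = summaries.merge(participants, on="participant_id", how="left", validate="1:1")
    n_invalid = int((~merged["valid"]).sum())
    if n_invalid:
        logger.warning("%d participants excluded (empty valence class)", n_invalid)
    merged = merged[merged["valid"]].copy()

    cols = [
        "participant_id",
        "age_group",
        "update_bias",
        "mean_update_desirable",
        "mean_update_undesirable",
    ] + covariates
    table = merged[cols].copy()
    complete = table[covariates].notna().all(axis=1) if covariates else pd.Series(True, index=table.index)
    table["covariates_complete"] = complete
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.info(
            "%d participants have missing covariates; retained for unadjusted tests only",
            n_incomplete,
        )
    return table.reset_index(drop=True)
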