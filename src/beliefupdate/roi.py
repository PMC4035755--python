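"""ROI grey-matter volume vs belief-updating correlations.

Correlates dorsal and ventral anterior cingulate (ACC) grey-matter volume
with the update bias within each age group: four primary correlations
(2 subregions x 2 groups), each also as a partial correlation controlling
age, gender and total intracranial volume; cross-group Fisher r-to-z
comparisons per subregion; within-group dorsal-vs-ventral comparisons;
and the volume-range-matching exclusion re-analysis.  The primary family
is tested at the Bonferroni level 0.0125 (four tests); post-hoc follow-up
correlations with the bias components carry no familywise flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    ROI_BONFERRONI_ALPHA,
    StatResult,
    fisher_z_compare,
    fisher_z_compare_dependent,
    pearson,
    partial_pearson,
)

__all__ = [
    "RoiSuiteResult",
    "roi_correlation_suite",
    "followup_components",
    "volume_match",
    "matched_reanalysis",
    "SUBREGIONS",
]

SUBREGIONS = {"dorsal": "dorsal_acc_volume", "ventral": "ventral_acc_volume"}
GROUPS = ("young", "older")
CONTROLS = ("age", "gender", "tiv")


@dataclass
class RoiSuiteResult:
    """Primary ROI correlation family plus its comparison tests."""

    #: (subregion, group) -> {"r": StatResult, "partial_r": StatResult,
    #:  "significant": bool (plain r against the Bonferroni threshold)}
    primary: dict
    #: subregion -> StatResult (young vs older Fisher z; sign follows
    #: young minus older, so a stronger older correlation gives z < 0)
    cross_group: dict
    #: group -> StatResult (dorsal vs ventral comparison)
    within_group: dict
    alpha: float = ROI_BONFERRONI_ALPHA
    n_per_group: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_per_group": self.n_per_group,
            "primary": {
                f"{sub}_{grp}": {
                    "r": res["r"].to_dict(),
                    "partial_r": res["partial_r"].to_dict(),
                    "significant": res["significant"],
                }
                for (sub, grp), res in self.primary.items()
            },
            "cross_group": {k: v.to_dict() for k, v in self.cross_group.items()},
            "within_group": {k: v.to_dict() for k, v in self.within_group.items()},
        }


def _merge(roi_records: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Inner-join volumes with summaries; error on unmatched participants."""
    missing = set(summaries["participant_id"]) - set(roi_records["participant_id"])
    if missing:
        raise ValueError(f"no ROI record for participants: {sorted(missing)}")
    value_cols = [
        c
        for c in ("update_bias", "mean_update_desirable", "mean_update_undesirable")
        if c in summaries.columns
    ]
    merged = roi_records.merge(
        summaries[["participant_id"] + value_cols], on="participant_id", validate="1:1"
    )
    merged["gender_code"] = (merged["gender"].astype(str) == "M").astype(float)
    return merged


def _controls_matrix(sub: pd.DataFrame) -> np.ndarray:
    return sub[["age", "gender_code", "tiv"]].to_numpy(float)


def roi_correlation_suite(
    roi_records: pd.DataFrame,
    summaries: pd.DataFrame,
    measure: str = "update_bias",
    alpha: float = ROI_BONFERRONI_ALPHA,
    dependent_within: bool = False,
) -> RoiSuiteResult:
    """The primary ROI correlation family on one task measure.

    Computes plain and partial (age, gender, TIV) Pearson correlations of
    each ACC subregion's volume with ``measure`` in each age group, flags
    the four plain correlations against ``alpha``, compares each
    subregion's correlation across groups (Fisher r-to-z, one-tailed),
    and compares dorsal vs ventral within each group (independent-form
    Fisher z by default; Steiger's dependent test when
    ``dependent_within`` is set).
    """
    merged = _merge(roi_records, summaries)
    primary: dict = {}
    n_per_group: dict = {}
    for grp in GROUPS:
        sub = merged[merged["age_group"] == grp]
        n_per_group[grp] = len(sub)
        if len(sub) < 8:
            raise ValueError(f"need >= 8 participants per group, got {len(sub)} in {grp!r}")
        controls = _controls_matrix(sub)
        y = sub[measure].to_numpy(float)
        for name, col in SUBREGIONS.items():
            vol = sub[col].to_numpy(float)
            r = pearson(vol, y, name=f"{name} ACC volume vs {measure} ({grp})")
            pr = partial_pearson(
                vol, y, controls,
                name=f"{name} ACC volume vs {measure} ({grp}, partial: age/gender/TIV)",
            )
            primary[(name, grp)] = {
                "r": r,
                "partial_r": pr,
                "significant": bool(r.p < alpha),
            }

    cross_group = {}
    for name in SUBREGIONS:
        r_y = primary[(name, "young")]["r"]
        r_o = primary[(name, "older")]["r"]
        cross_group[name] = fisher_z_compare(
            r_y.statistic, r_y.n, r_o.statistic, r_o.n,
            tails="one", name=f"{name} ACC correlation, young vs older",
        )

    within_group = {}
    for grp in GROUPS:
        r_d = primary[("dorsal", grp)]["r"]
        r_v = primary[("ventral", grp)]["r"]
        if dependent_within:
            sub = merged[merged["age_group"] == grp]
            r12 = float(
                np.corrcoef(
                    sub["dorsal_acc_volume"].to_numpy(float),
                    sub["ventral_acc_volume"].to_numpy(float),
                )[0, 1]
            )
            within_group[grp] = fisher_z_compare_dependent(
                r_d.statistic, r_v.statistic, r12, r_d.n,
                tails="one", name=f"dorsal vs ventral correlation ({grp}, dependent)",
            )
        else:
            within_group[grp] = fisher_z_compare(
                r_d.statistic, r_d.n, r_v.statistic, r_v.n,
                tails="one", name=f"dorsal vs ventral correlation ({grp})",
            )

    return RoiSuiteResult(
        primary=primary,
        cross_group=cross_group,
        within_group=within_group,
        alpha=alpha,
        n_per_group=n_per_group,
    )


def followup_components(
    roi_records: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Post-hoc correlations of subregion volumes with the update-bias
    components (desirable and undesirable mean update), plain and partial,
    per group.  No familywise flag — these are follow-ups."""
    merged = _merge(roi_records, summaries)
    rows = []
    for grp in GROUPS:
        sub = merged[merged["age_group"] == grp]
        controls = _controls_matrix(sub)
        for comp in ("mean_update_desirable", "mean_update_undesirable"):
            y = sub[comp].to_numpy(float)
            for name, col in SUBREGIONS.items():
                vol = sub[col].to_numpy(float)
                r = pearson(vol, y)
                pr = partial_pearson(vol, y, controls)
                rows.append(
                    {
                        "group": grp,
                        "subregion": name,
                        "component": comp,
                        "n": len(sub),
                        "r": r.statistic,
                        "p": r.p,
                        "partial_r": pr.statistic,
                        "partial_p": pr.p,
                    }
                )
    return pd.DataFrame(rows)


def volume_match(young_volumes, older_volumes) -> tuple[np.ndarray, np.ndarray]:
    """Volume-range matching: simultaneously drop young participants with
    volumes above the older group's maximum and older participants below
    the young group's minimum.

    Both rules use the ORIGINAL groups' extrema (single pass, not
    iterated) and boundary equality retains the participant.  Returns
    boolean keep-masks for the two groups.
    """
    young = np.asarray(young_volumes, float)
    older = np.asarray(older_volumes, float)
    if young.size == 0 or older.size == 0:
        raise ValueError("both groups must be non-empty")
    young_keep = young <= older.max()
    older_keep = older >= young.min()
    return young_keep, older_keep


def matched_reanalysis(
    roi_records: pd.DataFrame,
    summaries: pd.DataFrame,
    subregion: str = "dorsal",
    measure: str = "update_bias",
) -> dict:
    """Re-run the per-group volume-bias correlations on volume-matched
    subsets for one subregion, reporting exclusion counts per group."""
    if subregion not in SUBREGIONS:
        raise ValueError(f"subregion must be one of {sorted(SUBREGIONS)}")
    col = SUBREGIONS[subregion]
    merged = _merge(roi_records, summaries)
    young = merged[merged["age_group"] == "young"].reset_index(drop=True)
    older = merged[merged["age_group"] == "older"].reset_index(drop=True)
    young_keep, older_keep = volume_match(young[col], older[col])
    out = {
        "subregion": subregion,
        "n_excluded_young": int((~young_keep).sum()),
        "n_excluded_older": int((~older_keep).sum()),
    }
    for grp_name, sub, keep in (("young", young, young_keep), ("older", older, older_keep)):
        kept = sub[keep]
        if len(kept) >= 3 and np.ptp(kept[col].to_numpy(float)) > 0:
            res = pearson(
                kept[col].to_numpy(float),
                kept[measure].to_numpy(float),
                name=f"{subregion} ACC volume vs {measure} ({grp_name}, volume-matched)",
            )
        else:
            res = None
        out[grp_name] = res
    return out
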