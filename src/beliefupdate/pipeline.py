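"""End-to-end pipeline: simulate/load -> score -> infer -> ROI -> report.

``run_pipeline`` ties the stages together and writes a per-participant
summary table (CSV), machine-readable results (JSON, schema-validated,
byte-identical under a fixed config and seed) and a human-readable
markdown report.  Every result row carries the test's name, statistic,
degrees of freedom, p-value and tail convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as bio
from .inference import ROI_BONFERRONI_ALPHA, ancova_interaction, mixed_anova_2x2
from .roi import matched_reanalysis, roi_correlation_suite
from .scoring import COVARIATE_COLUMNS, build_analysis_table, classify_trials, summarize_participants
from .simulate import SimulationConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Provide either ``simulation`` (a :class:`SimulationConfig`) or both
    CSV paths.  ``covariates`` selects the ANCOVA covariate columns (the
    full 13-column schema by default; empty list disables the ANCOVA).
    """

    simulation: SimulationConfig | None = None
    trials_path: str | None = None
    participants_path: str | None = None
    covariates: tuple = COVARIATE_COLUMNS
    roi_alpha: float = ROI_BONFERRONI_ALPHA
    volume_matching: bool = True
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_paths = self.trials_path is not None and self.participants_path is not None
        if not (has_sim or has_paths):
            raise ValueError("provide a simulation config or both input CSV paths")


def _load_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if cfg.simulation is not None:
        sim = cfg.simulation
        return generate_cohort(sim)
    participants = bio.read_participants(cfg.participants_path)
    trials = bio.read_trials(cfg.trials_path)
    return participants, trials


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``cfg.out_dir``.

    Returns the results dict (the same object serialised to
    ``results.json``).
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    participants, trials = _load_inputs(cfg)
    classified = classify_trials(trials)
    summaries = summarize_participants(classified)
    table = build_analysis_table(summaries, participants)

    summaries_path = out_dir / "participant_summaries.csv"
    bio.write_table(table, summaries_path)

    anova = mixed_anova_2x2(table)
    results: dict = {
        "seed": int(cfg.seed if cfg.simulation is None else cfg.simulation.seed),
        "n_participants": int(len(table)),
        "summaries_path": summaries_path.name,
        "anova": anova.to_dict(),
    }

    covariates = list(cfg.covariates)
    if covariates:
        adj = table[table["covariates_complete"]]
        n_dropped = len(table) - len(adj)
        if n_dropped:
            logger.info("ANCOVA drops %d participants with incomplete covariates", n_dropped)
        ancova = ancova_interaction(adj, covariates)
        results["ancova"] = ancova.to_dict()

    roi_cols = {"dorsal_acc_volume", "ventral_acc_volume", "tiv", "age", "gender"}
    if roi_cols <= set(participants.columns):
        merged_meta = participants.merge(
            table[["participant_id"]], on="participant_id"
        )
        suite = roi_correlation_suite(
            merged_meta, table[["participant_id", "update_bias",
                                "mean_update_desirable", "mean_update_undesirable"]],
            alpha=cfg.roi_alpha,
        )
        results["roi"] = suite.to_dict()
        if cfg.volume_matching:
            matched = {}
            for subregion in ("dorsal", "ventral"):
                m = matched_reanalysis(merged_meta, table, subregion=subregion)
                matched[subregion] = {
                    "n_excluded_young": m["n_excluded_young"],
                    "n_excluded_older": m["n_excluded_older"],
                    "young": m["young"].to_dict() if m["young"] else None,
                    "older": m["older"].to_dict() if m["older"] else None,
                }
            results["roi_volume_matched"] = matched

    bio.validate_results(results)
    json_path = out_dir / "results.json"
    json_path.write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "report.md").write_text(_render_report(results), encoding="utf-8")
    return results


def _fmt_stat(d: dict) -> str:
    df = ", ".join(f"{v:g}" for v in d["df"])
    return (
        f"| {d['name']} | {d['statistic']:.4g} | ({df}) | {d['p']:.4g} | {d['tails']} |"
    )


def _render_report(results: dict) -> str:
    lines = [
        "# Belief-updating analysis report",
        "",
        f"N participants analysed: {results['n_participants']}",
        "",
        "## Group comparison (2x2 mixed ANOVA)",
        "",
        "| test | statistic | df | p | tails |",
        "|---|---|---|---|---|",
    ]
    for key in ("valence", "age", "interaction"):
        lines.append(_fmt_stat(results["anova"][key]))
    if "ancova" in results:
        lines += ["", "## Covariate-adjusted interaction (ANCOVA)", "",
                  "| test | statistic | df | p | tails |", "|---|---|---|---|---|",
                  _fmt_stat(results["ancova"])]
    if "roi" in results:
        roi = results["roi"]
        lines += [
            "",
            f"## ROI correlations (Bonferroni alpha = {roi['alpha']})",
            "",
            "| correlation | r | partial r | p | significant |",
            "|---|---|---|---|---|",
        ]
        for key, res in sorted(roi["primary"].items()):
            lines.append(
                f"| {key} | {res['r']['statistic']:.3f} | "
                f"{res['partial_r']['statistic']:.3f} | {res['r']['p']:.4g} | "
                f"{'yes' if res['significant'] else 'no'} |"
            )
        lines += ["", "Cross-group and within-group Fisher r-to-z comparisons:", ""]
        lines += ["| comparison | z | p (one-tailed) |", "|---|---|---|"]
        for key, d in sorted(roi["cross_group"].items()):
            lines.append(f"| {d['name']} | {d['statistic']:.3f} | {d['p']:.4g} |")
        for key, d in sorted(roi["within_group"].items()):
            lines.append(f"| {d['name']} | {d['statistic']:.3f} | {d['p']:.4g} |")
    if "roi_volume_matched" in results:
        lines += ["", "## Volume-matched re-analysis", ""]
        for subregion, m in sorted(results["roi_volume_matched"].items()):
            lines.append(
                f"- {subregion}: excluded {m['n_excluded_young']} young, "
                f"{m['n_excluded_older']} older"
            )
            for grp in ("young", "older"):
                if m[grp]:
                    lines.append(
                        f"  - {grp}: r = {m[grp]['statistic']:.3f}, p = {m[grp]['p']:.4g} "
                        f"(n = {m[grp]['n']})"
                    )
    lines.append("")
    return "\n".join(lines)
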