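"""ROI analysis: ACC volume vs update bias, matching, Fisher comparisons.

Correlates dorsal/ventral anterior cingulate grey-matter volume with the
update bias per age group (plain and partial, Bonferroni at 0.0125 for
the four primary tests), compares correlation strength across groups via
Fisher r-to-z, and re-runs the analysis on volume-range-matched subsets.
"""

import beliefupdate as bu

participants, trials = bu.generate_cohort(bu.paper_like_config(seed=7))
table = bu.build_analysis_table(
    bu.summarize_participants(bu.classify_trials(trials)), participants
)

suite = bu.roi_correlation_suite(participants, table)
print(f"primary family (alpha = {suite.alpha}):")
for (subregion, group), res in sorted(suite.primary.items()):
    flag = "*" if res["significant"] else " "
    print(f"  {subregion:8s} {group:6s} r = {res['r'].statistic:+.3f} "
          f"(p = {res['r'].p:.4g}){flag}  partial r = {res['partial_r'].statistic:+.3f}")
print("* survives the four-test Bonferroni threshold; the generator couples")
print("  dorsal volume to bias only in the older group, and only that cell flags.")
print()

for subregion, z in suite.cross_group.items():
    print(f"{z.name}: z = {z.statistic:.2f}, one-tailed p = {z.p:.4g}")
print("Negative z: the correlation is stronger in the older group.")
print()

m = bu.matched_reanalysis(participants, table, "dorsal")
print(f"volume matching (dorsal): excluded {m['n_excluded_young']} young, "
      f"{m['n_excluded_older']} older")
if m["older"]:
    print(f"  older matched subset: r = {m['older'].statistic:.2f}, "
          f"p = {m['older'].p:.4g} (n = {m['older'].n})")
print("The volume-bias link persists in the older group after equating the")
print("volume ranges across groups, so it is not a range artefact.")
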