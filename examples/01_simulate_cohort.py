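"""Simulate a two-group belief-updating cohort and look at its structure.

Generates 18 young and 18 older synthetic participants, each completing
45 adverse-life-event trials (first estimate, shown base rate, second
estimate, recall, ratings), then prints the group-level behavioural
pattern the generator builds in.
"""

import beliefupdate as bu

cfg = bu.paper_like_config(seed=7)
participants, trials = bu.generate_cohort(cfg)

print(f"{len(participants)} participants, {len(trials)} trials")
print(participants.head(3).to_string(index=False))
print()

classified = bu.classify_trials(trials)
summaries = bu.summarize_participants(classified)
table = bu.build_analysis_table(summaries, participants)
cols = ["update_bias", "mean_update_desirable", "mean_update_undesirable",
        "n_desirable", "n_undesirable", "mean_first_estimation_error"]
print(table.groupby("age_group")[cols].mean().round(2).to_string())
print()
print("A larger older-group update bias, driven by reduced updating after")
print("worse-than-expected (undesirable) information, with similar desirable")
print("updating and more undesirable than desirable trials in both groups:")
print("the age-modulated optimism pattern the analysis pipeline targets.")
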