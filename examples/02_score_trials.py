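"""Score trials: valence classification, updates, the bias identity.

Shows the scoring rules on a handful of hand-made trials: a trial is
desirable when the first estimate exceeded the shown base rate, the
update is signed toward the shown probability, and the update bias is
the desirable-minus-undesirable difference of mean updates.
"""

import beliefupdate as bu

print("classify_trial(40, 30) ->", bu.classify_trial(40, 30))
print("classify_trial(10, 30) ->", bu.classify_trial(10, 30))
print("classify_trial(30, 30) ->", bu.classify_trial(30, 30))
print()
print("desirable trial, estimates 40 -> 32:", bu.compute_update(40, 32, "desirable"),
      "(moved 8 points toward the shown 30)")
print("undesirable trial, estimates 10 -> 16:", bu.compute_update(10, 16, "undesirable"),
      "(moved 6 points toward the shown 30)")
print("memory_error(30, 25) ->", bu.memory_error(30, 25), "(absolute recall error)")
print()

# per-participant summary on a simulated cohort
participants, trials = bu.generate_cohort(bu.paper_like_config(seed=7))
summaries = bu.summarize_participants(bu.classify_trials(trials))
row = summaries.iloc[0]
print(f"participant {row['participant_id']}: "
      f"{row['n_desirable']} desirable / {row['n_undesirable']} undesirable trials, "
      f"bias = {row['update_bias']:.2f} "
      f"(= {row['mean_update_desirable']:.2f} - {row['mean_update_undesirable']:.2f})")
print("The bias is an exact identity: mean desirable minus mean undesirable update.")
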