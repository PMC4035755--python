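# Methods

## Scoring model

Each trial pairs a participant's first probability estimate *E1* for an
adverse life event (percent, 5-year horizon) with the presented
population base rate *P* and a later second estimate *E2*. The signed
estimation error is *E1* − *P*; trials with *E1* > *P* are *desirable*
(the news was better than expected), *E1* < *P* *undesirable*. The
update is signed toward the presented probability (*E1* − *E2* on
desirable trials, *E2* − *E1* on undesirable ones); movements away from
the evidence are negative and retained — no winsorising or truncation.
The per-participant update bias is the difference of the two class
means, an exact identity maintained to machine precision.

Ties (*E1* = *P* exactly) belong to neither class and are excluded from
both class means; including them in either class would bias that class
mean, and a between-class contrast is undefined for a participant with
an empty class, so such participants are flagged invalid and excluded
from group tests with a logged warning. Missing recall or rating values
exclude a trial from the affected covariate only; nothing is imputed.

The covariate set of the adjusted group comparison is fixed at 13
columns: IQ; LOT-R trait optimism (0–24); mean signed first estimation
error; desirable-minus-undesirable differences of the five Likert scales
(vividness, familiarity, experience, arousal, negativity); the same
difference of reaction times separately per estimation session (two
columns); mean absolute memory error; and the desirable and undesirable
trial counts. Counting the session-wise reaction-time differences as two
columns is what makes the denominator bookkeeping come out at
*N* − 2 − 13 (21 for an 18+18 cohort).

## Inference

**Two-sample t.** Pooled-variance (Student) form with df *n1*+*n2*−2,
from raw vectors or directly from summary statistics (means, SDs, group
sizes). The statistic's sign follows mean2 − mean1, so calling with
(young, older) makes positive values mean "older higher". Welch
correction is deliberately not applied: the reported df structure of the
design this replicates is the pooled one.

**2×2 mixed ANOVA.** The design is fixed at two valence levels within
subjects and two age groups between subjects, which admits an exact
reduction instead of a general sums-of-squares engine: with
per-participant difference scores *d* (the bias) and means *m* across
the two conditions, the interaction *F*(1, *N*−2) is the squared pooled
two-sample *t* on *d*; the valence main effect tests the *unweighted*
grand mean of the two group means of *d* against zero on the same
pooled error (the Type III convention, which matters when groups are
unbalanced); the group main effect is the squared two-sample *t* on
*m*. The test suite verifies equality with an independent long-format
least-squares cell-means fit (sum-to-zero coding, Type III model
comparisons) to 1e-8 relative on 200 random balanced and unbalanced
datasets, and with pingouin's mixed ANOVA on balanced data.

**ANCOVA.** The bias already encodes the within-subject contrast, so the
covariate-adjusted interaction is the squared *t* of the group
coefficient in an OLS of bias on group plus mean-centred covariates,
*F*(1, *N*−2−*k*). Centring keeps the group coefficient interpretable
as the adjusted group difference at covariate means. A rank-deficient
design raises an error naming the collinear columns. With *k* = 0 the
result equals the unadjusted interaction row exactly (nested-model
identity, tested).

**Correlations.** Pearson r with p from the t transform
(df = *n*−2, two-tailed by default); partial correlation by correlating
least-squares residuals on the controls, df = *n*−2−*k*. Independent
correlations are compared with the Fisher r-to-z statistic
(atanh-transform, normal reference), one-tailed by default because the
comparisons are directional ("stronger in the older group"); tails are a
parameter everywhere. A Steiger Z1* variant for overlapping dependent
correlations (dorsal vs ventral volume correlated with the same bias in
the same participants) is provided behind a separate entry point; the
independent form is the default used by the ROI suite. The only
multiplicity adjustment anywhere is the Bonferroni threshold
α = 0.0125 applied to the four primary ROI correlations (2 subregions ×
2 groups); follow-ups of the bias components are post-hoc and
unadjusted.

**Volume matching.** To rule out range artefacts, the matched
re-analysis drops young participants whose subregion volume exceeds the
older group's maximum and older participants below the young group's
minimum — both rules evaluated once against the *original* groups'
extrema (a single simultaneous pass, not iterated), with boundary
equality retaining the participant. Under this convention the operation
is idempotent.

## Synthetic cohort generator

The generator emulates the paradigm's data so the full chain is
exercisable without any download; it is a study-conditions device, not a
cognitive model fit to human data. Per participant *i* with optimism
shift *s_i* ~ N(μ_group, σ²):

- first estimate: *E1* = *P* − *s_i* + ε, ε ~ N(0, 15²), clipped to
  [1, 99] — positive shifts mean initial underestimation, larger in the
  older group;
- second estimate: *E2* = *E1* − α_v (*E1* − *P*) + η,
  η ~ N(0, 3²), clipped, where α_v is the group's learning rate for the
  trial's valence, giving update = α_v |estimation error| + noise;
- recall: *P* + memory noise (SD 8 young / 13 older), clipped to
  [0, 100];
- five Likert ratings around 3.5 with a per-scale valence shift
  (desirable trials more vivid/familiar/experienced, undesirable more
  arousing/negative), integer-clipped to 1..6; lognormal reaction times
  with no group or valence effect;
- ROI volumes from group-specific normals; in the older group only,
  dorsal ACC volume couples linearly to the participant's realised
  update bias (slope 0.02 volume units per percent of bias), inducing an
  older-specific volume–bias correlation of roughly 0.7–0.8.

Default parameter choices and their rationale:

| parameter | default | why |
|---|---|---|
| cohort | 18 + 18, 45 events | the paradigm's design |
| base-rate range | [10, 70] %, integer | plausible adverse-event rates; configurable |
| α desirable | 0.65 both groups | desirable updating does not differ by age |
| α undesirable | 0.35 young / 0.05 older | the age-modulated asymmetry; sized so the 18+18 interaction test has high but not trivial power |
| optimism shift μ | 4.71 young / 12.24 older (σ 6.0) | reproduces the groups' published mean ± SD first estimation errors |
| estimate noise SD | 15 % | implied by the published desirable/undesirable trial counts (≈18/25 young, 13/30 older out of ~43) |
| update noise SD | 3 % | trial-level revision jitter |
| LOT-R, ages, volume means/SDs | published group values | anchors the participant table to realistic scales |

Estimates and recalls are integer-rounded by default
(`integer_estimates=True`): participants type whole percents, and the
rounding produces occasional first-estimate/base-rate ties, so the
desirable and undesirable trial counts vary independently across
participants — without ties the two count covariates would sum to the
event count and make the 13-covariate ANCOVA rank-deficient on every
simulated cohort. Exactness tests (update = α|error| exactly, noiseless
recovery) switch rounding off, and "zero noise" in those contexts means
zero update noise: estimate dispersion must stay positive or every trial
of a participant falls in a single valence class and the bias is
undefined.

A single RNG stream per cohort is seeded once from the config, and
experiment-level loops derive per-replicate sub-seeds from a
`SeedSequence`, so every report is byte-reproducible from
(config, n_reps, seed).

What the generator does **not** emulate: event semantics, scale-use
habits, serial position or session-order effects, response-time
structure beyond lognormal noise, any voxel-level imaging data, and any
dependence of memory error on valence. Passing tests therefore show the
pipeline's arithmetic and inferential machinery behave correctly under
the assumed generative structure — not that the structure is true of
human data.

## Recovery and power

The learning-rate estimator is the least-squares slope *through the
origin* of update on |estimation error| within each valence class —
model-matched, because the generative rule has no intercept; it is
deliberately not a claim about human data. Estimates are unbounded and
reported as-is; a class with fewer than two nonzero-error trials is
flagged unidentifiable (NaN). Group-level recovery averages
per-participant slopes. With the default noise the estimator's absolute
bias stays below 0.05 for all four rates over 200 replicates (rounding
and edge-clipping contribute a bias of order 0.01); with zero update
noise recovery is exact to machine precision.

Power/type-I experiments rerun generate → score → mixed-ANOVA per
replicate. Under the null configuration (all four rates equal, identical
shift distributions, volume coupling off) the two groups are
exchangeable and the interaction test's rejection rate at α = 0.05 is
nominal within Monte-Carlo error (checked over 2000 cohorts). Problem
sizes used by the packaged experiments — 2000 cohorts for calibration,
500 for directional consistency, 200 replicates for recovery, 200
random datasets for the ANOVA oracle, 10,000 shuffles for the
permutation check — were chosen to make Monte-Carlo error small relative
to the tolerances tested.

## Numerical and design choices

- Estimates are continuous percents clipped to [1, 99] before optional
  rounding; clipping avoids degenerate 0/100 responses.
- The gender control variable enters partial correlations as a binary
  indicator; the coding direction does not affect |r|.
- Volumes are used as provided — total intracranial volume enters only
  as a control variable, never as a normaliser.
- Cross-group Fisher z is computed as young minus older, so a stronger
  older correlation yields negative z.
- JSON results are serialised with sorted keys so identical runs are
  byte-identical; the results dict is validated against a packaged
  schema by a small internal checker (required keys + types).
- Degenerate inputs error early with the offending field named: invalid
  config ranges, constant correlation inputs, |r| = 1 in the Fisher
  transform, rank-deficient designs, groups smaller than two.

## Known limitations

- The mixed-ANOVA reduction is exact only for the 2×2 design; more
  levels would need a general engine.
- The ANCOVA treats covariates as fixed and linear; no interaction
  between covariates and group is modelled (matching the standard
  difference-score GLM).
- Simulated estimate noise is homoscedastic across events and
  participants; real response noise is unlikely to be.
- The volume–bias coupling is linear by construction; the ROI suite's
  power against nonlinear couplings is untested.
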