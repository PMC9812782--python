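# Methods

This note documents the statistical model behind `mousedls`, the choices made
where the design was genuinely open, and what the synthetic-cohort tests do and
do not demonstrate about real data.

## The assessment model

A cohort is one group of interest versus one healthy control group (multi-arm
designs are decomposed by the caller). All decision statistics are group-level
two-sample comparisons; only severity is per animal.

**Z-scoring.** Every measurement is standardized against the control mean and
sample SD of the *same read-out and session* (`z = (X − μ)/σ`), then
sign-corrected so positive z = impairment. Control references require at least
two control animals and a control SD above `sd_tolerance` (default `1e-12`,
distinguishing true constancy from float noise); a degenerate control SD is an
error, never silently imputed. By construction the control sample itself
z-scores to mean 0, SD 1.

**Composites.** A composite z is the arithmetic mean of directional z values.
When read-outs are pooled (per criterion, per symptom, or for severity), the
composite is the mean of *per-read-out mean z values*, i.e. each read-out is
weighted equally even when read-outs differ in session count. For severity,
every configured read-out contributes.

**MESP.** A comparison counts as evidence only if `p ≤ α` **and** the effect
is at least moderate **and** points toward impairment. Defaults: α = 0.05,
|Cohen's d| ≥ 0.5, Cohen's f² ≥ 0.0625 for repeated-measures effects. The f²
default takes the stated "0.25²" threshold literally; because the conventional
"moderate" f² is 0.15 (0.25 being moderate *f*, not f²), the threshold is a
plain config field — users who read the criterion as f ≥ 0.25 should set
`f2_threshold=0.0625` (the default) and those wanting conventional moderate f²
should set 0.15. With three sessions and typical within-animal correlation the
group-effect f² comfortably exceeds either value at d ≈ 1.5, so the choice is
rarely decisive.

**Tests and effect sizes.** The two-group test is Welch's unequal-variance t
(two-sided) — two-sided despite directional hypotheses, because directionality
is enforced separately by the explicit `direction_consistent` flag; this keeps
p values comparable to common practice and makes the direction rule testable.
Cohen's d uses the pooled (n−1)-weighted SD (Glass's Δ with the control SD and
the Hedges small-sample correction are available as options, both off by
default). Longitudinal read-outs use the balanced mixed-design (group between ×
session within) ANOVA: the group main effect is tested against the
subject-within-group error, `F = (SS_group/1)/(SS_subj/(N−2))`, with partial
η² = SS_group/(SS_group+SS_subj) converted to f² = η²/(1−η²). The
implementation is coded directly from the sums of squares for speed inside
Monte-Carlo loops and is cross-checked in the test suite against both an
independently coded SS oracle and `pingouin.mixed_anova`. Balance (every animal
at every session) is a hard requirement: unbalanced panels are rejected at
validation rather than imputed — explicit failure beats silent bias. A
longitudinal read-out observed at a single session falls back to the
cross-sectional route with a disclosure.

Multiple-testing correction defaults to none (correction is the user's call);
`multiple_testing="holm_within_criterion"` applies Holm within each criterion's
evidence family.

## Criterion rules

- **Duration**: requires ≥ 1 longitudinal read-out observed at ≥ 2 sessions
  whose span reaches `min_duration_days` (default 7); a shorter span is ABSENT
  regardless of statistics, and statistics are then evaluated either as the
  repeated-measures group effect over the whole span (`duration_mode=
  "overall"`, default — the per-timepoint conjunction is far stricter than any
  clinical analogue) or as a cross-sectional pass at every session
  (`"per_timepoint"`). Longitudinal sociofunctional read-outs legitimately
  serve both the duration and sociofunctional criteria; the sharing is
  disclosed in the report.
- **Sociofunctional / biological**: the criterion's read-outs, pooled
  (composite mode) or binarized two-of-two (individual mode). A single
  configured read-out is allowed with a mandatory disclosure.
- **Symptoms**: anhedonia is the mandatory core symptom — if absent, the
  criterion is absent no matter what else is present. With anhedonia present,
  at least `n_additional_symptoms` (default 3) distinct additional symptoms
  must be present; if inconsistent symptoms could still close the shortfall the
  criterion is reported INCONSISTENT rather than ABSENT.
- **Verdict**: PRESENT when `n_criteria_required` (default 4) criteria are
  present; otherwise ABSENT if any criterion is definitively absent (a failed
  criterion cannot be rescued by resolving inconsistencies elsewhere — pending
  items are still disclosed); otherwise INCOMPLETE (inconsistent or
  non-assessable evidence, all disclosed).

**Evaluation mode.** `mode="composite"` is the default: each criterion or
symptom is decided by one MESP comparison on its per-animal composite z. The
composite is the framework's recommended aggregation — standardized,
between-study comparable, and better powered because read-out noise averages
out (pooling two independent read-outs scales an injected standardized shift by
≈ √2). Per-read-out binarization (`mode="individual"`) implements the
two-of-two / one-of-two / augmented-third logic verbatim and is preferable when
read-outs within a criterion measure clearly distinct constructs; note that at
n = 12 per group the conjunction of ~12 separate MESP passes leaves little
power even for large effects, which is a property of the design, not of the
implementation.

**Severity.** Each group-of-interest animal's composite z (control-SD units)
maps to none (≤ 0), mild (0–1], moderate (1–2], severe (> 2). The band unit is
the control SD embodied in the z-score itself, and the third band is open-ended
so the function is total. Whether severity should be read conditionally on a
PRESENT verdict is not settled; the report therefore carries both
`per_animal_severity` (always) and `severity_if_present` (empty unless the
verdict is PRESENT).

## Duration translation

Linear through the origin using two anchor pairs: 10 human months ↔ 52 mouse
hours (young adult, 10–64 weeks) and ↔ 176.5 h (presenescent, 65–72 weeks),
with a month fixed at 365.25/12 = 30.4375 days — the convention that reproduces
the published 2.4 h equivalent of the 14-day criterion from the 52 h anchor.
No interpolation is performed between age classes; ages in the 64–65-week gap
or outside both ranges raise an error rather than guessing.

## The synthetic-cohort generator

`simulate_cohort` emulates the measurement table of a chronic-stress mouse
study. Per read-out with control mean m and SD s, an animal random effect
`b ~ N(0, ρs²)` plus session noise `e ~ N(0, (1−ρ)s²)` gives marginal N(m, s²)
values with compound-symmetry within-animal correlation ρ — deliberately
matching the mixed-ANOVA assumptions so parameter-recovery tests are
interpretable. Susceptible interest-group animals (a Bernoulli latent class,
fraction `susceptible_fraction`) are shifted by `effect_d·s` in the impairment
direction. Bounded read-outs (sucrose preference) are clipped to their range
and the clipping disclosed in metadata. Replicate seeds are spawned from a
single base seed through `numpy.random.SeedSequence`, so every replicate is
independent and the whole map seed → dataset is a pure function.

Default conditions (chosen once as a realistic chronic-stress cohort and used
throughout the test suite): 12 animals per group, sessions at days 0/4/8 (an
8-day span, clearing the 7-day minimum), ρ = 0.5, susceptible fraction 1.0
(effects are stated as whole-group Cohen's d), balanced sexes, and a
12-read-out panel — social interaction-zone time and nest score (longitudinal,
sociofunctional, also carrying duration), corticosterone and BrdU+ cell count
(biological), sucrose preference and urine sniffing time (anhedonia), and three
additional symptoms with two read-outs each (weight loss: body weight, food
intake; self-neglect: coat state, grooming; fatigue: open-field distance, wheel
running). Means and SDs are in the range typical for adult C57BL/6-type
cohorts (e.g. sucrose preference 0.85 ± 0.08, corticosterone 45 ± 12 ng/ml).

**What the simulations do and do not show.** The generator is Gaussian,
balanced, and homoscedastic, with identical effect sizes on every read-out and
exchangeable animals. Passing operating-characteristic tests therefore
demonstrates the *decision logic and its calibration under the model's own
assumptions* — type-I error of the MESP conjunction below α, verdict false
positives far below α⁴-level, power increasing in effect size — not robustness
to skewed read-outs, floor/ceiling effects, missing sessions, litter effects,
or heteroscedastic stress responses found in real cohorts.

## Problem sizes used by the test suite

Monte-Carlo checks use 10,000 replicates for null calibration of the
single-read-out MESP rule and of the full classifier (n = 12 per group), and
500 replicates per effect-size level (d ∈ {0, 0.5, 1.0, 1.5}) for the power
curve; the repeated-measures implementation is verified exhaustively against
the SS oracle on all balanced designs up to 6 + 6 animals × 4 sessions. These
sizes give binomial standard errors ≈ 0.002 (null) and ≈ 0.015 (power), small
relative to the margins being tested.

## Known limitations

- Group-level verdict only; no individual-level DLS diagnosis (no individual
  decision thresholds exist — only severity is per animal).
- No nonparametric route (Mann–Whitney / rank-biserial) yet; skewed read-outs
  must be transformed by the user.
- Balanced panels are required for longitudinal read-outs; designs with
  dropout need pre-processing (e.g. complete-case restriction) first.
- Sex is carried as metadata and pooled by default; per-sex stratified runs
  are simply two invocations on subset data, as no stratified decision rule is
  defined.
- The severity bands read "within one SD" as bands of the control distribution
  (0–1, 1–2, > 2 control SDs); a reading centred on the interest-group mean
  would differ.
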