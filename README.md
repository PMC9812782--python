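# mousedls

Depression-like syndrome (DLS) assessment for laboratory-mouse cohorts.

Preclinical depression research suffers from vague terminology: "depressive-like
behavior" can mean anything from a single forced-swim score to a rich
longitudinal phenotype. `mousedls` implements a syndrome-level minimum-threshold
framework for mice: a group of interest is compared against a healthy control
group on **four criteria** — (I) minimum phenotype duration, (II) sociofunctional
impairment, (III) biological features, and (IV) depressive-like symptoms
(anhedonia plus additional symptoms) — and a DLS is called **present** only when
all four hold. The package is aimed at behavioral neuroscientists and
biostatisticians who phenotype chronic-stress mouse models and want
reproducible, disclosure-first syndrome calls.

## The statistics at the core

**Control-referenced z-scoring.** Each observation X is standardized against
the control group of the same read-out and session,

    z = (X − μ) / σ ,

sign-corrected so that positive z always means impairment, and averaged into a
composite

    Z = (z₁ + z₂ + … + z_k) / k ,

which stays in control-SD units and is comparable between studies.

**The MESP rule** (*minimum effect size plus p value*). A group difference only
counts as evidence when it is simultaneously significant **and** at least
moderate in size, in the impairment direction:

    p ≤ α (0.05)   and   |d| ≥ 0.5   (or Cohen's f² ≥ 0.25² for
                                      repeated-measures effects)

Cross-sectional read-outs use Welch's t test with Cohen's d; longitudinal
read-outs use the balanced mixed-design (group × session) ANOVA group effect
with f² = η²ₚ/(1 − η²ₚ). The conjunction is never more liberal than α alone.

**Classification.** Criteria are decided either on composite z-scores (default,
one MESP comparison per criterion/symptom) or read-out by read-out with
two-of-two binarization (both read-outs must pass; one of two is reported as
*inconsistent*; a post-hoc third measurement must be explicitly enabled and is
always disclosed). The verdict is PRESENT / INCOMPLETE / ABSENT, and every
group-of-interest animal is graded none / mild (0 < Z ≤ 1) / moderate
(1 < Z ≤ 2) / severe (Z > 2) on its composite z.

**Duration translation.** Human durations map linearly onto mouse time through
published anchor pairs (10 human months ↔ 52 mouse hours for young adults aged
10–64 weeks; ↔ 176.5 h for presenescent mice aged 65–72 weeks). The DSM/ICD
14-day criterion would translate to a biologically meaningless 2.4 h, which is
why the framework fixes a 7-day minimum phenotype duration instead.

## Worked example

```python
from mousedls import DLSClassifier, default_sim_config, simulate_cohort

cohort = simulate_cohort(default_sim_config(seed=7))   # d = 1.5, n = 12/group
clf = DLSClassifier().fit(cohort)
print(clf.verdict_.value)
for c in clf.criteria_:
    e = c.evidence[0]
    print(f"  {c.criterion.value:15s} {c.status.value:8s} "
          f"p={e.p_value:.4f} effect={e.effect_size:.2f}")
```

prints

```
present
  duration        present  p=0.0000 effect=1.28
  sociofunctional present  p=0.0000 effect=2.17
  biological      present  p=0.0017 effect=1.46
  symptoms        present  p=0.0007 effect=1.66
```

i.e. all four criteria meet the MESP thresholds (the duration effect is a
Cohen's f², the others Cohen's d on composite z-scores), so the simulated
chronic-stress cohort expresses a full DLS. `clf.per_animal_severity_` grades
each stressed animal (mostly *moderate* at an injected shift of 1.5 control
SDs).

The same pipeline runs from the shell:

```sh
mousedls simulate --out m.csv --config-out c.yaml --seed 7
mousedls classify --measurements m.csv --config c.yaml --out report.json
mousedls power --effect-d 1.5 --n-reps 200 --seed 1
mousedls translate-age --human-months 10 --age-class young_adult
```

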