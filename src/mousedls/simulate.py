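"""Synthetic chronic-stress cohort generator and operating characteristics.

Emulates the measurement tables a chronic-stress mouse study produces:
Gaussian read-outs with a compound-symmetry within-animal correlation
across sessions, a group effect expressed as a standardized shift (Cohen's
d) in the impairment direction, and an optional latent susceptible /
resilient split of the interest group.  Every generated dataset passes the
package's own validation, so the simulator can drive Monte-Carlo estimates
of the classifier's operating characteristics (type-I error under the null,
power under injected effects) without any real data.

Generative model per read-out with control mean m and SD s::

    value(animal, session) = m + b_animal + e_session (+ shift)
    b ~ N(0, rho * s^2),  e ~ N(0, (1 - rho) * s^2)
    shift = +/- d * s  for susceptible interest animals only

so the marginal distribution is N(m, s^2) for controls and the
within-animal correlation across sessions equals rho.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats
from .classifier import DLSClassifier, evaluate_readout
from .types import (
    CohortDataset,
    Direction,
    EffectKind,
    Group,
    MESPConfig,
    RDoCDomain,
    ReadoutCriterion,
    ReadoutSpec,
    Status,
    Verdict,
)

__all__ = [
    "ReadoutModel",
    "SimConfig",
    "default_readout_models",
    "default_sim_config",
    "simulate_cohort",
    "estimate_operating_characteristics",
    "null_mesp_pass_rate",
]


@dataclass(frozen=True)
class ReadoutModel:
    """Generative parameters plus configuration for one read-out."""

    spec: ReadoutSpec
    control_mean: float
    control_sd: float
    effect_d: float = 0.0
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ValueError("control_sd must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic cohort.

    Defaults describe a strongly affected chronic-stress cohort: 12 animals
    per group, three sessions at days 0/4/8 (an 8-day span, clearing the
    7-day minimum duration), within-animal correlation 0.5, the whole
    interest group susceptible, and an injected standardized shift of
    d = 1.5 on every read-out.  Set ``effect_d=0`` (via
    ``default_sim_config``) for a null cohort.
    """

    readout_models: Mapping[str, ReadoutModel]
    n_per_group: int = 12
    sessions: tuple[float, ...] = (0.0, 4.0, 8.0)
    within_animal_rho: float = 0.5
    susceptible_fraction: float = 1.0
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.within_animal_rho < 1:
            raise ValueError("within_animal_rho must lie in [0, 1)")
        if not 0 < self.susceptible_fraction <= 1:
            raise ValueError("susceptible_fraction must lie in (0, 1]")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not self.sessions:
            raise ValueError("at least one session is required")


def _spec(name, criterion, direction, domain, symptom, longitudinal=False):
    return ReadoutSpec(
        readout=name,
        criterion=criterion,
        direction=direction,
        rdoc_domain=domain,
        symptom_label=symptom,
        longitudinal=longitudinal,
    )


def default_readout_models(effect_d: float = 1.5) -> dict[str, ReadoutModel]:
    """The standard 12-read-out chronic-stress panel.

    Two longitudinal sociofunctional read-outs (social interaction-zone
    time, nest score) that also carry the duration criterion, two biological
    read-outs (plasma corticosterone, hippocampal BrdU+ cell count), two
    anhedonia read-outs (sucrose preference, urine sniffing time), and three
    additional symptoms with two read-outs each (weight loss: body weight
    and food intake; self-neglect: coat state score and grooming time;
    fatigue: open-field distance and wheel running).  ``effect_d`` is the
    standardized shift injected on every read-out in its impairment
    direction.
    """
    LOW, HIGH = Direction.LOWER_IS_IMPAIRED, Direction.HIGHER_IS_IMPAIRED
    C, D = ReadoutCriterion, RDoCDomain
    rows = [
        # name, criterion, direction, rdoc, symptom, longitudinal, mean, sd, bounds
        ("social_interaction_time", C.SOCIOFUNCTIONAL, LOW, D.SOCIAL_PROCESSES,
         "social_withdrawal", True, 120.0, 30.0, None),
        ("nest_score", C.SOCIOFUNCTIONAL, LOW, D.SOCIAL_PROCESSES,
         "functional_decline", True, 4.2, 0.7, None),
        ("corticosterone", C.BIOLOGICAL, HIGH, D.AROUSAL_REGULATION,
         "hpa_axis", False, 45.0, 12.0, None),
        ("brdu_cell_count", C.BIOLOGICAL, LOW, D.COGNITION,
         "neurogenesis", False, 250.0, 60.0, None),
        ("sucrose_preference", C.ANHEDONIA, LOW, D.POSITIVE_VALENCE,
         "anhedonia", False, 0.85, 0.08, (0.0, 1.0)),
        ("urine_sniffing_time", C.ANHEDONIA, LOW, D.POSITIVE_VALENCE,
         "anhedonia", False, 20.0, 6.0, None),
        ("body_weight", C.ADDITIONAL_SYMPTOM, LOW, D.AROUSAL_REGULATION,
         "weight_loss", False, 26.0, 2.5, None),
        ("food_intake", C.ADDITIONAL_SYMPTOM, LOW, D.AROUSAL_REGULATION,
         "weight_loss", False, 4.5, 0.8, None),
        ("coat_state_score", C.ADDITIONAL_SYMPTOM, HIGH, D.NEGATIVE_VALENCE,
         "self_neglect", False, 1.5, 0.6, None),
        ("grooming_time", C.ADDITIONAL_SYMPTOM, LOW, D.NEGATIVE_VALENCE,
         "self_neglect", False, 60.0, 18.0, None),
        ("open_field_distance", C.ADDITIONAL_SYMPTOM, LOW, D.SENSORIMOTOR,
         "fatigue", False, 35.0, 9.0, None),
        ("wheel_running", C.ADDITIONAL_SYMPTOM, LOW, D.SENSORIMOTOR,
         "fatigue", False, 4.0, 1.2, None),
    ]
    return {
        name: ReadoutModel(
            spec=_spec(name, crit, direction, domain, symptom, longitudinal),
            control_mean=mean,
            control_sd=sd,
            effect_d=effect_d,
            bounds=bounds,
        )
        for (name, crit, direction, domain, symptom,
             longitudinal, mean, sd, bounds) in rows
    }


def default_sim_config(effect_d: float = 1.5, **overrides) -> SimConfig:
    """Standard cohort conditions with an injected effect of ``effect_d``."""
    models = overrides.pop("readout_models", None) or default_readout_models(effect_d)
    return SimConfig(readout_models=models, **overrides)


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Generate one synthetic cohort; a pure function of ``config``.

    Longitudinal read-outs are sampled at every configured session;
    cross-sectional read-outs once, at the final session day.  Bounded
    read-outs (e.g. a preference ratio) are clipped to their bounds, which
    is recorded in the dataset metadata.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    width = max(2, len(str(2 * n)))
    animals = [f"I{str(i + 1).zfill(width)}" for i in range(n)] + [
        f"C{str(i + 1).zfill(width)}" for i in range(n)
    ]
    groups = np.array([Group.INTEREST.value] * n + [Group.CONTROL.value] * n)
    is_interest = np.arange(2 * n) < n
    susceptible = is_interest & (rng.random(2 * n) < config.susceptible_fraction)
    sexes = np.where(
        rng.random(2 * n) < config.sex_ratio, "female", "male"
    )

    rho = config.within_animal_rho
    frames = []
    clipped: list[str] = []
    last_day = max(config.sessions)
    for name, model in config.readout_models.items():
        days = tuple(config.sessions) if model.spec.longitudinal else (last_day,)
        k = len(days)
        sd = model.control_sd
        b = rng.normal(0.0, np.sqrt(rho) * sd, size=2 * n)
        e = rng.normal(0.0, np.sqrt(1.0 - rho) * sd, size=(2 * n, k))
        values = model.control_mean + b[:, None] + e
        if model.effect_d:
            sign = 1.0 if model.spec.direction is Direction.HIGHER_IS_IMPAIRED else -1.0
            values[susceptible] += sign * model.effect_d * sd
        if model.bounds is not None:
            lo, hi = model.bounds
            if (values < lo).any() or (values > hi).any():
                clipped.append(name)
            values = np.clip(values, lo, hi)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(animals, k),
                    "group": np.repeat(groups, k),
                    "sex": np.repeat(sexes, k),
                    "readout": name,
                    "session_day": np.tile(np.asarray(days, dtype=float), 2 * n),
                    "value": values.ravel(),
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    metadata = {
        "induction_protocol": "synthetic chronic-stress emulation (no real induction)",
        "simulated": True,
        "seed": config.seed,
    }
    if clipped:
        metadata["clipped_readouts"] = sorted(clipped)
    specs = [m.spec for m in config.readout_models.values()]
    return CohortDataset(frame, specs, metadata)


def _replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Deterministic per-replicate seeds: a counter-based spawn of the base
    seed sequence, folded below 2**31."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n_reps, dtype=np.uint32).astype(np.int64) % (2**31)


def estimate_operating_characteristics(
    config: SimConfig,
    n_reps: int,
    classifier: DLSClassifier | None = None,
    seed: int | None = None,
    readout_rates: bool = True,
) -> dict:
    """Monte-Carlo operating characteristics of the classifier.

    Simulates ``n_reps`` cohorts from ``config`` (replicate seeds derived
    from ``seed`` or ``config.seed``), classifies each, and returns overall
    verdict rates, per-criterion PRESENT rates and (optionally) per-read-out
    MESP pass rates, each with its binomial standard error
    sqrt(p * (1 - p) / n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    classifier = classifier or DLSClassifier()
    mesp = classifier._config()
    seeds = _replicate_seeds(config.seed if seed is None else seed, n_reps)

    verdict_counts = {v: 0 for v in Verdict}
    criterion_counts: dict[str, int] = {}
    readout_counts: dict[str, int] = {}
    for s in seeds:
        ds = simulate_cohort(dataclasses.replace(config, seed=int(s)))
        report = DLSClassifier(**classifier.get_params()).fit(ds).report_
        verdict_counts[report.verdict] += 1
        for c in report.criteria:
            key = c.criterion.value
            criterion_counts[key] = criterion_counts.get(key, 0) + (
                c.status is Status.PRESENT
            )
        if readout_rates:
            for name in config.readout_models:
                res = evaluate_readout(ds, name, mesp)
                readout_counts[name] = readout_counts.get(name, 0) + res.passes

    def rate(count: int) -> dict[str, float]:
        p = count / n_reps
        return {"rate": p, "se": float(np.sqrt(p * (1 - p) / n_reps))}

    out = {
        "n_reps": n_reps,
        "verdict_rates": {v.value: rate(c) for v, c in verdict_counts.items()},
        "criterion_present_rates": {k: rate(c) for k, c in criterion_counts.items()},
    }
    if readout_rates:
        out["readout_pass_rates"] = {k: rate(c) for k, c in readout_counts.items()}
    return out


def null_mesp_pass_rate(
    n_per_group: int = 12,
    n_reps: int = 10_000,
    seed: int = 0,
    config: MESPConfig | None = None,
) -> float:
    """Empirical single-read-out MESP pass rate under the null.

    Both groups are drawn i.i.d. from the same standard normal; each
    replicate applies the Welch test + Cohen's d MESP check (direction
    taken as higher-is-impaired, so a wrong-sign effect cannot pass).
    The MESP conjunction is never more liberal than alpha alone.
    """
    config = config or MESPConfig()
    rng = np.random.default_rng(seed)
    passes = 0
    for _ in range(n_reps):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        p = stats.welch_test(a, b)
        d = stats.cohens_d(a, b)
        res = stats.mesp_check(p, d, EffectKind.COHENS_D, d > 0, config)
        passes += res.passes
    return passes / n_reps
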