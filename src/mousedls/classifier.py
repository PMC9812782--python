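"""The DLS classification algorithm.

A cohort is classified on four criteria — minimum duration, sociofunctional
impairment, biological features, and depressive-like symptoms (anhedonia
plus additional symptoms) — each decided by MESP comparisons between the
group of interest and controls.  The overall verdict is PRESENT when the
required number of criteria are present, ABSENT when at least one criterion
is definitively absent, and INCOMPLETE otherwise (inconsistent or missing
evidence, always disclosed).  Every group-of-interest animal additionally
receives a severity grade from its composite z-score in control-SD units.

Two evaluation modes are offered:

``composite`` (default)
    Read-outs belonging to one criterion (or one symptom) are pooled into a
    per-animal composite z-score and a single MESP comparison decides the
    unit.  This is the recommended mode: the composite is standardized,
    comparable between studies, and averages out read-out-level noise.

``individual``
    Every read-out is tested on its own and presence is binarized by the
    two-of-two rule: both read-outs of a unit must pass; exactly one
    passing yields INCONSISTENT; with an explicitly allowed third
    (post-hoc augmented) measurement a majority decides, always disclosed.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import stats
from .types import (
    CohortDataset,
    UnbalancedPanelError,
    ConfigError,
    CriterionResult,
    DatasetValidationError,
    Direction,
    DLSCriterion,
    DLSReport,
    EffectKind,
    Group,
    MESPConfig,
    MESPResult,
    MultipleTesting,
    ReadoutCriterion,
    Severity,
    Status,
    Verdict,
    validate_dataset,
)

__all__ = [
    "DLSClassifier",
    "SeverityBands",
    "assign_severity",
    "binarize_symptom",
    "evaluate_readout",
    "evaluate_duration_criterion",
    "evaluate_simple_criterion",
    "evaluate_symptom_criterion",
    "classify_cohort",
]


class SeverityBands:
    """Severity bands on the composite z in control-SD units.

    Impairment within the first control SD is mild, within the second
    moderate, and beyond that severe; the third band is open-ended so every
    animal is classifiable.  Non-positive composite z means no impairment.
    """

    mild_upper: float = 1.0
    moderate_upper: float = 2.0

    @classmethod
    def grade(cls, z: float) -> Severity:
        if z <= 0:
            return Severity.NONE
        if z <= cls.mild_upper:
            return Severity.MILD
        if z <= cls.moderate_upper:
            return Severity.MODERATE
        return Severity.SEVERE


def assign_severity(composite_z: float, bands: type[SeverityBands] = SeverityBands) -> Severity:
    """Grade one animal's directional composite z-score."""
    return bands.grade(composite_z)


# ---------------------------------------------------------------------------
# prepared wide views (cached per dataset; all evaluations are numpy after)
# ---------------------------------------------------------------------------


class _Prepared:
    """Wide animal-indexed views of one dataset.

    ``value_wide`` / ``z_wide``: animals x (readout, session_day) matrices of
    raw values and directional z; ``mean_z``: animals x readouts mean
    directional z (each read-out weighted equally in composites).
    """

    def __init__(self, dataset: CohortDataset, config: MESPConfig):
        frame = dataset.frame
        scorer = stats.ControlZScorer(dataset.specs, sd_tolerance=config.sd_tolerance)
        zf = scorer.fit_transform(frame)
        self.value_wide = frame.pivot(
            index="animal_id", columns=["readout", "session_day"], values="value"
        )
        self.z_wide = zf.pivot(
            index="animal_id", columns=["readout", "session_day"], values="z"
        )
        groups = (
            frame.drop_duplicates("animal_id")
            .set_index("animal_id")["group"]
            .reindex(self.value_wide.index)
        )
        self.is_interest = (groups == Group.INTEREST.value).to_numpy()
        self.animals = self.value_wide.index
        # numpy views keyed by read-out for fast repeated access
        cols = self.value_wide.columns
        self._col_slices: dict[str, list[int]] = {}
        self._col_days: dict[str, np.ndarray] = {}
        for j, (readout, day) in enumerate(cols):
            self._col_slices.setdefault(readout, []).append(j)
        for readout, idx in self._col_slices.items():
            self._col_days[readout] = cols[idx].get_level_values("session_day").to_numpy()
        self._values = self.value_wide.to_numpy(dtype=float)
        self._z = self.z_wide.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            self._mean_z_by_readout = {
                r: np.nanmean(self._z[:, idx], axis=1)
                for r, idx in self._col_slices.items()
            }
        self.mean_z = pd.DataFrame(self._mean_z_by_readout, index=self.animals)
        self._panel_cache: dict[tuple, np.ndarray] = {}

    def n_sessions(self, readout: str) -> int:
        return len(self._col_slices[readout])

    def _rows(self, block: np.ndarray, interest: bool) -> np.ndarray:
        return block[self.is_interest if interest else ~self.is_interest]

    def values(self, readout: str, interest: bool) -> np.ndarray:
        """Per-animal values of one read-out (mean over its sessions)."""
        with np.errstate(invalid="ignore"):
            v = np.nanmean(self._values[:, self._col_slices[readout]], axis=1)
        v = self._rows(v[:, None], interest)[:, 0]
        return v[np.isfinite(v)]

    def panel(self, readout: str, interest: bool) -> np.ndarray:
        """animals x sessions value matrix of one longitudinal read-out."""
        return self._rows(self._values[:, self._col_slices[readout]], interest)

    def composite(self, readouts: Sequence[str], interest: bool) -> np.ndarray:
        """Per-animal composite z: mean of per-read-out mean directional z."""
        block = np.column_stack([self._mean_z_by_readout[r] for r in readouts])
        with np.errstate(invalid="ignore"):
            v = np.nanmean(self._rows(block, interest), axis=1)
        return v[np.isfinite(v)]

    def composite_panel(
        self, readouts: Sequence[str], interest: bool
    ) -> np.ndarray:
        """animals x sessions composite z (mean over read-outs per cell).

        Requires the read-outs to share one session grid (validated for
        longitudinal read-outs)."""
        key = (tuple(readouts), interest)
        cached = self._panel_cache.get(key)
        if cached is not None:
            return cached
        days0 = self._col_days[readouts[0]]
        blocks = []
        for r in readouts:
            days = self._col_days[r]
            if len(days) != len(days0) or not np.array_equal(days, days0):
                raise UnbalancedPanelError(
                    "longitudinal read-outs do not share a common session grid"
                )
            blocks.append(self._z[:, self._col_slices[r]])
        with np.errstate(invalid="ignore"):
            cell = np.nanmean(np.stack(blocks), axis=0)
        out = self._rows(cell, interest)
        self._panel_cache[key] = out
        return out


def _prepare(dataset: CohortDataset, config: MESPConfig) -> _Prepared:
    cached = getattr(dataset, "_prepared_cache", None)
    if cached is None:
        cached = _Prepared(dataset, config)
        dataset._prepared_cache = cached
    return cached


def evaluate_readout(
    dataset: CohortDataset, readout: str, config: MESPConfig
) -> MESPResult:
    """MESP comparison of one read-out between interest and control groups.

    Cross-sectional read-outs use the Welch test and Cohen's d on per-animal
    values (averaged over sessions if several).  Longitudinal read-outs with
    at least two sessions use the repeated-measures group effect and Cohen's
    f^2 from partial eta^2; with a single session they fall back to the
    cross-sectional route.
    """
    spec = dataset.specs[readout]
    pr = _prepare(dataset, config)
    n_sessions = pr.n_sessions(readout)
    if spec.longitudinal and n_sessions >= 2:
        a = pr.panel(readout, True)
        b = pr.panel(readout, False)
        p, eta_p2 = stats.rm_group_effect(a, b, sd_tolerance=config.sd_tolerance)
        effect = stats.eta2_to_f2(eta_p2) if eta_p2 < 1 else float("inf")
        diff = a.mean() - b.mean()
        kind = EffectKind.COHENS_F2
    else:
        av = pr.values(readout, True)
        bv = pr.values(readout, False)
        p = stats.welch_test(av, bv)
        effect = stats.cohens_d(av, bv, sd_tolerance=config.sd_tolerance)
        diff = effect
        kind = EffectKind.COHENS_D
    if spec.direction is Direction.HIGHER_IS_IMPAIRED:
        consistent = diff > 0
    else:
        consistent = diff < 0
    return stats.mesp_check(p, effect, kind, consistent, config, readout=readout)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize_symptom(
    results: Sequence[MESPResult], allow_augmentation: bool = False
) -> tuple[Status, list[str]]:
    """Binarize one symptom (or one criterion's read-out set).

    Two read-outs: both passing -> PRESENT, exactly one -> INCONSISTENT,
    none -> ABSENT.  Three read-outs are a post-hoc augmentation (must be
    explicitly allowed, always disclosed): a majority of passes decides.
    A single read-out is permitted with a mandatory disclosure and decides
    directly.
    """
    results = list(results)
    n = len(results)
    if n == 0 or n > 3:
        raise ValueError(f"binarize_symptom takes 1-3 results, got {n}")
    n_pass = sum(r.passes for r in results)
    notes: list[str] = []
    if n == 1:
        notes.append(
            "single read-out only; two read-outs per symptom are recommended"
        )
        return (Status.PRESENT if n_pass == 1 else Status.ABSENT), notes
    if n == 2:
        if n_pass == 2:
            return Status.PRESENT, notes
        if n_pass == 1:
            notes.append(
                "inconsistent evidence: one of two read-outs meets the MESP criteria"
            )
            return Status.INCONSISTENT, notes
        return Status.ABSENT, notes
    # n == 3: augmented third measurement
    if not allow_augmentation:
        raise ConfigError(
            "three read-outs supplied but post-hoc augmentation is not enabled "
            "(set allow_augmentation=True; augmentation requires strict blinding)"
        )
    notes.append(
        "post-hoc augmentation: a third measurement was added; decision by majority "
        "(perform only under strict blinding)"
    )
    return (Status.PRESENT if n_pass >= 2 else Status.ABSENT), notes


def _apply_holm(results: list[MESPResult], config: MESPConfig) -> list[MESPResult]:
    """Re-check MESP with Holm-adjusted p values within one criterion."""
    if config.multiple_testing is not MultipleTesting.HOLM_WITHIN_CRITERION:
        return results
    adj = stats.holm_adjust([r.p_value for r in results])
    return [
        stats.mesp_check(
            min(p, 1.0), r.effect_size, r.effect_kind, r.direction_consistent,
            config, readout=r.readout,
        )
        for r, p in zip(results, adj)
    ]


# ---------------------------------------------------------------------------
# composite z machinery
# ---------------------------------------------------------------------------


def _composite_mesp(
    dataset: CohortDataset,
    readouts: Sequence[str],
    config: MESPConfig,
    label: str,
) -> MESPResult:
    """Single MESP comparison on the pooled composite z of ``readouts``."""
    pr = _prepare(dataset, config)
    a = pr.composite(readouts, True)
    b = pr.composite(readouts, False)
    p = stats.welch_test(a, b)
    d = stats.cohens_d(a, b, sd_tolerance=config.sd_tolerance)
    # the composite is already impairment-positive, so a positive shift of
    # the interest group is the consistent direction
    return stats.mesp_check(
        p, d, EffectKind.COHENS_D, d > 0, config, readout=f"composite:{label}"
    )


def _composite_panels(
    dataset: CohortDataset, readouts: Sequence[str], config: MESPConfig
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-animal x session composite z panels (interest, control) plus a
    positive-direction flag (interest composite mean above control)."""
    pr = _prepare(dataset, config)
    a = pr.composite_panel(readouts, True)
    b = pr.composite_panel(readouts, False)
    return a, b, a.mean() > b.mean()


# ---------------------------------------------------------------------------
# criterion evaluations
# ---------------------------------------------------------------------------


def evaluate_duration_criterion(
    dataset: CohortDataset,
    config: MESPConfig,
    mode: str = "composite",
    duration_mode: str = "overall",
) -> CriterionResult:
    """Minimum-duration criterion.

    PRESENT requires (a) the longitudinal sessions to span at least
    ``min_duration_days`` and (b) the longitudinal evidence to meet MESP.
    ``duration_mode='overall'`` tests the repeated-measures group effect
    (on the composite z series by default, per read-out in individual
    mode); ``'per_timepoint'`` requires every session's cross-sectional
    comparison to pass.  A span below the minimum is ABSENT regardless of
    statistics; no longitudinal read-out means the criterion cannot be
    assessed.
    """
    longitudinal = dataset.longitudinal_readouts()
    crit = DLSCriterion.DURATION
    if not longitudinal:
        return CriterionResult(
            crit, Status.NOT_ASSESSED,
            notes=("no longitudinal read-out configured; duration cannot be assessed",),
        )
    frame = dataset.frame
    sub = frame[frame["readout"].isin(longitudinal)]
    days = np.sort(sub["session_day"].unique())
    span = float(days[-1] - days[0])
    notes: list[str] = []
    shared = [
        r for r in longitudinal
        if dataset.specs[r].criterion is ReadoutCriterion.SOCIOFUNCTIONAL
    ]
    if shared:
        notes.append(
            "duration evidence shared with the sociofunctional criterion: "
            + ", ".join(shared)
        )
    if len(days) < 2:
        return CriterionResult(
            crit, Status.NOT_ASSESSED,
            notes=tuple(notes) + ("fewer than 2 sessions; duration cannot be assessed",),
        )
    if span < config.min_duration_days:
        return CriterionResult(
            crit, Status.ABSENT,
            notes=tuple(notes)
            + (
                f"observed span {span:g} days is below the minimum duration of "
                f"{config.min_duration_days:g} days",
            ),
        )

    if duration_mode == "per_timepoint":
        pr = _prepare(dataset, config)
        results = []
        for j, day in enumerate(days):
            if mode == "composite":
                a = pr.composite_panel(longitudinal, True)[:, j]
                b = pr.composite_panel(longitudinal, False)[:, j]
                p = stats.welch_test(a, b)
                d = stats.cohens_d(a, b, sd_tolerance=config.sd_tolerance)
                results.append(
                    stats.mesp_check(
                        p, d, EffectKind.COHENS_D, d > 0, config,
                        readout=f"composite:duration@day{day:g}",
                    )
                )
            else:
                results.append(_all_pass_day(pr, dataset, longitudinal, config, day))
        if mode == "composite":
            results = _apply_holm(results, config)
        n_pass = sum(r.passes for r in results)
        if n_pass == len(results):
            status = Status.PRESENT
        elif n_pass == 0:
            status = Status.ABSENT
        else:
            status = Status.INCONSISTENT
            notes.append("per-timepoint evidence inconsistent across sessions")
        return CriterionResult(crit, status, tuple(results), tuple(notes))

    if duration_mode != "overall":
        raise ConfigError(f"unknown duration_mode {duration_mode!r}")

    if mode == "composite":
        a, b, positive = _composite_panels(dataset, longitudinal, config)
        p, eta_p2 = stats.rm_group_effect(a, b, sd_tolerance=config.sd_tolerance)
        f2 = stats.eta2_to_f2(eta_p2) if eta_p2 < 1 else float("inf")
        res = stats.mesp_check(
            p, f2, EffectKind.COHENS_F2, positive, config,
            readout="composite:duration",
        )
        notes.append("composite z-score mode: longitudinal read-outs pooled")
        status = Status.PRESENT if res.passes else Status.ABSENT
        return CriterionResult(crit, status, (res,), tuple(notes))

    results = [evaluate_readout(dataset, r, config) for r in longitudinal]
    results = _apply_holm(results, config)
    n_pass = sum(r.passes for r in results)
    if n_pass == len(results):
        status = Status.PRESENT
    elif n_pass == 0:
        status = Status.ABSENT
    else:
        status = Status.INCONSISTENT
        notes.append("longitudinal read-outs disagree on the MESP criteria")
    return CriterionResult(crit, status, tuple(results), tuple(notes))


def _all_pass_day(pr, dataset, longitudinal, config, day):
    """Individual-mode per-timepoint check: all read-outs must pass that day;
    folded into a single synthetic MESP result carrying the worst p."""
    results = []
    for r in longitudinal:
        a = pr.value_wide[(r, day)].to_numpy(dtype=float)[pr.is_interest]
        b = pr.value_wide[(r, day)].to_numpy(dtype=float)[~pr.is_interest]
        p = stats.welch_test(a, b)
        d = stats.cohens_d(a, b, sd_tolerance=config.sd_tolerance)
        spec = dataset.specs[r]
        consistent = d > 0 if spec.direction is Direction.HIGHER_IS_IMPAIRED else d < 0
        results.append(
            stats.mesp_check(p, d, EffectKind.COHENS_D, consistent, config, readout=r)
        )
    worst = max(results, key=lambda r: r.p_value)
    all_pass = all(r.passes for r in results)
    return MESPResult(
        readout=f"day{day:g}",
        p_value=worst.p_value,
        effect_size=worst.effect_size,
        effect_kind=worst.effect_kind,
        direction_consistent=worst.direction_consistent,
        passes=all_pass,
    )


_CRITERION_MAP = {
    DLSCriterion.SOCIOFUNCTIONAL: ReadoutCriterion.SOCIOFUNCTIONAL,
    DLSCriterion.BIOLOGICAL: ReadoutCriterion.BIOLOGICAL,
}


def evaluate_simple_criterion(
    dataset: CohortDataset,
    criterion: DLSCriterion | str,
    config: MESPConfig,
    mode: str = "composite",
) -> CriterionResult:
    """Sociofunctional-impairment or biological-features criterion.

    Composite mode pools the criterion's read-outs into a per-animal
    composite z and applies one MESP comparison.  Individual mode applies
    the two-of-two binarization to per-read-out MESP results.  At least two
    read-outs are recommended; a single one is allowed with disclosure.
    """
    criterion = DLSCriterion(criterion)
    want = _CRITERION_MAP[criterion]
    readouts = sorted(
        r for r, s in dataset.specs.items() if s.criterion is want
    )
    if not readouts:
        return CriterionResult(
            criterion, Status.NOT_ASSESSED,
            notes=(f"no read-out configured for the {criterion.value} criterion",),
        )
    notes: list[str] = []
    if len(readouts) == 1:
        notes.append(
            f"single read-out for {criterion.value}; two are recommended"
        )
    if mode == "composite":
        res = _composite_mesp(dataset, readouts, config, criterion.value)
        notes.append("composite z-score mode: read-outs pooled into one comparison")
        status = Status.PRESENT if res.passes else Status.ABSENT
        return CriterionResult(criterion, status, (res,), tuple(notes))
    results = [evaluate_readout(dataset, r, config) for r in readouts]
    results = _apply_holm(results, config)
    status, bnotes = binarize_symptom(results, config.allow_augmentation)
    return CriterionResult(criterion, status, tuple(results), tuple(notes + bnotes))


def evaluate_symptom_criterion(
    dataset: CohortDataset,
    config: MESPConfig,
    mode: str = "composite",
) -> CriterionResult:
    """Depressive-like-symptoms criterion: anhedonia plus additional symptoms.

    Anhedonia is the mandatory core symptom: if absent, the criterion is
    absent no matter how many other symptoms are present.  With anhedonia
    present, at least ``n_additional_symptoms`` distinct additional symptoms
    must also be present; a shortfall that inconsistent symptoms could still
    close yields INCONSISTENT.
    """
    crit = DLSCriterion.SYMPTOMS
    by_symptom: dict[str, list[str]] = defaultdict(list)
    anhedonia_label: str | None = None
    for r, s in sorted(dataset.specs.items()):
        if s.criterion is ReadoutCriterion.ANHEDONIA:
            anhedonia_label = s.symptom_label
            by_symptom[s.symptom_label].append(r)
        elif s.criterion is ReadoutCriterion.ADDITIONAL_SYMPTOM:
            by_symptom[s.symptom_label].append(r)
    if anhedonia_label is None:
        return CriterionResult(
            crit, Status.NOT_ASSESSED,
            notes=("anhedonia (the core symptom) is not configured",),
        )

    statuses: dict[str, Status] = {}
    evidence: list[MESPResult] = []
    notes: list[str] = []
    for label, readouts in sorted(by_symptom.items()):
        if mode == "composite":
            res = _composite_mesp(dataset, readouts, config, label)
            evidence.append(res)
            statuses[label] = Status.PRESENT if res.passes else Status.ABSENT
            if len(readouts) == 1:
                notes.append(f"symptom {label!r}: single read-out; two recommended")
        else:
            results = [evaluate_readout(dataset, r, config) for r in readouts]
            results = _apply_holm(results, config)
            status, bnotes = binarize_symptom(results, config.allow_augmentation)
            evidence.extend(results)
            statuses[label] = status
            notes.extend(f"symptom {label!r}: {n}" for n in bnotes)
        notes.append(f"symptom {label!r}: {statuses[label].value}")
    if mode == "composite":
        notes.append("composite z-score mode: one comparison per symptom")

    core = statuses[anhedonia_label]
    additional = {k: v for k, v in statuses.items() if k != anhedonia_label}
    n_present = sum(v is Status.PRESENT for v in additional.values())
    n_open = sum(v is Status.INCONSISTENT for v in additional.values())
    need = config.n_additional_symptoms

    if core is Status.ABSENT:
        status = Status.ABSENT
        notes.append("anhedonia absent: the core symptom rule fails the criterion")
    elif core is Status.INCONSISTENT:
        status = Status.INCONSISTENT
        notes.append("anhedonia evidence inconsistent; criterion pending")
    elif n_present >= need:
        status = Status.PRESENT
    elif n_present + n_open >= need:
        status = Status.INCONSISTENT
        notes.append(
            f"{n_present} of {need} additional symptoms present; "
            f"{n_open} inconsistent symptom(s) could still close the gap"
        )
    else:
        status = Status.ABSENT
        notes.append(f"only {n_present} of {need} additional symptoms present")
    return CriterionResult(crit, status, tuple(evidence), tuple(notes))


# ---------------------------------------------------------------------------
# severity and the full classifier
# ---------------------------------------------------------------------------


def _severity_map(
    dataset: CohortDataset, config: MESPConfig
) -> tuple[dict[str, Severity], dict[str, float]]:
    # every configured criterion read-out contributes to the composite
    pr = _prepare(dataset, config)
    composite = pr.mean_z.mean(axis=1)[pr.is_interest]
    severity = {a: assign_severity(float(z)) for a, z in composite.items()}
    return severity, {a: float(z) for a, z in composite.items()}


class DLSClassifier(BaseEstimator):
    """Group-level DLS classifier with per-animal severity grading.

    scikit-learn-style estimator: thresholds are constructor parameters,
    ``fit(dataset)`` runs the four criterion evaluations and exposes the
    results as fitted attributes (``report_``, ``verdict_``, ``criteria_``,
    ``per_animal_severity_``).

    Parameters
    ----------
    alpha : float, default 0.05
        MESP significance threshold.
    d_threshold : float, default 0.5
        Minimum |Cohen's d| (moderate effect).
    f2_threshold : float, default 0.0625
        Minimum Cohen's f^2 for repeated-measures effects (0.25 squared,
        literal; 0.15 is the conventional moderate f^2).
    min_duration_days : float, default 7
        Minimum span of the longitudinal sessions.
    n_additional_symptoms : int, default 3
        Additional depression-typical symptoms required besides anhedonia.
    n_criteria_required : int, default 4
        Criteria that must be PRESENT for a syndrome verdict.
    mode : {'composite', 'individual'}, default 'composite'
        Pool read-outs into composite z-scores (recommended) or binarize
        per read-out.
    duration_mode : {'overall', 'per_timepoint'}, default 'overall'
        Repeated-measures group effect over the whole span, or a
        cross-sectional pass at every session.
    multiple_testing : {'none', 'holm_within_criterion'}, default 'none'
        Optional post-hoc correction within each criterion's evidence.
    allow_augmentation : bool, default False
        Permit a third, post-hoc measurement per symptom (always disclosed).

    Examples
    --------
    >>> from mousedls.simulate import default_sim_config, simulate_cohort
    >>> clf = DLSClassifier().fit(simulate_cohort(default_sim_config(seed=7)))
    >>> clf.verdict_
    <Verdict.PRESENT: 'present'>
    """

    def __init__(
        self,
        alpha: float = 0.05,
        d_threshold: float = 0.5,
        f2_threshold: float = 0.0625,
        min_duration_days: float = 7.0,
        n_additional_symptoms: int = 3,
        n_criteria_required: int = 4,
        mode: str = "composite",
        duration_mode: str = "overall",
        multiple_testing: str = "none",
        allow_augmentation: bool = False,
        sd_tolerance: float = 1e-12,
    ):
        self.alpha = alpha
        self.d_threshold = d_threshold
        self.f2_threshold = f2_threshold
        self.min_duration_days = min_duration_days
        self.n_additional_symptoms = n_additional_symptoms
        self.n_criteria_required = n_criteria_required
        self.mode = mode
        self.duration_mode = duration_mode
        self.multiple_testing = multiple_testing
        self.allow_augmentation = allow_augmentation
        self.sd_tolerance = sd_tolerance

    def _config(self) -> MESPConfig:
        return MESPConfig(
            alpha=self.alpha,
            d_threshold=self.d_threshold,
            f2_threshold=self.f2_threshold,
            min_duration_days=self.min_duration_days,
            n_additional_symptoms=self.n_additional_symptoms,
            n_criteria_required=self.n_criteria_required,
            multiple_testing=MultipleTesting(self.multiple_testing),
            allow_augmentation=self.allow_augmentation,
            sd_tolerance=self.sd_tolerance,
        )

    @classmethod
    def from_config(cls, config: MESPConfig, **kwargs) -> "DLSClassifier":
        return cls(
            alpha=config.alpha,
            d_threshold=config.d_threshold,
            f2_threshold=config.f2_threshold,
            min_duration_days=config.min_duration_days,
            n_additional_symptoms=config.n_additional_symptoms,
            n_criteria_required=config.n_criteria_required,
            multiple_testing=config.multiple_testing.value,
            allow_augmentation=config.allow_augmentation,
            sd_tolerance=config.sd_tolerance,
            **kwargs,
        )

    def fit(self, dataset: CohortDataset, y=None) -> "DLSClassifier":
        """Classify a cohort; the dataset must pass validation (warnings are
        carried into the report, errors abort)."""
        if self.mode not in ("composite", "individual"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        config = self._config()
        findings = validate_dataset(dataset)
        errors = [f for f in findings if f.level == "error"]
        if errors:
            raise DatasetValidationError(errors)
        disclosures = [f.message for f in findings if f.level == "warning"]

        criteria = (
            evaluate_duration_criterion(
                dataset, config, mode=self.mode, duration_mode=self.duration_mode
            ),
            evaluate_simple_criterion(
                dataset, DLSCriterion.SOCIOFUNCTIONAL, config, mode=self.mode
            ),
            evaluate_simple_criterion(
                dataset, DLSCriterion.BIOLOGICAL, config, mode=self.mode
            ),
            evaluate_symptom_criterion(dataset, config, mode=self.mode),
        )
        statuses = [c.status for c in criteria]
        n_present = sum(s is Status.PRESENT for s in statuses)
        if n_present >= config.n_criteria_required:
            verdict = Verdict.PRESENT
        elif any(s is Status.ABSENT for s in statuses):
            # a definitively failed criterion cannot be rescued by resolving
            # inconsistencies elsewhere; pending items are still disclosed
            verdict = Verdict.ABSENT
        else:
            verdict = Verdict.INCOMPLETE

        for c in criteria:
            disclosures.extend(f"{c.criterion.value}: {n}" for n in c.notes)
            if c.status in (Status.INCONSISTENT, Status.NOT_ASSESSED):
                disclosures.append(
                    f"criterion {c.criterion.value} is {c.status.value}; "
                    "findings disclosed, not counted as present"
                )

        severity, composite = _severity_map(dataset, config)
        report = DLSReport(
            verdict=verdict,
            criteria=criteria,
            per_animal_severity=severity,
            per_animal_composite_z=composite,
            severity_if_present=severity if verdict is Verdict.PRESENT else {},
            config=config,
            disclosures=tuple(disclosures),
            metadata=dict(dataset.metadata),
        )
        self.report_ = report
        self.verdict_ = verdict
        self.criteria_ = criteria
        self.per_animal_severity_ = severity
        self.per_animal_composite_z_ = composite
        self.disclosures_ = tuple(disclosures)
        return self

    def predict(self, dataset: CohortDataset | None = None) -> Verdict:
        """Verdict for ``dataset`` (classifies it) or of the fitted cohort."""
        if dataset is not None:
            return type(self)(**self.get_params()).fit(dataset).verdict_
        if not hasattr(self, "verdict_"):
            raise RuntimeError("DLSClassifier is not fitted")
        return self.verdict_


def classify_cohort(
    dataset: CohortDataset, config: MESPConfig | None = None, **kwargs
) -> DLSReport:
    """Classify a cohort and return the full report (functional wrapper)."""
    config = config or MESPConfig()
    return DLSClassifier.from_config(config, **kwargs).fit(dataset).report_
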