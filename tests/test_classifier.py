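"""Decision logic: binarization, criterion rules, verdicts, severity."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from conftest import make_frame, models_with_effects, simple_spec
from mousedls.classifier import (
    DLSClassifier,
    assign_severity,
    binarize_symptom,
    classify_cohort,
    evaluate_duration_criterion,
    evaluate_readout,
    evaluate_symptom_criterion,
)
from mousedls.simulate import default_sim_config, simulate_cohort
from mousedls.types import (
    CohortDataset,
    ConfigError,
    DatasetValidationError,
    Direction,
    DLSCriterion,
    EffectKind,
    MESPConfig,
    MESPResult,
    ReadoutCriterion,
    Severity,
    Status,
    Verdict,
)


def res(passes, readout="r", p=0.01, d=1.0):
    return MESPResult(
        readout=readout,
        p_value=p if passes else 0.5,
        effect_size=d,
        effect_kind=EffectKind.COHENS_D,
        direction_consistent=True,
        passes=passes,
    )


class TestBinarizeSymptom:
    def test_both_pass_is_present(self):
        status, _ = binarize_symptom([res(True), res(True)])
        assert status is Status.PRESENT

    def test_one_of_two_is_inconsistent(self):
        status, notes = binarize_symptom([res(True), res(False)])
        assert status is Status.INCONSISTENT
        assert notes

    def test_none_pass_is_absent(self):
        status, _ = binarize_symptom([res(False), res(False)])
        assert status is Status.ABSENT

    def test_augmented_majority_is_present_with_disclosure(self):
        status, notes = binarize_symptom(
            [res(True), res(False), res(True)], allow_augmentation=True
        )
        assert status is Status.PRESENT
        assert any("augmentation" in n for n in notes)

    def test_augmented_minority_is_absent(self):
        status, notes = binarize_symptom(
            [res(True), res(False), res(False)], allow_augmentation=True
        )
        assert status is Status.ABSENT
        assert any("augmentation" in n for n in notes)

    def test_third_readout_requires_explicit_flag(self):
        with pytest.raises(ConfigError):
            binarize_symptom([res(True)] * 3)

    def test_single_readout_decides_with_disclosure(self):
        status, notes = binarize_symptom([res(True)])
        assert status is Status.PRESENT
        assert any("single read-out" in n for n in notes)

    @pytest.mark.parametrize("n", [0, 4])
    def test_wrong_cardinality_raises(self, n):
        with pytest.raises(ValueError):
            binarize_symptom([res(True)] * n)

    def test_removing_passing_evidence_never_upgrades(self):
        """Dropping a passing read-out can only hold or lower the status."""
        order = {Status.ABSENT: 0, Status.INCONSISTENT: 1, Status.PRESENT: 2}
        for flags in [(True, True), (True, False), (True, True, True)]:
            full, _ = binarize_symptom(list(map(res, flags)), allow_augmentation=True)
            kept = [res(f) for f in flags if not f] + [res(True)] * (
                sum(flags) - 1
            )
            if not 1 <= len(kept) <= 3:
                continue
            reduced, _ = binarize_symptom(kept, allow_augmentation=True)
            assert order[reduced] <= order[full]


class TestSeverity:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (0.5, Severity.MILD),
            (1.5, Severity.MODERATE),
            (2.5, Severity.SEVERE),
            (-0.3, Severity.NONE),
            (0.0, Severity.NONE),
            (1.0, Severity.MILD),
            (2.0, Severity.MODERATE),
        ],
    )
    def test_band_examples(self, z, expected):
        assert assign_severity(z) is expected

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(deadline=None)
    def test_bands_partition_and_are_monotone(self, z):
        order = [Severity.NONE, Severity.MILD, Severity.MODERATE, Severity.SEVERE]
        s = assign_severity(z)
        assert s in order
        # non-decreasing in z
        assert order.index(assign_severity(z + 0.5)) >= order.index(s)


class TestEvaluateReadout:
    def test_identical_samples_fail_with_zero_effect(self):
        rows = []
        for i, v in enumerate([1.0, 2.0, 3.0]):
            rows.append((f"I{i}", "interest", "cort", 0, v))
            rows.append((f"C{i}", "control", "cort", 0, v))
        rows += [(f"{g}{i}", gr, "sucrose", 0, 0.8 + 0.01 * i)
                 for g, gr in (("I", "interest"), ("C", "control")) for i in range(3)]
        specs = [
            simple_spec("cort", symptom="hpa"),
            simple_spec("sucrose", criterion=ReadoutCriterion.ANHEDONIA,
                        direction=Direction.LOWER_IS_IMPAIRED, symptom="anhedonia"),
        ]
        ds = CohortDataset(make_frame(rows), specs)
        out = evaluate_readout(ds, "cort", MESPConfig())
        assert not out.passes
        assert out.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_lower_is_impaired_direction_convention(self, strong_cohort):
        out = evaluate_readout(strong_cohort, "sucrose_preference", MESPConfig())
        assert out.direction_consistent  # interest mean is lower
        assert out.effect_size < 0

    def test_longitudinal_readout_reports_f2(self, strong_cohort):
        out = evaluate_readout(strong_cohort, "social_interaction_time", MESPConfig())
        assert out.effect_kind is EffectKind.COHENS_F2
        assert out.passes

    def test_strong_effect_passes(self, strong_cohort):
        out = evaluate_readout(strong_cohort, "corticosterone", MESPConfig())
        assert out.passes


class TestDurationCriterion:
    def test_short_span_is_absent_regardless_of_statistics(self):
        ds = simulate_cohort(default_sim_config(seed=5, sessions=(0.0, 5.0)))
        out = evaluate_duration_criterion(ds, MESPConfig())
        assert out.status is Status.ABSENT
        assert any("below the minimum duration" in n for n in out.notes)

    def test_no_longitudinal_readout_is_not_assessed(self, tiny_dataset):
        out = evaluate_duration_criterion(tiny_dataset, MESPConfig())
        assert out.status is Status.NOT_ASSESSED

    def test_persistent_effect_is_present(self, strong_cohort):
        out = evaluate_duration_criterion(strong_cohort, MESPConfig())
        assert out.status is Status.PRESENT

    def test_per_timepoint_mode_tests_every_session(self, strong_cohort):
        out = evaluate_duration_criterion(
            strong_cohort, MESPConfig(), duration_mode="per_timepoint"
        )
        assert len(out.evidence) == 3  # one comparison per session
        assert out.status is Status.PRESENT

    def test_shared_sociofunctional_evidence_is_disclosed(self, strong_cohort):
        out = evaluate_duration_criterion(strong_cohort, MESPConfig())
        assert any("shared with the sociofunctional" in n for n in out.notes)


class TestSymptomCriterion:
    def test_anhedonia_absent_fails_criterion_despite_other_symptoms(self):
        models = models_with_effects(
            {"sucrose_preference": 0.0, "urine_sniffing_time": 0.0}
        )
        ds = simulate_cohort(default_sim_config(readout_models=models, seed=21))
        out = evaluate_symptom_criterion(ds, MESPConfig())
        assert out.status is Status.ABSENT
        assert any("anhedonia absent" in n for n in out.notes)

    def test_all_symptoms_strong_is_present(self, strong_cohort):
        out = evaluate_symptom_criterion(strong_cohort, MESPConfig())
        assert out.status is Status.PRESENT

    def test_inconsistent_additional_symptom_keeps_criterion_open(self):
        # fatigue symptom: one read-out shifted strongly, the other not at all
        models = models_with_effects(
            {"open_field_distance": 3.0, "wheel_running": 0.0}, base_d=2.5
        )
        ds = simulate_cohort(default_sim_config(readout_models=models, seed=33))
        out = evaluate_symptom_criterion(ds, MESPConfig(), mode="individual")
        assert out.status is Status.INCONSISTENT


class TestClassifier:
    def test_strong_cohort_is_present(self, strong_cohort):
        clf = DLSClassifier().fit(strong_cohort)
        assert clf.verdict_ is Verdict.PRESENT
        assert all(c.status is Status.PRESENT for c in clf.criteria_)

    def test_null_cohort_is_not_present(self, null_cohort):
        assert DLSClassifier().fit(null_cohort).verdict_ is not Verdict.PRESENT

    def test_anhedonia_knockout_yields_absent(self):
        models = models_with_effects(
            {"sucrose_preference": 0.0, "urine_sniffing_time": 0.0}
        )
        ds = simulate_cohort(default_sim_config(readout_models=models, seed=21))
        report = classify_cohort(ds)
        assert report.verdict is Verdict.ABSENT
        assert report.criterion(DLSCriterion.SYMPTOMS).status is Status.ABSENT

    def test_inconsistent_without_absent_is_incomplete(self):
        models = models_with_effects(
            {"open_field_distance": 3.0, "wheel_running": 0.0}, base_d=2.5
        )
        ds = simulate_cohort(default_sim_config(readout_models=models, seed=33))
        report = classify_cohort(ds, mode="individual")
        assert report.verdict is Verdict.INCOMPLETE
        assert any("inconsistent" in d for d in report.disclosures)

    def test_verdict_is_deterministic(self, strong_cohort):
        r1 = classify_cohort(strong_cohort)
        r2 = classify_cohort(strong_cohort)
        assert r1.to_dict() == r2.to_dict()

    def test_severity_for_every_interest_animal(self, strong_cohort):
        clf = DLSClassifier().fit(strong_cohort)
        assert set(clf.per_animal_severity_) == set(strong_cohort.animals("interest"))
        # bands are non-decreasing in composite z
        pairs = sorted(
            clf.per_animal_composite_z_.items(), key=lambda kv: kv[1]
        )
        order = [Severity.NONE, Severity.MILD, Severity.MODERATE, Severity.SEVERE]
        ranks = [order.index(clf.per_animal_severity_[a]) for a, _ in pairs]
        assert ranks == sorted(ranks)

    def test_severity_if_present_only_when_verdict_present(
        self, strong_cohort, null_cohort
    ):
        assert DLSClassifier().fit(strong_cohort).report_.severity_if_present
        assert not DLSClassifier().fit(null_cohort).report_.severity_if_present

    def test_validation_errors_abort(self, strong_cohort):
        frame = strong_cohort.frame
        bad = CohortDataset(
            frame[frame["group"] == "interest"], strong_cohort.specs.values()
        )
        with pytest.raises(DatasetValidationError):
            DLSClassifier().fit(bad)

    def test_sklearn_param_contract(self):
        clf = DLSClassifier(alpha=0.01, mode="individual")
        params = clf.get_params()
        assert params["alpha"] == 0.01
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(alpha=0.05)
        assert cloned.alpha == 0.05

    def test_config_echo_and_metadata_in_report(self, strong_cohort):
        report = classify_cohort(strong_cohort)
        assert report.config == MESPConfig()
        assert "induction_protocol" in report.metadata
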