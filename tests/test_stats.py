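"""Statistical primitives against independent oracles and known arithmetic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from mousedls.stats import (
    cohens_d,
    composite_z,
    eta2_to_f2,
    mesp_check,
    rm_group_effect,
    welch_test,
    z_test,
)
from mousedls.types import (
    ControlReference,
    DegenerateControlError,
    EffectKind,
    MESPConfig,
    UnbalancedPanelError,
)


def ref(mu, sigma, readout="r"):
    return ControlReference(readout=readout, session_day=0.0, mu=mu, sigma=sigma, n_control=5)


class TestZTest:
    @pytest.mark.parametrize(
        "value,mu,sigma,expected",
        [(13.0, 10.0, 2.0, 1.5), (10.0, 10.0, 2.0, 0.0), (8.0, 10.0, 2.0, -1.0)],
    )
    def test_arithmetic(self, value, mu, sigma, expected):
        assert z_test(value, ref(mu, sigma)) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sigma_raises(self):
        with pytest.raises(DegenerateControlError):
            ControlReference(readout="r", session_day=0.0, mu=1.0, sigma=0.0, n_control=5)
        with pytest.raises(DegenerateControlError):
            z_test(1.0, ref(0.0, 1e-15))

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=20),
    )
    @settings(deadline=None, max_examples=50)
    def test_control_self_consistency(self, values):
        """z-scoring the control sample against its own reference yields
        mean 0 and sample SD 1."""
        v = np.asarray(values)
        sd = v.std(ddof=1)
        if sd < 1e-6:
            return
        r = ref(float(v.mean()), float(sd))
        z = np.array([z_test(x, r) for x in v])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestCompositeZ:
    @pytest.mark.parametrize(
        "components,expected",
        [([1.0, 2.0, 3.0], 2.0), ([0.0], 0.0), ([-1.0, 1.0], 0.0)],
    )
    def test_examples(self, components, expected):
        assert composite_z(components) == pytest.approx(expected, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            composite_z([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_matches_brute_force_mean(self, comps):
        brute = sum(comps) / len(comps)  # independent accumulation
        assert composite_z(comps) == pytest.approx(brute, abs=1e-9)


class TestWelch:
    def test_identical_groups(self):
        assert welch_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_equal_groups(self):
        assert welch_test([2, 2, 2], [2, 2]) == 1.0

    def test_matches_independent_reference(self):
        # scipy's Welch implementation serves as the independent oracle
        rng = np.random.default_rng(20)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(2, 15))
            b = rng.normal(0.5, 2, rng.integers(2, 15))
            expect = sps.ttest_ind(a, b, equal_var=False).pvalue
            assert welch_test(a, b) == pytest.approx(expect, abs=1e-9)
        assert welch_test([10, 12, 14], [13, 15, 17]) == pytest.approx(
            sps.ttest_ind([10, 12, 14], [13, 15, 17], equal_var=False).pvalue,
            abs=1e-9,
        )

    def test_separated_groups_tiny_p(self):
        assert welch_test([0, 0.1], [100, 100.1]) < 1e-4

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            welch_test([1], [1, 2])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_magnitude_and_sign(self):
        # pooled SD 2, mean difference -3 (interest minus control)
        assert cohens_d([10, 12, 14], [13, 15, 17]) == pytest.approx(-1.5)
        assert cohens_d([13, 15, 17], [10, 12, 14]) == pytest.approx(1.5)

    def test_scale_invariance(self):
        a, b = [10, 12, 14], [13, 15, 17]
        assert cohens_d([2 * x for x in a], [2 * x for x in b]) == pytest.approx(
            cohens_d(a, b)
        )

    def test_glass_delta_uses_control_sd(self):
        a, b = [0.0, 10.0], [0.0, 2.0]
        # control SD = sqrt(2); mean diff = 4
        assert cohens_d(a, b, sd="control") == pytest.approx(4 / np.sqrt(2))

    def test_hedges_correction_shrinks(self):
        a, b = [13, 15, 17], [10, 12, 14]
        assert 0 < cohens_d(a, b, hedges=True) < cohens_d(a, b)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateControlError):
            cohens_d([1, 1, 1], [1, 1, 1])


def rm_oracle(groups):
    """Independent sums-of-squares oracle for the balanced mixed design,
    coded directly from the textbook cell-mean decomposition."""
    all_values = [x for g in groups for row in g for x in row]
    grand = sum(all_values) / len(all_values)
    k = len(groups[0][0])
    ss_group = 0.0
    ss_bs = 0.0
    for g in groups:
        gm = sum(x for row in g for x in row) / (len(g) * k)
        ss_group += len(g) * k * (gm - grand) ** 2
        for row in g:
            sm = sum(row) / k
            ss_bs += k * (sm - grand) ** 2
    ss_subj = ss_bs - ss_group
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    f = (ss_group / df1) / (ss_subj / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta = ss_group / (ss_group + ss_subj)
    return p, eta


class TestRmGroupEffect:
    def test_zero_group_effect(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        p, eta = rm_group_effect(a, a.copy())
        assert p == pytest.approx(1.0)
        assert eta == pytest.approx(0.0)

    def test_pure_offset_zero_noise_limit(self):
        base = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        p, eta = rm_group_effect(base + 5.0, base)
        assert p == pytest.approx(0.0, abs=1e-12)
        assert eta == pytest.approx(1.0)

    def test_exhaustive_small_designs_match_ss_oracle(self):
        rng = np.random.default_rng(77)
        for n_a, n_b, k in itertools.product(range(2, 7), range(2, 7), range(2, 5)):
            a = rng.normal(0, 1, (n_a, k))
            b = rng.normal(0.7, 1.3, (n_b, k))
            p, eta = rm_group_effect(a, b)
            p0, eta0 = rm_oracle([a.tolist(), b.tolist()])
            assert p == pytest.approx(p0, abs=1e-8)
            assert eta == pytest.approx(eta0, abs=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (5, 3))
        b = rng.normal(0.8, 1, (6, 3))
        rows = [
            dict(subj=f"{g}{i}", group=g, time=j, y=mat[i, j])
            for g, mat in (("i", a), ("c", b))
            for i in range(mat.shape[0])
            for j in range(3)
        ]
        res = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="time", between="group",
            subject="subj",
        )
        grp = res[res["Source"] == "group"].iloc[0]
        p, eta = rm_group_effect(a, b)
        assert p == pytest.approx(float(grp["p_unc"]), abs=1e-9)
        assert eta == pytest.approx(float(grp["np2"]), abs=1e-9)

    def test_unbalanced_raises(self):
        a = np.array([[1.0, np.nan], [3.0, 4.0]])
        with pytest.raises(UnbalancedPanelError):
            rm_group_effect(a, np.ones((2, 2)))

    def test_single_session_raises(self):
        with pytest.raises(ValueError):
            rm_group_effect(np.ones((3, 1)), np.ones((3, 1)))


class TestEta2ToF2:
    @pytest.mark.parametrize("eta,f2", [(0.0, 0.0), (0.5, 1.0), (0.2, 0.25)])
    def test_examples(self, eta, f2):
        assert eta2_to_f2(eta) == pytest.approx(f2)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            eta2_to_f2(1.0)


class TestMespCheck:
    @pytest.mark.parametrize(
        "p,d,consistent,expected",
        [
            (0.04, 0.6, True, True),
            (0.04, 0.4, True, False),
            (0.06, 0.8, True, False),
            (0.01, 0.9, False, False),
            (0.01, -0.9, True, True),  # magnitude rule for d
        ],
    )
    def test_decision_table(self, p, d, consistent, expected):
        res = mesp_check(p, d, EffectKind.COHENS_D, consistent, MESPConfig())
        assert res.passes is expected

    def test_f2_threshold(self):
        cfg = MESPConfig()
        assert mesp_check(0.01, 0.07, EffectKind.COHENS_F2, True, cfg).passes
        assert not mesp_check(0.01, 0.05, EffectKind.COHENS_F2, True, cfg).passes

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            mesp_check(1.5, 0.6, EffectKind.COHENS_D, True, MESPConfig())

    def test_null_conjunction_never_more_liberal_than_alpha(self):
        """Under the null, the Welch+d MESP pass rate stays below alpha."""
        rng = np.random.default_rng(9)
        cfg = MESPConfig()
        n_reps, n = 2000, 12
        passes = 0
        for _ in range(n_reps):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            d = cohens_d(a, b)
            passes += mesp_check(
                welch_test(a, b), d, EffectKind.COHENS_D, d > 0, cfg
            ).passes
        rate = passes / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert rate <= 0.05 + 3 * se

    def test_pass_probability_monotone_in_effect(self):
        """With common random numbers, the simulated MESP pass rate is
        non-decreasing in the true standardized group difference."""
        rng = np.random.default_rng(10)
        cfg = MESPConfig()
        n_reps, n = 400, 12
        noise = [
            (rng.standard_normal(n), rng.standard_normal(n)) for _ in range(n_reps)
        ]
        rates = []
        for delta in (0.0, 0.5, 1.0, 1.5):
            passes = 0
            for a0, b in noise:
                a = a0 + delta
                d = cohens_d(a, b)
                passes += mesp_check(
                    welch_test(a, b), d, EffectKind.COHENS_D, d > 0, cfg
                ).passes
            rates.append(passes / n_reps)
        assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))
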