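"""Group statistics: t-tests, FDR, rm-GLM vs oracle, trends, BF, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from threatdyn import (
    bf10_paired,
    cohens_dz,
    fdr_bh,
    min_conjunction,
    min_detectable_effect,
    one_sample_t,
    polynomial_trends,
    rm_anova,
)
from threatdyn.exceptions import IncompleteDesignError, ZeroVarianceError
from threatdyn.groupstats import DEFAULT_RSCALE, dz_band, power_one_sample_t


class TestOneSampleT:
    def test_symmetric_values_give_null(self):
        t, p, dz = one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert t == 0.0 and p == pytest.approx(1.0) and dz == 0.0

    def test_hand_computed_example(self):
        t, p, dz = one_sample_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))
        assert dz == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            one_sample_t([1.0, 1.0, 1.0])

    def test_type_one_error_calibration(self):
        # under the null, the 0.05-level test rejects ~5% of the time
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p, _ = one_sample_t(rng.normal(size=30))
            rejections += p < 0.05
        # binomial 99.9% interval around 0.05 with 1000 reps
        assert 27 <= rejections <= 75


class TestFdrBH:
    def test_stepup_thresholds_example(self):
        rej = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0], q=0.05).any()

    def test_single_small_p_rejected(self):
        assert fdr_bh([0.04], q=0.05).all()

    def test_matches_direct_enumeration(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_array_equal(
                fdr_bh(p, q=0.05), oracles.fdr_bh_oracle(p, 0.05))

    def test_controls_fdr_on_mixed_nulls(self):
        # half the tests null, half with a strong effect; the realized false
        # discovery proportion stays near or below q on average
        rng = np.random.default_rng(7)
        fdp = []
        for _ in range(200):
            n0, n1 = 50, 50
            t0 = rng.normal(size=n0)
            t1 = rng.normal(loc=4.0, size=n1)
            from scipy import stats
            p = 2 * stats.norm.sf(np.abs(np.concatenate([t0, t1])))
            rej = fdr_bh(p, q=0.05)
            false = rej[:n0].sum()
            fdp.append(false / max(rej.sum(), 1))
        assert np.mean(fdp) <= 0.055

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestMinConjunction:
    def test_idempotent(self):
        m = np.array([True, False, True])
        np.testing.assert_array_equal(min_conjunction(m, m), m)

    def test_empty_annihilates(self):
        m = np.array([True, True])
        assert not min_conjunction(m, np.zeros(2, bool)).any()

    def test_elementwise_and(self):
        a = np.array([1, 0, 1], bool)
        b = np.array([1, 1, 0], bool)
        np.testing.assert_array_equal(min_conjunction(a, b),
                                      np.array([1, 0, 0], bool))

    def test_monotone_in_masks(self, rng):
        a = rng.uniform(size=50) < 0.5
        b = rng.uniform(size=50) < 0.5
        c = rng.uniform(size=50) < 0.5
        assert min_conjunction(a, b, c).sum() <= min_conjunction(a, b).sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            min_conjunction(np.ones(3, bool), np.ones(4, bool))


def _long_table(data, factors, levels):
    """subjects x cells array -> long DataFrame (cells in product order)."""
    import itertools
    rows = []
    cells = list(itertools.product(*levels))
    for s in range(data.shape[0]):
        for c, combo in enumerate(cells):
            row = dict(subject=s, value=data[s, c])
            row.update(dict(zip(factors, combo)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestRMAnova:
    def test_two_level_factor_epsilon_is_one(self, rng):
        data = rng.normal(size=(8, 2))
        df = _long_table(data, ["A"], [["a1", "a2"]])
        res = rm_anova(df, ["A"])
        assert res["A"].hf_epsilon == 1.0

    def test_additive_truth_kills_interaction(self, rng):
        # value = subject effect + factor effects, no interaction, no noise
        subs = rng.normal(size=10)
        a_eff = np.array([0.0, 1.0])
        b_eff = np.array([0.0, 0.5, 1.5])
        data = np.zeros((10, 6))
        for s in range(10):
            c = 0
            for i in range(2):
                for j in range(3):
                    data[s, c] = subs[s] + a_eff[i] + b_eff[j]
                    c += 1
        df = _long_table(data, ["A", "B"], [["a1", "a2"], [1, 2, 3]])
        res = rm_anova(df, ["A", "B"])
        # the interaction sum of squares vanishes up to float roundoff
        assert res["A x B"].ss_effect == pytest.approx(0.0, abs=1e-20)
        assert res["A"].F > 1e6 and res["B"].F > 1e6

    @settings(max_examples=12, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k_per = [int(rng.integers(2, 4)) for _ in range(int(rng.integers(1, 4)))]
        n = int(rng.integers(max(k_per) + 2, 12))
        data = rng.normal(size=(n, int(np.prod(k_per))))
        factors = [f"F{i}" for i in range(len(k_per))]
        levels = [list(range(k)) for k in k_per]
        res = rm_anova(_long_table(data, factors, levels), factors)
        ora = oracles.rm_anova_oracle(data, k_per)
        import itertools
        for r in range(1, len(k_per) + 1):
            for combo in itertools.combinations(range(len(k_per)), r):
                name = " x ".join(factors[i] for i in combo)
                e, o = res[name], ora[combo]
                assert e.F == pytest.approx(o["F"], abs=1e-8)
                assert e.hf_epsilon == pytest.approx(o["hf_eps"], abs=1e-8)
                assert e.p_hf == pytest.approx(o["p_hf"], abs=1e-8)
                assert e.partial_eta2 == pytest.approx(o["partial_eta2"], abs=1e-8)

    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(size=(9, 6)) + np.arange(6) * 0.3
        df = _long_table(data, ["A", "B"], [["x", "y"], [1, 2, 3]])
        res = rm_anova(df, ["A", "B"])
        ref = pg.rm_anova(data=df, dv="value", within=["A", "B"],
                          subject="subject", correction=True, detailed=True)
        for src, name in [("A", "A"), ("B", "B"), ("A * B", "A x B")]:
            row = ref[ref["Source"] == src].iloc[0]
            assert res[name].F == pytest.approx(row["F"], rel=1e-10)
            assert res[name].p_unc == pytest.approx(row["p_unc"], rel=1e-10)

    def test_incomplete_table_rejected(self, rng):
        df = _long_table(rng.normal(size=(6, 4)), ["A", "B"],
                         [["a", "b"], [1, 2]])
        with pytest.raises(IncompleteDesignError):
            rm_anova(df.iloc[:-1], ["A", "B"])


class TestPolynomialTrends:
    def test_pure_linear_has_zero_quadratic(self):
        Y = np.tile([1.0, 2.0, 3.0], (6, 1))
        res = polynomial_trends(Y)
        assert res["quadratic"].estimate == 0.0
        assert res["linear"].estimate == pytest.approx(2.0)

    def test_pure_v_has_zero_linear(self):
        Y = np.tile([1.0, 0.0, 1.0], (6, 1))
        res = polynomial_trends(Y)
        assert res["linear"].estimate == 0.0
        assert res["quadratic"].estimate == pytest.approx(2.0)

    def test_v_shaped_group_detected_with_high_power(self):
        # group V-shape (1, 0, 1), between-subject sd 0.5, n = 50
        rng = np.random.default_rng(11)
        hits = 0
        reps = 100
        for _ in range(reps):
            Y = np.array([1.0, 0.0, 1.0]) + rng.normal(0, 0.5, size=(50, 3))
            if polynomial_trends(Y)["quadratic"].p < 0.001:
                hits += 1
        assert hits >= 95


class TestCohensDz:
    def test_zero_mean_is_nil(self, rng):
        d = rng.normal(size=40)
        d = d - d.mean()
        dz, band = cohens_dz(d)
        assert dz == pytest.approx(0.0) and band == "nil"

    def test_mean_equals_sd(self):
        d = np.array([0.0, 1.0, 2.0])  # mean 1, sd 1
        dz, band = cohens_dz(d)
        assert dz == pytest.approx(1.0) and band == "large"

    def test_boundary_point_one_is_nil_inclusive(self):
        assert dz_band(0.10) == "nil"
        assert dz_band(-0.10) == "nil"
        assert dz_band(0.1000001) == "small"

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            cohens_dz([2.0, 2.0])


class TestBayesFactor:
    def test_null_t_large_n_favors_null(self):
        res = bf10_paired(0.0, 220)
        assert res.bf10 < 0.33
        assert res.band in ("strong_null", "moderate_null")

    def test_monotone_in_abs_t(self):
        bfs = [bf10_paired(t, 50).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(b < a for b, a in zip(bfs, bfs[1:]))

    def test_band_assignment(self):
        assert bf10_paired(0.0, 500).band == "strong_null"
        from threatdyn.groupstats import bf10_band
        assert bf10_band(0.08) == "strong_null"
        assert bf10_band(0.2) == "moderate_null"
        assert bf10_band(0.5) == "weak_null"
        assert bf10_band(2.0) == "favors_alternative"

    def test_null_bf_vanishes_with_n(self):
        bfs = [bf10_paired(0.0, n).bf10 for n in (20, 200, 2000)]
        assert bfs[0] > bfs[1] > bfs[2]

    def test_matches_effect_size_integration_oracle(self):
        for t in (0.0, 0.8, 2.0):
            for n in (10, 50, 220):
                mine = bf10_paired(t, n).bf10
                ref = oracles.bf10_oracle(t, n, DEFAULT_RSCALE)
                assert mine == pytest.approx(ref, abs=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bf10_paired(1.0, 1)
        with pytest.raises(ValueError):
            bf10_paired(1.0, 10, rscale=0.0)


class TestMinDetectableEffect:
    def test_study_sample_size_reproduces_benchmark(self):
        assert round(min_detectable_effect(220, 0.05, 0.80), 2) == 0.19

    def test_large_n_normal_approximation(self):
        n = 5000
        approx = oracles.power_normal_approx(n, 0.05, 0.80)
        assert min_detectable_effect(n) == pytest.approx(approx, rel=0.01)

    def test_inverse_consistency(self):
        n = 80
        d = min_detectable_effect(n)
        assert power_one_sample_t(n, d) >= 0.80 - 1e-9
        assert power_one_sample_t(n, d - 0.001) < 0.80

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            min_detectable_effect(1)
        with pytest.raises(ValueError):
            min_detectable_effect(10, alpha=1.5)
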