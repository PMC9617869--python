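"""Permutation inference, FDR, partial correlations, demographic tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynconn as dc


class TestPermutationTest:
    def test_identical_constant_groups_null(self):
        res = dc.permutation_test([2.0] * 4, [2.0] * 4, n_perm=200, seed=0)
        assert res.observed_diff == 0.0
        assert res.p_perm == pytest.approx(1.0)

    def test_perfect_separation_small_p(self):
        # exact enumeration: only 2 of C(8,4)=70 arrangements reach the
        # observed |difference|, so the true p is 2/70 ~ 0.029
        a, b = [0.0] * 4, [10.0] * 4
        res = dc.permutation_test(a, b, n_perm=10_000, seed=1)
        assert res.p_perm <= 0.04
        pooled = a + b
        count = 0
        for idx in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(8) if i not in idx]
            if abs(np.mean(ga) - np.mean(gb)) >= 10.0 - 1e-12:
                count += 1
        assert count == 2
        assert res.p_perm == pytest.approx(2 / 70, abs=0.01)

    def test_two_sidedness_label_exchange(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 10)
        p_ab = dc.permutation_test(a, b, n_perm=4999, seed=5).p_perm
        p_ba = dc.permutation_test(b, a, n_perm=4999, seed=5).p_perm
        assert p_ab == pytest.approx(p_ba, abs=0.02)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            dc.permutation_test([], [1.0], n_perm=10)

    def test_t_statistic_variant(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(2, 1, 15)
        res = dc.permutation_test(a, b, n_perm=999, seed=0, statistic="t")
        assert res.p_perm < 0.01

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.05 stays within Monte-Carlo
        bounds over 1000 null datasets (n_perm=999)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            if dc.permutation_test(a, b, n_perm=999, rng=rng).p_perm < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestFdrBh:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            dc.fdr_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(dc.fdr_bh([0.37]), [0.37])

    def test_equal_ps_are_fixed_point(self):
        np.testing.assert_allclose(dc.fdr_bh([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dc.fdr_bh([0.5, 0.0])
        with pytest.raises(ValueError):
            dc.fdr_bh([1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_rejections(self, ps):
        ps = np.asarray(ps)
        adj = dc.fdr_bh(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= 1.0)
        # step-up rule agreement at alpha = 0.05
        alpha = 0.05
        m = len(ps)
        order = np.argsort(ps)
        thresh = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= alpha * rank / m:
                thresh = rank
        rejected_rule = np.zeros(m, bool)
        rejected_rule[order[:thresh]] = True
        np.testing.assert_array_equal(adj <= alpha, rejected_rule)


class TestSpearmanPartial:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.linspace(0, 1, 20)
        res = dc.spearman_partial(x, np.exp(3 * x))
        assert res.rho == pytest.approx(1.0)

    def test_reduces_to_plain_spearman_without_covariates(self, rng):
        from scipy.stats import spearmanr

        x = rng.standard_normal(30)
        y = 0.4 * x + rng.standard_normal(30)
        res = dc.spearman_partial(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_matches_pingouin_with_covariates(self, rng):
        import pandas as pd
        import pingouin as pg

        # covariates as permutations of 1..n: they equal their own ranks,
        # so pingouin's rank-everything route and the residualize-on-raw-
        # covariates route must coincide
        n = 40
        z = np.column_stack(
            [rng.permutation(n) + 1.0, rng.permutation(n) + 1.0]
        )
        x = z @ [0.05, -0.03] + rng.standard_normal(n)
        y = z @ [0.02, 0.04] + 0.5 * x + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"],
                              method="spearman")
        res = dc.spearman_partial(x, y, z, covariate_names=("z1", "z2"))
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_constant_input_flagged_undefined(self):
        res = dc.spearman_partial([1.0] * 10, list(range(10)))
        assert res.undefined
        assert np.isnan(res.rho)

    def test_planted_symptom_effect_recovered(self):
        cfg = dc.default_config(
            n_patients=200, n_controls=0, n_nodes=8, n_volumes=30,
            symptom_effect=-0.5, seed=21,
        )
        subjects, gt = dc.simulate_cohort(cfg)
        sev = [ts.panss["total"] for ts in subjects]
        var = [gt.node_variability[ts.subject_id] for ts in subjects]
        covars = np.array(
            [[ts.covariates["age"], ts.covariates["sex"], ts.covariates["education"]]
             for ts in subjects]
        )
        res = dc.spearman_partial(sev, var, covars)
        assert -0.7 < res.rho < -0.3


class TestDemographicTests:
    def test_chi_square_matches_reported_cohort_value(self):
        stat, p = dc.chi_square_2x2([[41, 54], [47, 53]])
        assert stat == pytest.approx(0.290, abs=0.001)

    def test_proportional_table_is_independent(self):
        stat, _ = dc.chi_square_2x2([[10, 10], [20, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 10*625/625 = 10
        stat, _ = dc.chi_square_2x2([[5, 0], [0, 5]])
        assert stat == pytest.approx(10.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            dc.chi_square_2x2([[0, 0], [3, 4]])

    def test_t_identical_groups(self):
        t, p = dc.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_t_matches_textbook_formula(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.3, 17)
        t, p = dc.two_sample_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_ref, abs=1e-12)

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.raises(ValueError):
            dc.two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestCompareGroups:
    def test_family_wise_fdr_and_summary_columns(self, rng):
        import pandas as pd

        n = 30
        df = pd.DataFrame(
            {
                "signal": np.r_[rng.normal(1, 1, 15), rng.normal(0, 1, 15)],
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n),
            }
        )
        groups = ["patient"] * 15 + ["control"] * 15
        out = dc.compare_groups(
            df, groups, families={"a": ["signal"], "b": ["noise1", "noise2"]},
            n_perm=999, seed=0,
        )
        assert set(out["family"]) == {"a", "b"}
        assert (out["p_fdr"] >= out["p_perm"] - 1e-12).all()
        sig = out.set_index("feature")
        assert sig.loc["signal", "observed_diff"] == pytest.approx(
            df["signal"][:15].mean() - df["signal"][15:].mean()
        )
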