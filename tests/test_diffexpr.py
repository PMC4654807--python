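"""Differential expression: normalization, moderated t, BH, DE filter."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from thlineage.containers import ExpressionMatrix
from thlineage.diffexpr import (
    apply_de_filter,
    bh_adjust,
    count_de_test,
    estimate_variance_prior,
    median_of_ratios_size_factors,
    moderated_t_test,
    variance_stabilize,
)
from thlineage.errors import DegenerateInputError, ValidationError


def brute_force_bh(p):
    """Step-up definition: adj_i = min_{j >= rank_i} p_(j) * n / j, clipped."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def _matrix(values, groups=("Thp", "Th1"), reps=3, kind="intensity"):
    samples = [f"{g}_r{i}" for g in groups for i in range(1, reps + 1)]
    design = pd.DataFrame(
        {"sample": samples, "group": [s.split("_")[0] for s in samples],
         "replicate": [int(s[-1]) for s in samples]}
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, columns=samples), design=design, platform_kind=kind
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 50, 7], "b": [10, 50, 7]})
        np.testing.assert_allclose(median_of_ratios_size_factors(counts), [1.0, 1.0])

    def test_hand_computed_two_by_two(self):
        # rows (100, 200) and (300, 600): geometric means 141.42, 424.26;
        # per-sample ratios (0.7071, 1.4142) in both rows, already geomean 1
        counts = pd.DataFrame({"a": [100, 300], "b": [200, 600]})
        f = median_of_ratios_size_factors(counts)
        np.testing.assert_allclose(f, [np.sqrt(0.5), np.sqrt(2.0)], rtol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(300, 4)), columns=list("abcd"))
        base = median_of_ratios_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        f = median_of_ratios_size_factors(scaled)
        ratio = (f / base).to_numpy()
        assert ratio[2] / ratio[0] == pytest.approx(3.0, rel=1e-9)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 3)), columns=list("abc"))
        perm = counts.sample(frac=1, random_state=2)
        np.testing.assert_allclose(
            median_of_ratios_size_factors(counts), median_of_ratios_size_factors(perm)
        )

    def test_geometric_mean_one_and_errors(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 5)))
        f = median_of_ratios_size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(DegenerateInputError):
            median_of_ratios_size_factors(pd.DataFrame({"a": [0, 5], "b": [3, 0]}))


class TestVarianceStabilize:
    def test_zero_count_maps_to_zero_and_count_equal_factor_to_one(self):
        counts = pd.DataFrame({"a": [0, 2]})
        out = variance_stabilize(counts, pd.Series({"a": 2.0}))
        assert out.loc[0, "a"] == 0.0
        assert out.loc[1, "a"] == 1.0  # log2(2/2 + 1)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(np.sort(rng.poisson(30, size=(50, 2)), axis=0))
        out = variance_stabilize(counts, pd.Series([1.3, 0.7], index=counts.columns))
        assert (out.diff().dropna() >= 0).all().all()


class TestModeratedT:
    def test_no_shrinkage_limit_equals_students_t(self, two_group_matrix):
        tab = moderated_t_test(two_group_matrix, ("Thp", "Th1"), d0_override=0.0)
        ref = two_group_matrix.values[two_group_matrix.samples_in_group("Thp")]
        tst = two_group_matrix.values[two_group_matrix.samples_in_group("Th1")]
        t, p = scipy.stats.ttest_ind(tst, ref, axis=1, equal_var=True)
        np.testing.assert_allclose(tab["t"], t, rtol=1e-10)
        np.testing.assert_allclose(tab["pvalue"], p, rtol=1e-10)

    def test_full_shrinkage_limit_uses_common_variance(self, two_group_matrix):
        tab = moderated_t_test(two_group_matrix, ("Thp", "Th1"), d0_override=np.inf)
        ref = two_group_matrix.values[two_group_matrix.samples_in_group("Thp")].to_numpy()
        tst = two_group_matrix.values[two_group_matrix.samples_in_group("Th1")].to_numpy()
        s2 = (ref.var(axis=1, ddof=1) * 2 + tst.var(axis=1, ddof=1) * 2) / 4
        lfc = tst.mean(axis=1) - ref.mean(axis=1)
        expected_t = lfc / np.sqrt(np.mean(s2) * (2 / 3))
        np.testing.assert_allclose(tab["t"], expected_t, rtol=1e-10)

    def test_hyperparameter_recovery(self):
        # full hierarchy: sigma_g^2 ~ s0^2 * d0 / chi2_d0, s^2 ~ sigma^2 chi2_df / df
        d0_true, s0_true, df = 8.0, 2.0, 4
        est_d0, est_s0 = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
            s2 = sigma2 * rng.chisquare(df, size=5000) / df
            d0, s0 = estimate_variance_prior(s2, df)
            est_d0.append(d0)
            est_s0.append(s0)
        assert np.mean(est_s0) == pytest.approx(s0_true, rel=0.10)
        assert np.mean(est_d0) == pytest.approx(d0_true, rel=0.25)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        m = _matrix(rng.normal(0, 1, size=(2000, 6)))
        tab = moderated_t_test(m, ("Thp", "Th1"))
        ks = scipy.stats.kstest(tab["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_replication(self):
        samples = ["Thp_r1", "Th1_r1", "Th1_r2"]
        design = pd.DataFrame(
            {"sample": samples, "group": ["Thp", "Th1", "Th1"], "replicate": [1, 1, 2]}
        )
        m = ExpressionMatrix(
            values=pd.DataFrame(np.ones((5, 3)), columns=samples),
            design=design,
            platform_kind="intensity",
        )
        with pytest.raises(DegenerateInputError):
            moderated_t_test(m, ("Thp", "Th1"))


class TestCountDE:
    def test_doubling_counts_leaves_log2fc_invariant(self):
        # global depth is absorbed by normalization up to the +1 pseudocount,
        # which vanishes in the large-count limit
        rng = np.random.default_rng(4)
        counts = rng.poisson(500, size=(300, 6)) + 50
        a = count_de_test(_matrix(counts, kind="count"), ("Thp", "Th1"))
        b = count_de_test(_matrix(counts * 2, kind="count"), ("Thp", "Th1"))
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=2e-3)

    def test_planted_fold_change_power(self):
        # 500 genes with a 4-fold change, NB dispersion 0.05, n=3 per group,
        # embedded in a 4500-gene null background
        rng = np.random.default_rng(6)
        disp = 0.05
        r = 1 / disp
        mu_bg = rng.lognormal(np.log(200), 0.8, size=4500)[:, None]
        bg = rng.negative_binomial(r, r / (r + mu_bg), size=(4500, 6))
        mu = 200.0
        base = rng.negative_binomial(r, r / (r + mu), size=(500, 3))
        up = rng.negative_binomial(r, r / (r + 4 * mu), size=(500, 3))
        counts = np.vstack([bg, np.hstack([base, up])])
        tab = count_de_test(_matrix(counts, kind="count"), ("Thp", "Th1"))
        tab = apply_de_filter(tab)
        assert tab["is_de"].tail(500).mean() >= 0.9

    def test_null_calibration(self):
        # homogeneous data with permuted labels: p-values uniform
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(50):
            counts = rng.poisson(150, size=(40, 6))
            tab = count_de_test(_matrix(counts, kind="count"), ("Thp", "Th1"))
            pvals.extend(tab["pvalue"])
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBH:
    def test_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_and_equal_values(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037, abs=1e-15)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 200))
    def test_equals_brute_force_step_up(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        p = np.random.default_rng(12).uniform(size=500)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestDEFilter:
    def _table(self, adj_p, lfc, comparison="Thp_vs_Th1"):
        return pd.DataFrame(
            {
                "comparison": comparison,
                "log2fc": [lfc],
                "pvalue": [adj_p],
                "adj_pvalue": [adj_p],
            },
            index=["G1"],
        )

    def _presence(self, thp, th1):
        return pd.DataFrame({"Thp": [thp], "Th1": [th1]}, index=["G1"])

    def test_thresholds_met_and_present(self):
        tab = apply_de_filter(self._table(0.049, 1.01), self._presence(False, True))
        assert tab["is_de"].iloc[0]

    def test_lfc_boundary_is_strict(self):
        tab = apply_de_filter(self._table(0.049, 1.0), self._presence(True, True))
        assert not tab["is_de"].iloc[0]

    def test_alpha_boundary_is_strict(self):
        tab = apply_de_filter(self._table(0.05, 2.0), self._presence(True, True))
        assert not tab["is_de"].iloc[0]

    def test_absent_in_both_groups_refined_away(self):
        tab = apply_de_filter(self._table(0.01, 3.0), self._presence(False, False))
        assert not tab["is_de"].iloc[0]

    def test_refinement_rules(self):
        table = self._table(0.01, 3.0)
        only_ref = self._presence(True, False)
        assert apply_de_filter(table, only_ref, refinement="either")["is_de"].iloc[0]
        assert not apply_de_filter(table, only_ref, refinement="both")["is_de"].iloc[0]
        assert not apply_de_filter(table, only_ref, refinement="test")["is_de"].iloc[0]
        assert apply_de_filter(table, only_ref, refinement="none")["is_de"].iloc[0]

    def test_idempotent(self, two_group_matrix):
        tab = moderated_t_test(two_group_matrix, ("Thp", "Th1"))
        once = apply_de_filter(tab)
        twice = apply_de_filter(once)
        pd.testing.assert_frame_equal(once, twice)
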