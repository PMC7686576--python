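"""Differential engine: normalization, weights, moderation, contrasts, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tcellatac.differential import (
    ContrastError, ContrastSpec, _gls_fit, aging_contrast, bh_adjust,
    design_matrix, filter_low_counts, fit_differential, fit_f_dist, log_cpm,
    moderate_variances, normalize_and_weight, subset_age_contrast,
    trigamma_inverse,
)

from _oracles import bh_oracle


def _toy_counts(rng, n_feat=80, groups=("g1",) * 4 + ("g2",) * 4, lib=50_000):
    n = len(groups)
    base = rng.gamma(2.0, 50.0, size=n_feat)
    counts = rng.poisson(np.outer(base, np.ones(n)))
    cols = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(counts, index=[f"f{i}" for i in range(n_feat)], columns=cols)
    g = pd.Series(list(groups), index=cols)
    return df, g


# ---------------------------------------------------------------- log-CPM

def test_log_cpm_closed_form():
    counts = pd.DataFrame({"s": [100]}, index=["f"])
    counts.loc["rest"] = 10**6 - 100
    val = log_cpm(counts).loc["f", "s"]
    assert val == pytest.approx(np.log2(100.5 / (10**6 + 1) * 1e6), abs=1e-9)
    assert val == pytest.approx(6.6512, abs=1e-3)


class TestFilterLowCounts:
    def test_all_zero_feature_removed(self):
        df = pd.DataFrame({"a": [0, 100], "b": [0, 100]}, index=["z", "ok"])
        out = filter_low_counts(df, min_cpm=1, min_samples=1)
        assert list(out.index) == ["ok"]

    def test_boundary_feature_kept(self):
        # feature with CPM exactly >= 1 in exactly min_samples samples
        df = pd.DataFrame({"a": [1, 10**6 - 1], "b": [0, 10**6]},
                          index=["edge", "big"])
        cpm_a = 1 / df["a"].sum() * 1e6
        assert cpm_a >= 1.0
        out = filter_low_counts(df, min_cpm=1.0, min_samples=1)
        assert "edge" in out.index

    def test_zero_min_samples_is_identity(self):
        df = pd.DataFrame({"a": [0, 1], "b": [0, 2]})
        assert filter_low_counts(df, 1, 0).equals(df)

    def test_empty_result_raises(self):
        df = pd.DataFrame({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(ValueError, match="thresholds"):
            filter_low_counts(df, min_cpm=1e9, min_samples=2)


# ------------------------------------------------------- Benjamini-Hochberg

class TestBHAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_literal_stepup_and_statsmodels(self, pvals):
        mine = bh_adjust(pvals)
        assert np.allclose(mine, bh_oracle(pvals), atol=1e-12)
        sm = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(mine, sm, atol=1e-12)
        # monotone in rank
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(mine[order]) >= -1e-15).all()


# ------------------------------------------------- empirical-Bayes moderation

class TestModeration:
    def test_matches_limma_squeezevar_frozen_values(self):
        # input variances reproduce a scaled-inv-chisq mixture; the expected
        # hyperparameters and posteriors below were computed once with
        # Bioconductor limma::squeezeVar (v3.58.1) on this exact vector
        rng = np.random.default_rng(123)
        sg2 = 1.2 * 6.0 / rng.chisquare(6.0, size=120)
        s2 = np.round(sg2 * rng.chisquare(9, size=120) / 9, 10)
        d0, s02 = fit_f_dist(s2, 9.0)
        assert d0 == pytest.approx(6.894208053, rel=1e-8)
        assert s02 == pytest.approx(1.03697977, rel=1e-8)
        post, _, _ = moderate_variances(s2, 9.0, robust=False)
        assert post[:3] == pytest.approx(
            [0.7954112729, 1.045816299, 1.138539699], rel=1e-8)

    def test_posterior_is_convex_combination(self, rng):
        # overdispersed mixture so the fitted prior df is finite
        sg2 = 1.0 * 4.0 / rng.chisquare(4.0, size=200)
        s2 = sg2 * rng.chisquare(5, size=200) / 5
        post, d0, s02 = moderate_variances(s2, 5.0, robust=False)
        assert np.isfinite(d0)
        assert (post >= np.minimum(s2, s02) - 1e-12).all()
        assert (post <= np.maximum(s2, s02) + 1e-12).all()

    def test_underdispersed_variances_give_infinite_prior(self):
        s2 = np.full(50, 1.0) + np.linspace(-1e-4, 1e-4, 50)
        post, d0, s02 = moderate_variances(s2, 10.0, robust=False)
        assert np.isinf(d0)
        assert np.allclose(post, s02)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (0.01, 0.5, 2.0, 50.0):
            assert polygamma(1, trigamma_inverse(y)) == pytest.approx(y, rel=1e-6)


# ------------------------------------------------------------------ GLS fits

class TestFitDifferential:
    def test_unmoderated_t_equals_classical_two_sample_t(self, rng):
        """With unit weights, rho=0 and no shrinkage, the GLS contrast t equals
        the classical equal-variance two-sample t feature by feature."""
        Y = rng.normal(size=(30, 10))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"s{i}" for i in range(10)])
        X, labels = design_matrix(groups)
        fit = _gls_fit(Y, np.ones_like(Y), X, None)
        c = np.array([1.0, -1.0]) if labels == ["a", "b"] else np.array([-1.0, 1.0])
        est = fit["beta"] @ c
        varfac = np.einsum("k,gkl,l->g", c, fit["cov_unscaled"], c)
        t_mine = est / np.sqrt(fit["sigma2"] * varfac)
        t_ref = stats.ttest_ind(Y[:, :5], Y[:, 5:], axis=1, equal_var=True).statistic
        assert np.allclose(np.abs(t_mine), np.abs(t_ref), atol=1e-10)

    def test_combined_aging_contrast_is_sum_of_subset_differences(self, default_bundle):
        b = default_bundle
        counts = b.atac_counts.iloc[:150]
        wm = normalize_and_weight(counts, b.samples["group"], b.samples["donor"])
        specs = [aging_contrast("CD8")] + [
            subset_age_contrast("CD8", s) for s in ("naive", "CM", "EM")]
        res = fit_differential(wm, specs)
        combined = res.for_contrast("aging_CD8")["log_fc"]
        total = sum(res.for_contrast(f"age_{s}_CD8")["log_fc"]
                    for s in ("naive", "CM", "EM"))
        assert np.allclose(combined, total, atol=1e-10)

    def test_adjusted_p_at_least_p(self, default_bundle):
        b = default_bundle
        counts = b.atac_counts.iloc[:200]
        wm = normalize_and_weight(counts, b.samples["group"], b.samples["donor"])
        res = fit_differential(wm, [aging_contrast("CD4")])
        tab = res.for_contrast("aging_CD4")
        assert (tab["q_value"] >= tab["p_value"] - 1e-15).all()

    def test_unknown_group_in_contrast_raises(self, rng):
        counts, groups = _toy_counts(rng)
        wm = normalize_and_weight(counts, groups)
        bad = ContrastSpec("bad", {"nonexistent": 1.0})
        with pytest.raises(ContrastError, match="nonexistent"):
            fit_differential(wm, [bad])


# -------------------------------------------------------- weights / trend

class TestNormalizeAndWeight:
    def test_flat_counts_give_equal_observation_weights(self):
        cols = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(
            np.tile([[100], [200], [400]], (1, 6)), columns=cols,
            index=["f1", "f2", "f3"])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cols)
        wm = normalize_and_weight(counts, groups)
        # zero residual variance everywhere -> flat trend -> equal weights
        assert np.allclose(wm.obs_weights, wm.obs_weights[0, 0])

    def test_duplicated_sample_gets_matching_quality_weight(self, rng):
        counts, groups = _toy_counts(rng, n_feat=300)
        counts["dup"] = counts["s0"]
        groups["dup"] = groups["s0"]
        wm = normalize_and_weight(counts, groups)
        w = wm.sample_weights
        assert abs(w["dup"] - w["s0"]) / w["s0"] < 0.05

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
        groups = pd.Series(["g", "g"], index=["a", "b"])
        with pytest.raises(ValueError, match="zero library size"):
            normalize_and_weight(counts, groups)

    def test_rho_recovers_planted_donor_correlation_sign(self, default_bundle):
        b = default_bundle
        wm = normalize_and_weight(b.atac_counts.iloc[:600], b.samples["group"],
                                  b.samples["donor"])
        assert 0.1 < wm.rho < 0.8

    def test_rho_zero_without_donor_replicates(self, rng):
        counts, groups = _toy_counts(rng)
        donors = pd.Series([f"d{i}" for i in range(counts.shape[1])],
                           index=counts.columns)
        wm = normalize_and_weight(counts, groups, donors)
        assert wm.rho == 0.0
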