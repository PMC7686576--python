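"""PCA and stratified permutation inference on component scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellatac.ordination import (
    ordering_probability, paired_stratified_perm_test, pc_loading_peaks,
    pca_scores, stratified_trend_test, top_variable_features,
    twosample_stratified_perm_test,
)

from conftest import TEST_SEED, null_score_cohort


class TestTopVariableFeatures:
    def test_ranks_by_row_variance(self):
        m = pd.DataFrame([[1, 2, 3], [1, 5, 9], [1, 3, 5]],
                         index=["lo", "hi", "mid"])
        assert top_variable_features(m, 2) == ["hi", "mid"]

    def test_saturates_and_breaks_ties_by_id(self):
        m = pd.DataFrame([[0, 1], [0, 1], [5, 5]], index=["b", "a", "const"])
        assert top_variable_features(m, 10) == ["a", "b", "const"]
        assert top_variable_features(m, 2) == ["a", "b"]


class TestPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 4)),
                         index=list("fgh"), columns=list("wxyz"))
        res = pca_scores(m, 3)
        Xc = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(min(3, np.sum(evals > 1e-10))):
            got = res.loadings.iloc[:, k].to_numpy()
            want = evecs[:, k]
            assert np.allclose(np.abs(got), np.abs(want), atol=1e-8)
        assert np.allclose(res.variance_fractions,
                           (evals / evals.sum())[: len(res.variance_fractions)],
                           atol=1e-8)

    def test_scores_are_orthogonal_and_rank1_explains_all(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        m = pd.DataFrame(np.outer(u, v))
        res = pca_scores(m, 2)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        s = res.scores.to_numpy()
        assert abs(s[:, 0] @ s[:, 1]) < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_scores(pd.DataFrame(np.ones((4, 3))))

    def test_loading_peak_selection_by_magnitude(self):
        res = pca_scores(pd.DataFrame(
            [[1.0, -1.0], [2.0, -2.0], [0.1, -0.1]], index=["a", "b", "c"]), 1)
        top2 = pc_loading_peaks(res, 1, 2)
        assert top2 == ["b", "a"]
        assert pc_loading_peaks(res, 1, 99) == ["b", "a", "c"]


def _paired_instance(diffs_by_donor, strata=1):
    """Samples frame with two lineages per donor and the given CD8-CD4 diffs."""
    rows, vals = [], {}
    for d, diff in diffs_by_donor.items():
        for s in range(strata):
            for lin, v in (("CD4", 0.0), ("CD8", diff)):
                sid = f"{d}_{lin}_{s}"
                rows.append({"sample": sid, "donor": d, "lineage": lin,
                             "subset": f"sub{s}", "age_group": "young"})
                vals[sid] = v
    samples = pd.DataFrame(rows).set_index("sample", drop=False)
    return pd.Series(vals), samples


class TestPairedSignFlip:
    def test_degenerate_null_gives_p_one(self):
        values, samples = _paired_instance({f"d{i}": 0.0 for i in range(5)})
        r = paired_stratified_perm_test(values, samples)
        assert r.p_value == 1.0

    def test_six_donors_all_positive_two_sided(self):
        values, samples = _paired_instance({f"d{i}": 1.0 + 0.1 * i for i in range(6)})
        r = paired_stratified_perm_test(values, samples)
        assert r.exhaustive and r.n_arrangements == 64
        assert r.p_value == pytest.approx(2 / 64)

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        diffs = {f"d{i}": float(v) for i, v in enumerate(rng.normal(0.4, 1, 10))}
        values, samples = _paired_instance(diffs)
        exact = paired_stratified_perm_test(values, samples)
        assert exact.exhaustive
        import tcellatac.ordination as ordn
        old = ordn.EXHAUSTIVE_LIMIT
        try:
            ordn.EXHAUSTIVE_LIMIT = 1
            mc = paired_stratified_perm_test(values, samples, n_perm=4000, seed=7)
        finally:
            ordn.EXHAUSTIVE_LIMIT = old
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_arrangements)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1 / mc.n_arrangements

    def test_missing_lineage_names_donor_and_stratum(self):
        values, samples = _paired_instance({"d0": 1.0, "d1": 2.0})
        values = values.drop("d1_CD8_0")
        samples = samples.drop("d1_CD8_0")
        with pytest.raises(ValueError, match="d1"):
            paired_stratified_perm_test(values, samples)

    def test_donor_is_the_exchangeability_unit(self, rng):
        """Arrangements are counted per donor (2^donors, not 2^samples), and a
        donor-level constant added to all of a donor's samples cancels in the
        paired differences, leaving statistic and p unchanged."""
        samples, values = null_score_cohort(rng, 4, 4)
        r1 = paired_stratified_perm_test(values, samples)
        assert r1.n_arrangements == 2 ** samples["donor"].nunique()
        shifted = values.copy()
        shifted[samples.index[samples["donor"] == "Y0"]] += 5.0
        r2 = paired_stratified_perm_test(shifted, samples)
        assert r2.statistic == pytest.approx(r1.statistic)
        assert r2.p_value == pytest.approx(r1.p_value)


def _twosample_instance(values_by_donor, ages_by_donor):
    rows, vals = [], {}
    for d, v in values_by_donor.items():
        sid = f"{d}_CD8_naive"
        rows.append({"sample": sid, "donor": d, "lineage": "CD8",
                     "subset": "naive", "age_group": ages_by_donor[d]})
        vals[sid] = v
    samples = pd.DataFrame(rows).set_index("sample", drop=False)
    return pd.Series(vals), samples


class TestTwoSampleRelabel:
    def test_identical_groups_give_p_one(self):
        vals = {f"d{i}": 1.0 for i in range(6)}
        ages = {f"d{i}": "young" if i < 3 else "old" for i in range(6)}
        values, samples = _twosample_instance(vals, ages)
        r = twosample_stratified_perm_test(values, samples)
        assert r.p_value == 1.0

    def test_complete_separation_one_sided(self):
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 10.0, "e": 11.0, "f": 12.0}
        ages = {k: ("young" if k in "abc" else "old") for k in vals}
        values, samples = _twosample_instance(vals, ages)
        r = twosample_stratified_perm_test(values, samples, alternative="greater")
        assert r.exhaustive and r.n_arrangements == 20
        assert r.p_value == pytest.approx(1 / 20)

    def test_single_age_stratum_rejected(self):
        vals = {"a": 1.0, "b": 2.0}
        ages = {"a": "young", "b": "young"}
        values, samples = _twosample_instance(vals, ages)
        with pytest.raises(ValueError, match="two labels"):
            twosample_stratified_perm_test(values, samples)


class TestTrend:
    def _monotone_instance(self, n_donors=4, reverse=False):
        rows, vals = [], {}
        for d in range(n_donors):
            for si, sub in enumerate(("naive", "CM", "EM")):
                sid = f"d{d}_{sub}"
                rows.append({"sample": sid, "donor": f"d{d}", "subset": sub,
                             "subset_rank": (2 - si) if reverse else si,
                             "age_group": "young"})
                vals[sid] = si + 0.01 * d
        samples = pd.DataFrame(rows).set_index("sample", drop=False)
        return pd.Series(vals), samples

    def test_perfect_trend_attains_minimum_p(self):
        values, samples = self._monotone_instance(4)
        r = stratified_trend_test(values, samples, strata=("age_group",))
        assert r.exhaustive and r.n_arrangements == 6**4
        # only the all-identity and all-reversed label assignments reach |obs|
        assert r.p_value == pytest.approx(2 / 6**4)

    def test_reversing_ordinal_direction_keeps_two_sided_p(self):
        v1, s1 = self._monotone_instance(3)
        v2, s2 = self._monotone_instance(3, reverse=True)
        r1 = stratified_trend_test(v1, s1, strata=("age_group",))
        r2 = stratified_trend_test(v2, s2, strata=("age_group",))
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_null_p_values_roughly_uniform(self):
        """Scores independent of subset: KS test must not reject uniformity."""
        rng = np.random.default_rng(TEST_SEED)
        ps = []
        for _ in range(120):
            samples, values = null_score_cohort(rng, 3, 3, lineages=("CD4",))
            r = stratified_trend_test(values, samples, n_perm=99,
                                      seed=int(rng.integers(2**31)))
            ps.append(r.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_level_stratum_rejected(self):
        values, samples = self._monotone_instance(2)
        samples["subset_rank"] = 1
        with pytest.raises(ValueError, match="ordinal"):
            stratified_trend_test(values, samples, strata=("age_group",))


class TestOrderingProbability:
    def test_four_groups_matches_one_in_twentyfour(self):
        means = {"cm_old": 4.0, "cm_young": 3.0, "naive_old": 2.0, "naive_young": 1.0}
        ok, p = ordering_probability(
            means, ["cm_old", "cm_young", "naive_old", "naive_young"])
        assert ok
        assert p == pytest.approx(1 / 24)
        assert round(p, 3) == 0.042

    def test_two_groups(self):
        ok, p = ordering_probability({"a": 1.0, "b": 0.0}, ["a", "b"])
        assert ok and p == 0.5

    def test_three_groups_against_enumeration(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        _, p = ordering_probability(means, ["a", "b", "c"])
        favorable = sum(
            1 for perm in itertools.permutations(means.values())
            if perm[0] > perm[1] > perm[2])
        assert p == pytest.approx(favorable / math.factorial(3))
        assert p == pytest.approx(1 / 6)

    def test_mismatch_detected_and_ties_rejected(self):
        ok, _ = ordering_probability({"a": 0.0, "b": 1.0}, ["a", "b"])
        assert not ok
        with pytest.raises(ValueError, match="tie"):
            ordering_probability({"a": 1.0, "b": 1.0}, ["a", "b"])


def test_every_permutation_p_is_positive(rng):
    samples, values = null_score_cohort(rng, 3, 3)
    for fn in (paired_stratified_perm_test, twosample_stratified_perm_test):
        r = fn(values, samples, n_perm=200, seed=1)
        assert r.p_value >= 1 / (r.n_arrangements + 1)
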