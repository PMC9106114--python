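"""Shapiro-Wilk, Kruskal-Wallis, Dunn post-hoc, compact letter display."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vcgkit import (
    MethodComparison,
    compact_letter_display,
    dunn_posthoc,
    kruskal_wallis,
    run_full_comparison,
    shapiro_wilk,
)
from vcgkit.comparison import DegenerateInputError


def kw_permutation_p(groups, n_resamples, rng):
    """Brute-force permutation p-value for the Kruskal-Wallis statistic."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    obs = kruskal_wallis(groups).statistic
    idx = np.argsort(rng.random((n_resamples, n)), axis=1)
    permuted = ranks[idx]
    edges = np.cumsum(sizes)[:-1]
    t2 = sum(
        part.sum(axis=1) ** 2 / part.shape[1]
        for part in np.split(permuted, edges, axis=1)
    )
    q = -3.0 * (n + 1) + 12.0 / (n * (n + 1)) * t2
    _, counts = np.unique(pooled, return_counts=True)
    q /= 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return (np.sum(q >= obs - 1e-12) + 1) / (n_resamples + 1)


def brute_force_letter_relation(letters):
    """Symmetric boolean 'shares a letter' relation from a letter map."""
    labels = list(letters)
    k = len(labels)
    rel = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        rel[i, j] = rel[j, i] = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
    np.fill_diagonal(rel, True)
    return rel


class TestShapiroWilk:
    def test_w_bounded_by_one(self, rng):
        for _ in range(10):
            res = shapiro_wilk(rng.normal(size=rng.integers(5, 50)))
            assert 0.0 < res.statistic <= 1.0

    def test_affine_invariance(self, rng):
        x = rng.exponential(size=40)
        a = shapiro_wilk(x)
        b = shapiro_wilk(5.0 * x - 3.0)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([1.0] * 10)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            shapiro_wilk([1.0, 2.0])

    def test_type_one_error_calibrated(self):
        # N(0,1), n=30: rejection rate at alpha=0.05 must sit near 0.05
        rng = np.random.default_rng(42)
        rejections = sum(
            shapiro_wilk(rng.normal(size=30)).p_value < 0.05 for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_power_against_exponential(self):
        rng = np.random.default_rng(43)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=30)).p_value < 0.05 for _ in range(2000)
        )
        assert rejections / 2000 >= 0.5


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_equal_mean_rank_groups_give_zero(self):
        res = kruskal_wallis([[1, 6], [2, 5], [3, 4]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [np.round(rng.normal(size=rng.integers(5, 15)), 1)
                      for _ in range(rng.integers(2, 5))]
            mine = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_no_ties_equals_tie_corrected_form(self, rng):
        # distinct values: the correction factor is exactly 1
        values = rng.permutation(30).astype(float)
        groups = [values[:10], values[10:20], values[20:]]
        n, t = 30, [g.sum() for g in (sps.rankdata(values)[:10],
                                      sps.rankdata(values)[10:20],
                                      sps.rankdata(values)[20:])]
        uncorrected = -3 * (n + 1) + 12 / (n * (n + 1)) * sum(
            sps.rankdata(np.concatenate(groups))[i * 10:(i + 1) * 10].sum() ** 2 / 10
            for i in range(3)
        )
        assert kruskal_wallis(groups).statistic == pytest.approx(uncorrected)

    def test_permutation_oracle_agreement(self):
        # chi-square p vs 10,000-resample permutation p at total n = 15;
        # agreement is limited by the chi-square approximation itself,
        # whose error at this sample size reaches ~0.05
        rng = np.random.default_rng(2024)
        for _ in range(10):
            groups = [rng.normal(size=5) for _ in range(3)]
            p_chi = kruskal_wallis(groups).p_value
            p_perm = kw_permutation_p(groups, 10_000, rng)
            assert abs(p_chi - p_perm) <= 0.06

    def test_small_groups_warn(self):
        with pytest.warns(UserWarning, match="fewer than 5"):
            kruskal_wallis([[1, 2, 3], [4, 5, 6]])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([[1, 2, 3]])

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis([[2.0] * 6, [2.0] * 6])


class TestDunnPosthoc:
    def test_identical_groups_give_z_zero_p_one(self):
        res = dunn_posthoc([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]], ["a", "b"])
        assert res.z_matrix[0, 1] == pytest.approx(0.0)
        assert res.p_matrix[0, 1] == pytest.approx(1.0)

    def test_p_matrix_symmetric_unit_diagonal(self, rng):
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.5, 2.0)]
        res = dunn_posthoc(groups, ["g0", "g1", "g2"])
        np.testing.assert_allclose(res.p_matrix, res.p_matrix.T)
        np.testing.assert_array_equal(np.diag(res.p_matrix), 1.0)

    def test_z_antisymmetric(self, rng):
        groups = [rng.normal(loc=m, size=10) for m in (0.0, 1.0, 3.0, 5.0)]
        res = dunn_posthoc(groups, list("abcd"))
        np.testing.assert_allclose(res.z_matrix, -res.z_matrix.T, atol=1e-12)

    def test_separated_group_isolated(self):
        g1 = list(range(1, 11))
        g2 = list(range(1, 11))
        g3 = list(range(101, 111))
        res = dunn_posthoc([g1, g2, g3], ["a", "b", "far"], alpha=0.05)
        assert res.p_matrix[0, 2] < 0.05 and res.p_matrix[1, 2] < 0.05
        assert res.p_matrix[0, 1] >= 0.05
        assert res.letters["far"] not in (res.letters["a"], res.letters["b"])
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_bonferroni_never_smaller_than_unadjusted(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.7, 1.5)]
        plain = dunn_posthoc(groups, list("abc"), adjust="none")
        bonf = dunn_posthoc(groups, list("abc"), adjust="bonferroni")
        iu = np.triu_indices(3, 1)
        assert (bonf.p_matrix[iu] >= plain.p_matrix[iu] - 1e-12).all()

    def test_holm_between_none_and_bonferroni(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.7, 1.5, 2.0)]
        plain = dunn_posthoc(groups, list("abcd"), adjust="none")
        holm = dunn_posthoc(groups, list("abcd"), adjust="holm")
        bonf = dunn_posthoc(groups, list("abcd"), adjust="bonferroni")
        iu = np.triu_indices(4, 1)
        assert (holm.p_matrix[iu] >= plain.p_matrix[iu] - 1e-12).all()
        assert (holm.p_matrix[iu] <= bonf.p_matrix[iu] + 1e-12).all()


class TestCompactLetterDisplay:
    def _cld(self, sig_pairs, k=4, medians=None):
        labels = [f"m{i}" for i in range(k)]
        p = np.ones((k, k))
        for i, j in sig_pairs:
            p[i, j] = p[j, i] = 0.01
        medians = medians or {lab: float(i) for i, lab in enumerate(labels)}
        return compact_letter_display(p, labels, medians, alpha=0.05)

    def test_no_significant_pairs_single_letter(self):
        letters, _ = self._cld([])
        assert all(l == "a" for l in letters.values())

    def test_all_pairs_significant_distinct_singletons(self):
        letters, _ = self._cld(list(itertools.combinations(range(4), 2)))
        values = list(letters.values())
        assert all(len(l) == 1 for l in values)
        assert len(set(values)) == 4

    def test_chain_case(self):
        # A~B, B~C, A!~C with medians A<B<C  ->  A:'a', B:'ab', C:'b'
        letters, order = self._cld([(0, 2)], k=3)
        assert letters == {"m0": "a", "m1": "ab", "m2": "b"}
        assert [m for m, _, _ in order] == ["m0", "m1", "m2"]

    def test_letter_a_tags_best_median_group(self):
        letters, order = self._cld(
            [(0, 1), (0, 2), (0, 3)],
            medians={"m0": 9.0, "m1": 1.0, "m2": 2.0, "m3": 3.0},
        )
        # m1-m3 form the accurate homogeneous group -> letter 'a'
        assert letters["m1"] == letters["m2"] == letters["m3"] == "a"
        assert letters["m0"] == "b"
        assert order[0][0] == "m1"

    def test_exhaustive_k4_matches_relation(self):
        # all 64 significance patterns over the 6 pairs of k=4 methods:
        # sharing a letter must coincide exactly with non-significance
        labels = ["m0", "m1", "m2", "m3"]
        medians = {lab: float(i) for i, lab in enumerate(labels)}
        pairs = list(itertools.combinations(range(4), 2))
        for pattern in itertools.product([0, 1], repeat=6):
            p = np.ones((4, 4))
            for bit, (i, j) in zip(pattern, pairs):
                if bit:
                    p[i, j] = p[j, i] = 0.001
            letters, _ = compact_letter_display(p, labels, medians, alpha=0.05)
            assert all(letters[lab] for lab in labels), pattern
            rel = brute_force_letter_relation(letters)
            expected = p >= 0.05
            np.fill_diagonal(expected, True)
            np.testing.assert_array_equal(rel, expected, err_msg=str(pattern))


class TestFullComparison:
    @staticmethod
    def _table(rng, shift=None):
        rows = []
        for lead in ("X", "Y", "Z"):
            for m, method in enumerate(["kors", "idt", "qlsv", "quasi"]):
                values = rng.lognormal(mean=-2.0, sigma=0.5, size=30)
                if shift is not None and method == shift:
                    values = values + 50.0
                rows += [
                    {"record_id": f"r{i}", "method": method, "lead": lead, "mse": v}
                    for i, v in enumerate(values)
                ]
        return pd.DataFrame(rows)

    def test_null_calibration(self):
        # all methods drawn from one distribution: KW must reject rarely
        rng = np.random.default_rng(7)
        rejections = 0
        n_cohorts = 200
        for _ in range(n_cohorts):
            groups = [rng.lognormal(-2.0, 0.5, size=30) for _ in range(4)]
            if kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        assert rejections / n_cohorts <= 0.10

    def test_strong_effect_isolates_method(self, rng):
        results = run_full_comparison(self._table(rng, shift="quasi"))
        for lead in ("X", "Y", "Z"):
            letters = results.letters(lead)
            others = {m: l for m, l in letters.items() if m != "quasi"}
            assert not set(letters["quasi"]) & set("".join(others.values()))

    def test_report_shape(self, rng):
        results = run_full_comparison(self._table(rng))
        report = results.to_dict()
        assert set(report["leads"]) == {"X", "Y", "Z"}
        for lead in ("X", "Y", "Z"):
            assert len(report["leads"][lead]["letters"]) == 4
            assert len(report["leads"][lead]["resulting_order"]) == 4

    def test_no_rejection_means_single_group(self, rng):
        results = run_full_comparison(self._table(rng))
        for lead, comp in results.per_lead.items():
            if comp.kruskal.p_value >= 0.05:
                assert set(results.letters(lead).values()) == {"a"}

    def test_summary_text_mentions_each_method(self, rng):
        text = run_full_comparison(self._table(rng)).summary()
        for method in ("kors", "idt", "qlsv", "quasi"):
            assert method in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            MethodComparison(pd.DataFrame({"method": [], "mse": []}))

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            MethodComparison(self._table(rng)).fit(alpha=1.5)
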