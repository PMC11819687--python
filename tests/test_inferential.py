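"""ANOVA, Tukey HSD, letter displays, effect sizes, Bayes factors, power."""

import math

import numpy as np
import pingouin
import pytest
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from figleaf.inferential import (anova_decomposition, anova_oneway,
                                 bayes_factor10, classify_effect, cohens_d,
                                 compact_letter_display, pairwise_panel,
                                 pairwise_t, posthoc_power, tukey_hsd)


class TestAnova:
    def test_hand_decomposed_f_statistic(self):
        F, p = anova_oneway([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert F == pytest.approx(27.0)
        assert p == pytest.approx(stats.f.sf(27.0, 2, 6))

    def test_agrees_with_scipy_oracle(self, rng):
        groups = [rng.normal(m, 1.5, 12) for m in (0, 0.5, 2.0, 2.1)]
        F, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_constant_groups_report_f_zero(self):
        F, p = anova_oneway([[2.0, 2.0], [2.0, 2.0]])
        assert (F, p) == (0.0, 1.0)

    def test_two_equal_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        F, _ = anova_oneway([a, b])
        T, _, _ = pairwise_t(a, b)
        assert F == pytest.approx(T * T, rel=1e-10)

    def test_sum_of_squares_is_conserved(self, rng):
        groups = [rng.normal(m, 2, n) for m, n in ((0, 8), (1, 12), (3, 5))]
        _, _, ssb, ssw, _, _ = anova_decomposition(groups)
        allv = np.concatenate(groups)
        sst = np.sum((allv - allv.mean()) ** 2)
        assert ssb + ssw == pytest.approx(sst, rel=1e-9)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        p = tukey_hsd([g, g, g])
        off = p[~np.eye(3, dtype=bool)]
        assert np.all(off > 0.99)

    def test_symmetric_with_unit_diagonal(self, rng):
        p = tukey_hsd([rng.normal(m, 1, 10) for m in (0, 1, 5)])
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(8, 1, 20)
        p = tukey_hsd([a, b])
        assert p[0, 1] < 0.001
        # studentized-range tail oracle for the two-group case
        q = abs(a.mean() - b.mean()) / math.sqrt(
            ((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2) / 20)
        assert p[0, 1] == pytest.approx(
            stats.studentized_range.sf(q, 2, 38), rel=1e-6, abs=1e-12)


class TestLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        p = np.full((3, 3), 0.9)
        np.fill_diagonal(p, 1.0)
        assert compact_letter_display(p, [3, 2, 1]) == ["a", "a", "a"]

    def test_all_pairs_significant_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        assert compact_letter_display(p, [3, 2, 1]) == ["a", "b", "c"]

    def test_chain_overlap_inserts_shared_letter(self):
        # A != C significant; A~B and B~C not
        p = np.array([[1.0, 0.5, 0.01],
                      [0.5, 1.0, 0.5],
                      [0.01, 0.5, 1.0]])
        assert compact_letter_display(p, [3, 2, 1]) == ["a", "ab", "b"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_roundtrip_letters_encode_significance(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        p = np.where(rng.random((n, n)) < 0.4, 0.01, 0.5)
        p = np.triu(p, 1)
        p = p + p.T
        np.fill_diagonal(p, 1.0)
        letters = compact_letter_display(p, rng.normal(size=n))
        for i in range(n):
            for j in range(i + 1, n):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share == (p[i, j] >= 0.05)

    def test_asymmetric_matrix_rejected(self):
        p = np.array([[1.0, 0.1], [0.5, 1.0]])
        with pytest.raises(ValueError):
            compact_letter_display(p, [1, 0])


class TestPairwiseT:
    def test_identical_groups_null_result(self):
        g = [1.0, 2.0, 3.0]
        T, p, ci = pairwise_t(g, g)
        assert T == 0 and p == pytest.approx(1.0)
        assert ci[0] <= 0 <= ci[1]

    def test_ci_excludes_zero_iff_significant(self, rng):
        for shift in (0.0, 0.3, 1.0, 3.0):
            a = rng.normal(0, 1, 20)
            b = rng.normal(shift, 1, 20)
            _, p, ci = pairwise_t(a, b)
            assert (p < 0.05) == (ci[0] > 0 or ci[1] < 0)

    def test_strong_separation_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        _, p, _ = pairwise_t(a, b)
        assert p < 0.001

    def test_matches_scipy_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 17)
        T, p, _ = pairwise_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert T == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            pairwise_t([1.0, 1.0], [2.0, 2.0])


class TestEffectSize:
    @pytest.mark.parametrize("d, label", [
        (11.90, "Huge"), (1.86, "Very large"), (0.00, "Negligible"),
        (0.15, "Very small"), (0.3, "Small"), (0.6, "Medium"), (1.0, "Large"),
        (0.2, "Small"), (2.0, "Huge"),  # left-closed thresholds
    ])
    def test_class_labels(self, d, label):
        assert classify_effect(d) == label

    def test_every_magnitude_maps_to_exactly_one_label(self):
        for d in np.linspace(0, 15, 601):
            assert classify_effect(float(d)) in {
                "Negligible", "Very small", "Small", "Medium", "Large",
                "Very large", "Huge"}

    def test_cohens_d_pooled_sd(self):
        d = cohens_d([0.0, 2.0], [4.0, 6.0])
        # pooled sd = sqrt(2); |0-4|... means 1 vs 5 -> 4/sqrt(2)
        assert d == pytest.approx(4 / math.sqrt(2))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert bayes_factor10(0.0, 20, 20) < 1

    def test_monotone_in_t_magnitude(self):
        bfs = [bayes_factor10(t, 20, 20) for t in (0.0, 1.0, 2.5, 5.0, 10.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_pingouin_jzs_oracle(self):
        for t, na, nb in [(2.5, 20, 20), (0.8, 15, 30), (6.0, 10, 10)]:
            ours = bayes_factor10(t, na, nb)
            ref = float(pingouin.bayesfactor_ttest(t, na, nb, paired=False,
                                                   r=0.707))
            assert ours == pytest.approx(ref, rel=1e-4)


class TestPower:
    def test_zero_effect_power_is_alpha(self):
        assert posthoc_power(0.0, 20, 20) == pytest.approx(0.05, abs=1e-6)

    def test_huge_effect_power_is_one(self):
        assert posthoc_power(8.0, 20, 20) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_effect_and_n(self):
        assert posthoc_power(0.5, 20, 20) < posthoc_power(1.0, 20, 20)
        assert posthoc_power(0.5, 20, 20) < posthoc_power(0.5, 60, 60)

    def test_matches_statsmodels_oracle(self):
        for d, na, nb in [(0.5, 20, 20), (1.2, 15, 25)]:
            ref = TTestIndPower().power(effect_size=d, nobs1=na,
                                        ratio=nb / na, alpha=0.05,
                                        alternative="two-sided")
            assert posthoc_power(d, na, nb) == pytest.approx(ref, abs=1e-6)


def test_pairwise_panel_covers_all_pairs_with_consistent_labels(rng):
    samples = {c: rng.normal(m, 1, 12) for c, m in
               [("A", 0.0), ("B", 0.2), ("C", 4.0)]}
    panel = pairwise_panel(samples, "PL")
    assert len(panel) == 3
    for cmp_ in panel:
        assert 0 <= cmp_.p <= 1 and 0 <= cmp_.power <= 1 and cmp_.bf10 > 0
        assert cmp_.ci95[0] <= cmp_.ci95[1]
        assert cmp_.effect_class == classify_effect(cmp_.effect_size)
    big = next(c for c in panel if c.pair == ("A", "C"))
    assert big.effect_class in ("Very large", "Huge") and big.p < 0.001
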