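"""Trichome length-class binning, Poisson MLE, LRT, density clustering."""

import numpy as np
import pytest
from scipy import stats

from figleaf.synthetic import generate_trichome_lengths
from figleaf.trichome import (CLASS_BOUNDS, N_CLASSES, TrichomeHistogram,
                              bin_trichome_lengths, fit_lambda_mle,
                              lambda_density_dendrogram, lrt_poisson,
                              poisson_pmf, significance_matrix,
                              trichome_density)


def hist_from_counts(counts, cultivar="X"):
    return TrichomeHistogram(cultivar=cultivar, surface="lower",
                             counts=np.asarray(counts, dtype=int))


class TestBinning:
    def test_eleven_classes_defined(self):
        assert N_CLASSES == 11

    @pytest.mark.parametrize("length, cls", [
        (50.0, 1), (150.0, 3), (99.5, 1), (100.0, 2), (477.0, 11),
        (240.0, 5), (333.0, 7), (0.1, 1),
    ])
    def test_class_assignment(self, length, cls):
        h = bin_trichome_lengths([length])
        assert h.counts[cls - 1] == 1 and h.n == 1

    @pytest.mark.parametrize("bad", [0.0, -5.0, 500.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            bin_trichome_lengths([bad])

    def test_strict_mode_rejects_gap_values(self):
        assert bin_trichome_lengths([99.5]).counts[0] == 1
        with pytest.raises(ValueError):
            bin_trichome_lengths([99.5], strict=True)

    def test_strict_and_default_agree_on_printed_intervals(self, rng):
        lows = np.array([b[0] for b in CLASS_BOUNDS])
        highs = np.array([b[1] for b in CLASS_BOUNDS])
        vals = rng.uniform(lows, highs)
        a = bin_trichome_lengths(vals)
        b = bin_trichome_lengths(vals, strict=True)
        assert np.array_equal(a.counts, b.counts)


class TestPoissonPmf:
    def test_closed_form_at_zero(self):
        assert poisson_pmf(2.5, 0) == pytest.approx(np.exp(-2.5))
        assert poisson_pmf(0.0, 0) == 1.0

    def test_normalization(self):
        for lam in (0.1, 1.0, 3.0, 10.0):
            total = sum(poisson_pmf(lam, x) for x in range(101))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_support_rejected(self):
        with pytest.raises(ValueError):
            poisson_pmf(1.0, -1)


class TestMle:
    def test_all_mass_in_first_class_gives_zero_rate(self):
        fit = fit_lambda_mle(hist_from_counts([7] + [0] * 10))
        assert fit.lam == 0.0
        assert fit.loglik <= 0

    def test_half_and_half_gives_mean(self):
        fit = fit_lambda_mle(hist_from_counts([5, 5] + [0] * 9))
        assert fit.lam == pytest.approx(0.5)

    @pytest.mark.parametrize("lam", [0.1, 0.3, 1.8, 3.0])
    def test_mle_equals_grid_search_of_loglik(self, lam, rng):
        lengths = generate_trichome_lengths(lam, 400, rng)
        hist = bin_trichome_lengths(lengths)
        fit = fit_lambda_mle(hist)
        grid = np.arange(max(fit.lam - 0.3, 1e-4), fit.lam + 0.3, 1e-4)
        x = np.arange(N_CLASSES)
        ll = np.array([np.dot(hist.counts, stats.poisson.logpmf(x, g))
                       for g in grid])
        assert abs(grid[np.argmax(ll)] - fit.lam) <= 1e-4 + 1e-9

    def test_large_sample_recovery_near_printed_rate(self):
        lengths = generate_trichome_lengths(3.0, 20_000, seed=99)
        fit = fit_lambda_mle(bin_trichome_lengths(lengths))
        assert fit.lam == pytest.approx(3.0, abs=0.05)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            fit_lambda_mle(hist_from_counts([0] * 11))


class TestLrt:
    def test_identical_histograms_null(self):
        h = hist_from_counts([10, 5, 2, 1] + [0] * 7)
        res = lrt_poisson(h, h)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.tier == "NS"

    def test_statistic_non_negative_and_symmetric(self, rng):
        for _ in range(20):
            a = hist_from_counts(rng.integers(0, 30, 11))
            b = hist_from_counts(rng.integers(0, 30, 11))
            if a.n == 0 or b.n == 0:
                continue
            ab = lrt_poisson(a, b)
            ba = lrt_poisson(b, a)
            assert ab.statistic >= 0
            assert ab.statistic == pytest.approx(ba.statistic, rel=1e-12)

    def test_contrasting_rates_strongly_significant(self):
        a = bin_trichome_lengths(generate_trichome_lengths(0.1, 500, seed=1))
        b = bin_trichome_lengths(generate_trichome_lengths(3.0, 500, seed=2))
        res = lrt_poisson(a, b)
        assert res.tier == "***" and res.p < 0.001

    def test_statistic_matches_grid_search_null_oracle(self, rng):
        a = bin_trichome_lengths(generate_trichome_lengths(0.8, 300, rng))
        b = bin_trichome_lengths(generate_trichome_lengths(1.6, 300, rng))
        res = lrt_poisson(a, b)
        # brute-force maximum of the common-rate log likelihood
        x = np.arange(N_CLASSES)
        grid = np.arange(1e-4, 4.0, 1e-4)

        def ll(counts, lam_grid):
            return np.array([np.dot(counts, stats.poisson.logpmf(x, g))
                             for g in lam_grid])

        null = ll(a.counts + b.counts, grid).max()
        alt = ll(a.counts, grid).max() + ll(b.counts, grid).max()
        assert res.statistic == pytest.approx(2 * (alt - null), abs=1e-4)

    def test_significance_matrix_symmetric_with_ns_diagonal(self):
        hists = [bin_trichome_lengths(
            generate_trichome_lengths(lam, 300, seed=i), cultivar=str(i))
            for i, lam in enumerate((0.3, 1.8, 1.8, 3.0))]
        M = significance_matrix(hists)
        for i in range(4):
            assert M[i][i] == "NS"
            for j in range(4):
                assert M[i][j] == M[j][i]
        assert M[0][3] == "***"

    def test_matched_rates_usually_ns_at_study_sample_sizes(self):
        # PA vs PE: same rate, n near the printed lower-page densities
        a = bin_trichome_lengths(generate_trichome_lengths(1.8, 188, seed=10))
        b = bin_trichome_lengths(generate_trichome_lengths(1.8, 175, seed=11))
        assert lrt_poisson(a, b).tier == "NS"


class TestDensity:
    def test_count_per_area(self):
        assert trichome_density(100, 4.0) == 25.0
        assert trichome_density(0, 2.0) == 0.0

    def test_non_positive_area_rejected(self):
        with pytest.raises(ValueError):
            trichome_density(10, 0.0)


class TestLambdaDensityTree:
    def test_identical_profiles_merge_at_zero(self):
        lam = {"a": 1.0, "b": 1.0, "c": 3.0}
        den = {"a": 50.0, "b": 50.0, "c": 90.0}
        t = lambda_density_dendrogram(lam, den)
        first = min(t.internal_nodes(), key=lambda n: n.height)
        assert first.leaf_labels() == frozenset({"a", "b"})
        assert first.height == pytest.approx(0.0)

    def test_fifteen_cultivars_fourteen_merges(self, rng):
        lam = {f"c{i}": float(rng.uniform(0, 3)) for i in range(15)}
        den = {f"c{i}": float(rng.uniform(20, 95)) for i in range(15)}
        t = lambda_density_dendrogram(lam, den)
        assert len(t.internal_nodes()) == 14

    def test_low_rate_low_density_cultivars_co_cluster(self):
        # FI-like and VE-like profiles segregate from the high-rate group
        lam = {"FI": 0.3, "VE": 0.1, "PO": 3.0, "PA": 1.8, "PE": 1.8}
        den = {"FI": 23.2, "VE": 48.2, "PO": 61.5, "PA": 93.8, "PE": 87.5}
        t = lambda_density_dendrogram(lam, den)
        clades = {n.leaf_labels() for n in t.internal_nodes()}
        assert frozenset({"FI", "VE"}) in clades
        assert frozenset({"PA", "PE"}) in clades

    def test_mismatched_cultivar_sets_rejected(self):
        with pytest.raises(ValueError):
            lambda_density_dendrogram({"a": 1.0}, {"b": 2.0})
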