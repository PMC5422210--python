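"""Monotone background fitting, rank-product inference and peak calls."""

import itertools

import numpy as np
import pytest
from scipy import stats

from loopscape import (
    FourCProfile,
    GenomicInterval,
    call_peaks,
    combined_rank,
    enrichment_stats,
    fit_monotonic_background,
    gen_4c_profile,
    peakc_analysis,
    rank_product_p,
)

VP = GenomicInterval("chrT", 999_000, 1_001_000)


def profile_one_side(counts, spacing=1_000.0):
    """Downstream-only profile with unit spacing (distance order = index)."""
    n = len(counts)
    pos = VP.midpoint + spacing * np.arange(1, n + 1)
    return FourCProfile(VP, pos, np.asarray(counts, dtype=float))


def brute_force_monotone_fit(y):
    """Exact non-increasing least squares by enumerating level-set partitions."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    best_fit, best_sse = None, np.inf
    for mask in range(1 << (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if (mask >> i) & 1] + [n]
        means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        if any(means[i] < means[i + 1] - 1e-12 for i in range(len(means) - 1)):
            continue
        fit = np.concatenate(
            [np.full(b - a, m) for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), means)]
        )
        sse = ((fit - y) ** 2).sum()
        if sse < best_sse - 1e-15:
            best_sse, best_fit = sse, fit
    return best_fit


class TestMonotonicBackground:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 3, 4, 1], [5, 3.5, 3.5, 1]),
            ([9, 4, 2, 2], [9, 4, 2, 2]),
            ([3, 3, 3], [3, 3, 3]),
        ],
    )
    def test_hand_examples(self, counts, expected):
        fit = fit_monotonic_background(profile_one_side(counts))
        np.testing.assert_allclose(fit, expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            y = rng.uniform(0, 10, size=rng.integers(2, 9))
            fit = fit_monotonic_background(profile_one_side(y))
            oracle = brute_force_monotone_fit(y)
            assert np.abs(fit - oracle).max() < 1e-9

    def test_fit_conserves_mean_per_side(self, rng):
        y = rng.uniform(0, 50, size=40)
        fit = fit_monotonic_background(profile_one_side(y))
        assert fit.mean() == pytest.approx(y.mean())

    def test_sides_fit_independently(self, rng):
        n = 30
        pos = np.sort(VP.midpoint + np.concatenate([-np.arange(1, n + 1), np.arange(1, n + 1)]) * 500.0)
        counts = rng.poisson(20, size=2 * n).astype(float)
        prof = FourCProfile(VP, pos, counts)
        fit = fit_monotonic_background(prof)
        sides = prof.sides()
        for side in (-1, 1):
            sub = FourCProfile(VP, pos[sides == side], counts[sides == side])
            np.testing.assert_allclose(fit[sides == side], fit_monotonic_background(sub))

    def test_degenerate_side_warns_and_copies(self):
        pos = np.array([VP.midpoint - 500.0, VP.midpoint + 500.0, VP.midpoint + 1500.0])
        prof = FourCProfile(VP, pos, np.array([7.0, 3.0, 5.0]))
        with pytest.warns(UserWarning, match="<2 fragments"):
            fit = fit_monotonic_background(prof)
        assert fit[0] == 7.0


class TestEnrichmentStats:
    @pytest.mark.parametrize(
        "obs,exp,r,d",
        [(10, 5, 2.0, 5.0), (4, 4, 1.0, 0.0), (0, 4, 0.0, -4.0)],
    )
    def test_arithmetic(self, obs, exp, r, d):
        ratio, delta = enrichment_stats(np.array([obs]), np.array([exp]))
        assert ratio[0] == pytest.approx(r)
        assert delta[0] == pytest.approx(d)

    def test_pseudocount_guards_small_background(self):
        ratio, _ = enrichment_stats(np.array([10.0]), np.array([0.1]))
        assert ratio[0] == 10.0  # divided by eps=1, not 0.1


class TestCombinedRank:
    def test_concordant_ranks(self):
        ranks = combined_rank(np.array([30, 20, 10]), np.array([3, 2, 1]))
        np.testing.assert_array_equal(ranks, [1, 2, 3])

    def test_discordant_pair_ties_to_average(self):
        ranks = combined_rank(np.array([2.0, 1.0]), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(ranks, [1.5, 1.5])

    def test_single_fragment(self):
        np.testing.assert_array_equal(combined_rank(np.array([5.0]), np.array([1.0])), [1])


class TestRankProductP:
    def test_k1_closed_form(self):
        for r in (1, 7, 50, 99):
            _, p = rank_product_p(np.array([[float(r)]]), n=99, k=1)
            assert p[0] == pytest.approx(r / 100.0, rel=1e-12)

    def test_worst_rank_gives_p_near_one(self):
        # worst achievable ranks: rho -> 1 and P -> 1 (exact at rho = 1)
        _, p = rank_product_p(np.full((2, 1), 100.0), n=100, k=2)
        assert 0.999 < p[0] <= 1.0
        assert stats.gamma.sf(0.0, a=2) == 1.0  # the rho = 1 boundary

    def test_monotone_in_rank_product(self):
        ranks = np.vstack([np.arange(1, 51), np.arange(1, 51)]).astype(float)
        _, p = rank_product_p(ranks, n=50, k=2)
        assert np.all(np.diff(p) > 0)

    def test_rank_outside_range_errors(self):
        with pytest.raises(ValueError):
            rank_product_p(np.array([[0.5]]), n=10, k=1)
        with pytest.raises(ValueError):
            rank_product_p(np.array([[11.0]]), n=10, k=1)

    def test_null_calibration_discrete_permutations(self, rng):
        """Fraction of null fragments below alpha stays within 1.5*alpha.

        The Gamma approximation is evaluated against the discrete rank
        null it approximates: per profile the per-replicate ranks are
        independent permutations.
        """
        n, k, n_profiles = 150, 3, 200
        frac = {0.01: 0.0, 0.05: 0.0}
        count = 0
        for _ in range(n_profiles):
            ranks = np.vstack([rng.permutation(n) + 1.0 for _ in range(k)])
            _, p = rank_product_p(ranks, n=n, k=k)
            for a in frac:
                frac[a] += (p < a).sum()
            count += n
        for a in frac:
            assert frac[a] / count <= 1.5 * a


class TestCallPeaks:
    @staticmethod
    def result_with_pvalues(pvals, spacing=1_000):
        from loopscape.peakc import PeakCResult

        n = len(pvals)
        pos = VP.midpoint + spacing * np.arange(1, n + 1)
        z = np.zeros((1, n))
        return PeakCResult(
            viewpoint=VP, positions=pos, observed=z, expected=z, ratio=z,
            delta=z, ranks=z + 1, rank_product=np.ones(n),
            pvalue=np.asarray(pvals, dtype=float), n=n, k=1,
        )

    def test_no_significant_fragments(self):
        res = self.result_with_pvalues([0.5] * 10)
        assert call_peaks(res, alpha=0.01) == []

    def test_adjacent_significant_fragments_merge(self):
        res = self.result_with_pvalues([0.9, 1e-5, 1e-5, 1e-5, 0.9])
        peaks = call_peaks(res, alpha=0.01, min_fragments=3)
        assert len(peaks) == 1
        assert peaks[0].start == int(res.positions[1])

    def test_merge_gap_bridges_one_nonsignificant_fragment(self):
        res = self.result_with_pvalues([1e-5, 1e-5, 0.9, 1e-5, 1e-5])
        assert len(call_peaks(res, alpha=0.01, merge_gap=1, min_fragments=3)) == 1
        assert len(call_peaks(res, alpha=0.01, merge_gap=0, min_fragments=2)) == 2

    def test_invalid_alpha_errors(self):
        res = self.result_with_pvalues([0.5])
        with pytest.raises(ValueError):
            call_peaks(res, alpha=1.5)


class TestFullAnalysis:
    def test_planted_peaks_recovered_without_false_calls(self):
        planted = [(920_000.0, 10.0), (1_090_000.0, 10.0)]
        profiles, _ = gen_4c_profile(peaks=planted, seed=11)
        res = peakc_analysis(profiles)
        peaks = call_peaks(res, alpha=0.01)
        assert len(peaks) == 2
        for (pos, _), peak in zip(sorted(planted), peaks):
            assert peak.start <= pos <= peak.end

    def test_peak_calls_invariant_to_coverage_scaling(self):
        profiles, _ = gen_4c_profile(
            peaks=[(920_000.0, 10.0)], seed=5, replicates=2
        )
        scaled = [
            FourCProfile(p.viewpoint, p.positions, p.counts * 13.0, p.replicate)
            for p in profiles
        ]
        r1 = peakc_analysis(profiles)
        r2 = peakc_analysis(scaled)
        # ranks agree up to floating-point tie resolution in the ratios
        assert np.abs(r1.ranks - r2.ranks).max() <= 0.02 * r1.n
        p1 = call_peaks(r1)
        p2 = call_peaks(r2)
        assert [(p.start, p.end) for p in p1] == [(q.start, q.end) for q in p2]
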