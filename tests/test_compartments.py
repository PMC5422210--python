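"""Compartment eigenvectors, switch detection, DamID ratios and LAD calls."""

import numpy as np
import pytest

from loopscape import (
    ContactMatrix,
    GenomicInterval,
    Track,
    call_lads,
    compartment_eigenvector,
    damid_log_ratio,
    detect_switches,
    gen_contact_matrix,
    gen_damid_track,
    switch_totals_mb,
)
from loopscape.compartments import DamIDTrack
from loopscape.digestion import ExtendedGATCFragment


def block_vector(n, period):
    v = np.sign(np.sin(np.arange(n) * 2 * np.pi / period))
    v[v == 0] = 1.0
    return v


class TestCompartmentEigenvector:
    def test_plaid_vector_recovered(self):
        v = block_vector(200, 50)
        m, _ = gen_contact_matrix(
            n_bins=200, bin_size=100_000, compartment_vector=v, base=400.0, seed=2
        )
        track = compartment_eigenvector(m, reference=v)
        r = np.corrcoef(track.values, v)[0, 1]
        assert abs(r) >= 0.95

    def test_reference_flip_flips_sign(self):
        v = block_vector(100, 20)
        m, _ = gen_contact_matrix(
            n_bins=100, bin_size=100_000, compartment_vector=v, base=400.0, seed=3
        )
        t1 = compartment_eigenvector(m, reference=v)
        t2 = compartment_eigenvector(m, reference=-v)
        np.testing.assert_allclose(t1.values, -t2.values)

    def test_checkerboard_toy_splits_by_block(self):
        v = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        m, _ = gen_contact_matrix(
            n_bins=12, bin_size=100_000, compartment_vector=v,
            kappa=0.5, noise=False, seed=0,
        )
        track = compartment_eigenvector(m, reference=v)
        assert np.all(np.sign(track.values) == v)

    def test_degenerate_matrix_errors(self):
        m = ContactMatrix("chrT", 100_000, np.ones((12, 12)))
        with pytest.raises(ValueError, match="degenerate"):
            compartment_eigenvector(m)

    def test_too_few_covered_bins_errors(self):
        m = ContactMatrix("chrT", 100_000, np.eye(5))
        with pytest.raises(ValueError):
            compartment_eigenvector(m)

    def test_scale_invariant_up_to_sign(self):
        v = block_vector(60, 20)
        m, _ = gen_contact_matrix(
            n_bins=60, bin_size=100_000, compartment_vector=v, base=300.0, seed=4
        )
        scaled = ContactMatrix(m.chrom, m.bin_size, m.values * 11.0)
        t1 = compartment_eigenvector(m, reference=v)
        t2 = compartment_eigenvector(scaled, reference=v)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)


def track_from(values, bin_size=100_000):
    values = np.asarray(values, dtype=float)
    return Track("chrT", np.arange(len(values)) * bin_size, values)


class TestDetectSwitches:
    def test_identical_tracks_no_switches(self, rng):
        t = track_from(rng.normal(0, 1, 50))
        assert detect_switches(t, t) == []

    def test_rule_arithmetic_b_to_a(self):
        # wild-type percentiles give threshold 0.8; one bin flips -0.5 -> +0.5
        base = np.concatenate([np.linspace(-0.8, 0.8, 20), [-0.5]])
        mut = base.copy()
        mut[-1] = 0.5
        calls = detect_switches(track_from(base), track_from(mut))
        assert len(calls) == 1
        assert calls[0].direction == "BtoA"
        assert calls[0].threshold == pytest.approx(
            (np.percentile(base, 85) - np.percentile(base, 15)) / 2
        )

    def test_no_sign_flip_is_never_a_switch(self):
        base = np.concatenate([np.linspace(-0.8, 0.8, 20), [-2.0]])
        mut = base.copy()
        mut[-1] = -0.1  # large difference but same sign
        assert detect_switches(track_from(base), track_from(mut)) == []

    def test_adjacent_same_direction_bins_merge(self):
        base = np.concatenate([np.linspace(-0.1, 0.1, 20), [0.5, 0.5, 0.5]])
        mut = base.copy()
        mut[-3:] = -0.5
        calls = detect_switches(track_from(base), track_from(mut))
        assert len(calls) == 1
        assert calls[0].direction == "AtoB"
        assert calls[0].interval.length == 300_000

    def test_every_switched_bin_in_exactly_one_call(self, rng):
        wt = track_from(rng.normal(0, 0.5, 200))
        mut = track_from(rng.normal(0, 0.5, 200))
        calls = detect_switches(wt, mut)
        covered = []
        for c in calls:
            covered.extend(
                range(c.interval.start, c.interval.end, 100_000)
            )
        assert len(covered) == len(set(covered))
        totals = switch_totals_mb(calls)
        assert totals["AtoB"] + totals["BtoA"] == pytest.approx(
            len(covered) * 0.1
        )


class TestDamIDLogRatio:
    @staticmethod
    def frags(n, size=50_000):
        return [
            ExtendedGATCFragment(
                GenomicInterval("chrT", i * size, (i + 1) * size), 1
            )
            for i in range(n)
        ]

    def test_equal_counts_zero(self):
        t = damid_log_ratio(self.frags(3), [5, 5, 5], [5, 5, 5], pseudocount=0)
        np.testing.assert_allclose(t.values, 0.0)

    def test_ratio_arithmetic_without_pseudocount(self):
        t = damid_log_ratio(self.frags(1), [8], [2], pseudocount=0)
        assert t.values[0] == pytest.approx(2.0)

    def test_both_zero_masked(self):
        t = damid_log_ratio(self.frags(2), [0, 4], [0, 1])
        assert np.isnan(t.values[0]) and np.isfinite(t.values[1])


class TestCallLADs:
    @staticmethod
    def track_kb(segments):
        """segments: list of (length_kb, value) tiles -> DamIDTrack."""
        frags, vals = [], []
        pos = 0
        for length_kb, val in segments:
            end = pos + length_kb * 1000
            frags.append(
                ExtendedGATCFragment(GenomicInterval("chrT", pos, end), 1)
            )
            vals.append(val)
            pos = end
        return DamIDTrack(frags, np.array(vals, dtype=float))

    def test_small_gap_bridged(self):
        # 1000 kb + 150 kb gap + 1000 kb: 150 < 20% of 2150 -> one LAD
        t = self.track_kb([(1000, 1.0), (150, -1.0), (1000, 1.0)])
        lads = call_lads(t)
        assert [(l.start, l.end) for l in lads] == [(0, 2_150_000)]

    def test_exact_twenty_percent_gap_not_bridged(self):
        # 400 + 200 + 400: gap exactly 20% of would-be 1000 kb LAD
        t = self.track_kb([(400, 1.0), (200, -1.0), (400, 1.0)])
        lads = call_lads(t)
        assert len(lads) == 2

    def test_no_enrichment_empty(self):
        t = self.track_kb([(500, -1.0), (500, -0.2)])
        assert call_lads(t) == []

    def test_masked_fragments_count_as_not_enriched(self):
        # 100 kb masked gap between 500 kb runs: 100/1100 < 20% -> bridged
        t = self.track_kb([(500, 1.0), (100, np.nan), (500, 1.0)])
        assert [(l.start, l.end) for l in call_lads(t)] == [(0, 1_100_000)]
        # masked gap too large relative to the runs: not bridged
        t2 = self.track_kb([(100, 1.0), (100, np.nan), (100, 1.0)])
        assert len(call_lads(t2)) == 2

    def test_mirror_symmetry(self):
        for seed in range(10):
            track, truth = gen_damid_track(
                lads=[(20, 50), (90, 140), (160, 180)], sigma=0.3, seed=seed
            )
            fwd = call_lads(track)
            total = track.fragments[-1].interval.end
            rev_frags = [
                ExtendedGATCFragment(
                    GenomicInterval(
                        "chrT",
                        total - f.interval.end,
                        total - f.interval.start,
                    ),
                    1,
                )
                for f in reversed(track.fragments)
            ]
            rev = call_lads(DamIDTrack(rev_frags, track.values[::-1].copy()))
            mirrored = sorted((total - l.end, total - l.start) for l in rev)
            assert sorted((l.start, l.end) for l in fwd) == mirrored

    def test_noiseless_recovery_exact(self):
        track, truth = gen_damid_track(lads=[(30, 60), (120, 170)], sigma=0.0, seed=1)
        lads = call_lads(track)
        assert [[l.start, l.end] for l in lads] == truth.lads

    def test_noisy_recovery_of_planted_bp(self):
        recovered, boundary_errs = [], []
        for seed in range(25):
            track, truth = gen_damid_track(
                lads=[(30, 60), (120, 170)], sigma=0.3, seed=seed
            )
            lads = call_lads(track)
            planted = [(a, b) for a, b in truth.lads]
            total_planted = sum(b - a for a, b in planted)
            got = 0
            for a, b in planted:
                for l in lads:
                    got += max(0, min(b, l.end) - max(a, l.start))
            recovered.append(got / total_planted)
            # boundary error in fragments for matched LADs
            sizes = np.array([f.interval.length for f in track.fragments])
            med = float(np.median(sizes))
            for a, b in planted:
                best = min(
                    lads,
                    key=lambda l: abs(l.start - a) + abs(l.end - b),
                    default=None,
                )
                if best is not None:
                    boundary_errs.append(abs(best.start - a) / med)
                    boundary_errs.append(abs(best.end - b) / med)
        assert np.mean(recovered) >= 0.95
        assert np.mean(boundary_errs) <= 1.0
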