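import numpy as np
import pandas as pd
import pytest

from aneuhic.readdepth import (
    RDProfile,
    correct_rd_signal,
    count_window_reads,
    fragment_counts,
    rd_baseline,
    rd_from_fragment_counts,
    rd_from_genomic_pairs,
)
from aneuhic.restriction import BinFeatureTrack, build_fragment_end_windows

from conftest import make_pairs, make_rmap


def _valid_pairs_at(positions):
    """One single-chromosome valid-style pair per position; side2 far away, unmapped."""
    return (
        make_pairs([("chrT", p, "+", True, "chrT", 0, "+", False) for p in positions]),
        pd.Series(["single_sided"] * len(positions)),
    )


class TestWindowCounting:
    def test_counts_per_window(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        # fragment 0: left [0,300), right [700,1000)
        pairs, classes = _valid_pairs_at([10, 20, 30, 710, 720])
        counts = count_window_reads(pairs, classes, wins)
        assert counts[0] == 3 and counts[1] == 2

    def test_zero_reads(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        pairs, classes = _valid_pairs_at([])
        assert count_window_reads(pairs, classes, wins).sum() == 0

    def test_side_outside_windows_discarded(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        pairs, classes = _valid_pairs_at([500])  # gap between windows of fragment 0
        assert count_window_reads(pairs, classes, wins).sum() == 0

    def test_valid_pair_counts_both_sides_noninformative_once(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        pairs = make_pairs(
            [
                ("chrT", 10, "+", True, "chrT", 2600, "-", True),  # valid: 2 counts
                ("chrT", 20, "+", True, "chrT", 900, "-", True),  # dangling: 1 count
            ]
        )
        classes = pd.Series(["valid_pair", "dangling_end"])
        counts = count_window_reads(pairs, classes, wins)
        assert counts.sum() == 3

    def test_valid_only_restriction(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        pairs = make_pairs([("chrT", 20, "+", True, "chrT", 900, "-", True)])
        classes = pd.Series(["dangling_end"])
        assert count_window_reads(pairs, classes, wins, use_all_reads=False).sum() == 0


class TestFragmentCounts:
    def test_sum_of_two_windows(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        wc = np.zeros(len(wins))
        wc[0], wc[1] = 3, 2
        fc = fragment_counts(wc, wins, toy_rmap.n_fragments)
        assert fc[0] == 5

    def test_whole_window_passthrough(self):
        rmap = make_rmap(400, [])
        wins = build_fragment_end_windows(rmap, 300)
        fc = fragment_counts(np.array([7]), wins, 1)
        assert fc.tolist() == [7]

    def test_conservation(self, toy_rmap):
        wins = build_fragment_end_windows(toy_rmap, 300)
        pairs, classes = _valid_pairs_at([10, 20, 710, 1100, 2600, 3900])
        wc = count_window_reads(pairs, classes, wins)
        fc = fragment_counts(wc, wins, toy_rmap.n_fragments)
        assert fc.sum() == wc.sum() == 6


class TestEntireFragmentRD:
    def test_constant_counts(self, toy_rmap):
        rd = rd_from_fragment_counts(np.array([4, 4, 4]), toy_rmap, 500)
        np.testing.assert_allclose(rd.values, 4.0)

    def test_boundary_bin_weighted_mean(self):
        rmap = make_rmap(20, [6])
        rd = rd_from_fragment_counts(np.array([4, 9]), rmap, 10)
        assert rd.values[0] == pytest.approx((6 * 4 + 4 * 9) / 10)

    def test_matches_per_base_oracle(self, planted_genome):
        from aneuhic.restriction import digest_genome

        seq, _ = planted_genome
        rmap = digest_genome(seq, "AAGCTT", 1)
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=rmap.n_fragments)
        rd = rd_from_fragment_counts(counts, rmap, 5000)
        per_base = np.repeat(counts, rmap.fragment_lengths)
        expected = [
            per_base[i : i + 5000].mean() for i in range(0, len(per_base), 5000)
        ]
        np.testing.assert_allclose(rd.values, expected)


class TestGenomicRD:
    def test_single_pair_partial_bin(self):
        pairs = make_pairs([("c", 10, "+", True, "c", 10, "-", True)])
        classes = pd.Series(["genomic"])
        rd = rd_from_genomic_pairs(pairs, classes, 100, read_length=50, bin_size=50)
        assert rd.values[0] == pytest.approx(40 / 50)  # covers [10,60)
        assert rd.values[1] == pytest.approx(10 / 50)

    def test_zero_pairs(self):
        pairs = make_pairs([])
        rd = rd_from_genomic_pairs(pairs, pd.Series([], dtype=object), 1000, 50, 100)
        np.testing.assert_array_equal(rd.values, 0.0)

    def test_rejects_non_genomic(self):
        pairs = make_pairs([("c", 10, "+", True, "c", 60, "-", True)])
        with pytest.raises(ValueError):
            rd_from_genomic_pairs(pairs, pd.Series(["valid_pair"]), 1000, 50, 100)

    def test_matches_pileup_oracle(self):
        rng = np.random.default_rng(5)
        L, rl = 50_000, 50
        p1 = rng.integers(0, L - 2000, size=1000)
        p2 = p1 + rng.integers(0, 1500, size=1000)
        pairs = make_pairs(
            [("c", int(a), "+", True, "c", int(b), "-", True) for a, b in zip(p1, p2)]
        )
        classes = pd.Series(["genomic"] * 1000)
        rd = rd_from_genomic_pairs(pairs, classes, L, rl, 5000)
        cov = np.zeros(L)
        for a, b in zip(p1, p2):
            cov[a : min(b + rl, L)] += 1
        expected = [cov[i : i + 5000].mean() for i in range(0, L, 5000)]
        np.testing.assert_allclose(rd.values, expected)


class TestRDCorrection:
    def _features(self, n, gc=None, mapp=None, eff=None, bin_size=5000):
        return BinFeatureTrack(
            bin_size,
            np.full(n, 0.45) if gc is None else gc,
            np.ones(n) if mapp is None else mapp,
            np.full(n, 1000.0) if eff is None else eff,
        )

    def test_constant_features_preserve_relative_signal(self):
        values = np.array([10.0, 20.0, 30.0, 40.0] * 50)
        rd = RDProfile("c", 5000, values)
        out = correct_rd_signal(rd, self._features(len(values)))
        ratio = out.values / values
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_known_gc_bias_flattened(self):
        rng = np.random.default_rng(6)
        n = 400
        gc = rng.uniform(0.3, 0.6, n)
        base = 50.0
        values = base * (gc / 0.45) ** 1.5  # pure multiplicative GC effect
        rd = RDProfile("c", 5000, values)
        out = correct_rd_signal(rd, self._features(n, gc=gc))
        cv = out.values.std() / out.values.mean()
        assert cv < 0.05

    def test_zero_mappability_masked(self):
        n = 50
        mapp = np.ones(n)
        mapp[7] = 0.0
        rd = RDProfile("c", 5000, np.full(n, 10.0))
        out = correct_rd_signal(rd, self._features(n, mapp=mapp))
        assert out.mask[7]

    def test_idempotent_on_flat_profile(self):
        n = 300
        rd = RDProfile("c", 5000, np.full(n, 25.0))
        out = correct_rd_signal(rd, self._features(n))
        np.testing.assert_allclose(out.values, 25.0, rtol=0.01)


class TestBaselineModes:
    """Midpoint and exact-cut counting exist only as comparison baselines."""

    def _data(self, toy_rmap):
        pairs = make_pairs(
            [("chrT", p, "+", True, "chrT", 0, "+", False) for p in (10, 20, 1100, 2600)]
        )
        return pairs, pd.Series(["single_sided"] * 4)

    def test_exact_cut_places_reads_at_their_coordinate(self, toy_rmap):
        pairs, classes = self._data(toy_rmap)
        rd = rd_baseline(pairs, classes, toy_rmap, bin_size=1000, mode="exact_cut")
        np.testing.assert_allclose(rd.values * 1000, [2, 1, 1, 0])

    def test_midpoint_places_reads_at_fragment_midpoints(self, toy_rmap):
        pairs, classes = self._data(toy_rmap)
        rd = rd_baseline(pairs, classes, toy_rmap, bin_size=1000, mode="midpoint")
        # fragment midpoints: 500, 1750, 3250
        np.testing.assert_allclose(rd.values * 1000, [2, 1, 0, 1])

    def test_conservation(self, toy_rmap):
        pairs, classes = self._data(toy_rmap)
        for mode in ("midpoint", "exact_cut"):
            rd = rd_baseline(pairs, classes, toy_rmap, bin_size=1000, mode=mode)
            assert rd.values.sum() * 1000 == pytest.approx(4)

    def test_unknown_mode_rejected(self, toy_rmap):
        pairs, classes = self._data(toy_rmap)
        with pytest.raises(ValueError, match="mode"):
            rd_baseline(pairs, classes, toy_rmap, mode="whole_read")


def test_all_reads_vs_valid_only_rank_correlated(planted_genome):
    """Entire-fragment RD from all reads vs valid pairs only should agree in rank."""
    from scipy.stats import spearmanr

    from aneuhic.reads import classify_read_pairs
    from aneuhic.restriction import digest_genome
    from aneuhic.simulate import simulate_read_pairs

    seq, _ = planted_genome
    rmap = digest_genome(seq, "AAGCTT", 1)
    props = {
        "valid_pair": 0.5,
        "dangling_end": 0.3,
        "extra_dangling_end": 0.1,
        "self_circle": 0.05,
        "single_sided": 0.05,
    }
    pairs, _ = simulate_read_pairs(rmap, props, 8000, mml=500, read_length=50, seed=9)
    classes = classify_read_pairs(pairs, rmap, 500, 50)
    wins = build_fragment_end_windows(rmap, 500)
    rd_all = rd_from_fragment_counts(
        fragment_counts(count_window_reads(pairs, classes, wins, True), wins, rmap.n_fragments),
        rmap,
        5000,
    )
    rd_valid = rd_from_fragment_counts(
        fragment_counts(count_window_reads(pairs, classes, wins, False), wins, rmap.n_fragments),
        rmap,
        5000,
    )
    rho, _ = spearmanr(rd_all.values, rd_valid.values)
    assert rho > 0.5
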