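import numpy as np
import pytest
from sklearn.base import clone

from aneuhic.cnv import (
    CopyNumberCaller,
    FocalAlteration,
    Segment,
    detect_focal_alterations,
    fit_copy_number_distribution,
    merge_cnv_track,
    segment_large_events,
    to_copy_number,
)
from aneuhic.readdepth import RDProfile


def _profile(values, bin_size=5000):
    return RDProfile("chrT", bin_size, np.asarray(values, dtype=float))


def _simulated_rd(states_per_bin, unit=40.0, sigma_copies=0.2, seed=0):
    rng = np.random.default_rng(seed)
    states = np.asarray(states_per_bin, dtype=float)
    rd = unit * states + rng.normal(0, sigma_copies * unit, size=len(states))
    return _profile(np.clip(rd, 0.01, None))


class TestDistributionFit:
    def test_unimodal_anchors_dominant_peak_at_cn2(self):
        rng = np.random.default_rng(1)
        fit = fit_copy_number_distribution(_profile(np.abs(rng.normal(80, 5, 800))))
        assert fit.reference_rd == pytest.approx(80, rel=0.05)

    def test_bimodal_hint_selects_low_ploidy_grid(self):
        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(100, 5, 600), rng.normal(50, 5, 400)]
        fit = fit_copy_number_distribution(_profile(np.abs(vals)), ploidy_hint=2)
        assert fit.reference_rd == pytest.approx(100, rel=0.05)
        assert sorted(fit.peak_states.tolist()) == [1, 2]

    def test_three_peaks_integer_grid(self):
        rng = np.random.default_rng(3)
        vals = np.r_[
            rng.normal(50, 4, 400), rng.normal(100, 4, 400), rng.normal(150, 4, 400)
        ]
        fit = fit_copy_number_distribution(_profile(np.abs(vals)))
        assert fit.unit_spacing == pytest.approx(50, rel=0.05)
        assert sorted(fit.peak_states.tolist()) == [1, 2, 3]

    def test_hypotetraploid_hint(self):
        rng = np.random.default_rng(4)
        # mostly CN4 genome with a CN2 minority: modes at 2u and 4u
        vals = np.r_[rng.normal(50, 5, 200), rng.normal(100, 5, 800)]
        fit = fit_copy_number_distribution(_profile(np.abs(vals)), ploidy_hint=4)
        assert fit.reference_rd == pytest.approx(50, rel=0.05)

    def test_peaks_land_near_integer_grid(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(60, 5, 500), rng.normal(120, 5, 500)]
        fit = fit_copy_number_distribution(_profile(np.abs(vals)))
        assert np.all(np.abs(fit.peak_locations / fit.unit_spacing - fit.peak_states) < 0.25)

    def test_needs_enough_bins(self):
        with pytest.raises(ValueError, match="500"):
            fit_copy_number_distribution(_profile(np.full(100, 50.0)))


class TestToCopyNumber:
    def test_linearity(self):
        rng = np.random.default_rng(1)
        rd = _profile(np.abs(rng.normal(80, 5, 800)))
        fit = fit_copy_number_distribution(rd)
        probe = _profile([fit.reference_rd, 0.0, 1.5 * fit.reference_rd])
        np.testing.assert_allclose(to_copy_number(probe, fit), [2.0, 0.0, 3.0])


class TestSegmentation:
    def test_constant_single_neutral_segment(self):
        segs = segment_large_events(np.full(1000, 2.0), 5000, min_lcv_size=1e6)
        assert len(segs) == 1
        assert segs[0].state == 2 and segs[0].cls == "neutral"
        assert (segs[0].start, segs[0].end) == (0, 5_000_000)

    def test_planted_step_recovered(self):
        rng = np.random.default_rng(7)
        cn = np.r_[np.full(500, 2.0), np.full(500, 3.0)] + rng.normal(0, 0.2, 1000)
        segs = segment_large_events(cn, 5000, min_lcv_size=1e6)
        assert len(segs) == 2
        assert [s.state for s in segs] == [2, 3]
        assert abs(segs[0].end // 5000 - 500) <= 5

    def test_short_excursion_left_for_fa_stage(self):
        rng = np.random.default_rng(8)
        cn = np.full(1000, 2.0) + rng.normal(0, 0.1, 1000)
        cn[400:420] = 4.0  # 100 kb at 5-kb bins, below min_lcv_size
        segs = segment_large_events(cn, 5000, min_lcv_size=1e6)
        assert all(s.cls == "neutral" for s in segs)


class TestFocalAlterations:
    def test_flat_segment_empty(self):
        rng = np.random.default_rng(9)
        cn = 2.0 + rng.normal(0, 0.1, 500)
        segs = [Segment(0, 500 * 5000, 2.0, 2)]
        assert detect_focal_alterations(cn, segs, 5000) == []

    def test_planted_amplification_recovered(self):
        rng = np.random.default_rng(10)
        cn = 2.0 + rng.normal(0, 0.1, 500)
        cn[100:130] = 5.0
        segs = [Segment(0, 500 * 5000, 2.0, 2)]
        fas = detect_focal_alterations(cn, segs, 5000)
        assert len(fas) == 1
        fa = fas[0]
        assert fa.kind == "amplification"
        assert fa.start <= 100 * 5000 < 130 * 5000 <= fa.end + 5000
        assert fa.cn == pytest.approx(5.0, abs=0.2)

    def test_short_spike_rejected(self):
        rng = np.random.default_rng(11)
        cn = 2.0 + rng.normal(0, 0.1, 500)
        cn[100:102] = 6.0  # 2 bins < min_fa_size / bin_size = 3
        segs = [Segment(0, 500 * 5000, 2.0, 2)]
        assert detect_focal_alterations(cn, segs, 5000, min_fa_size=15e3) == []


class TestMergeTrack:
    def test_no_fas_equals_states(self):
        segs = [Segment(0, 50_000, 2.1, 2), Segment(50_000, 100_000, 3.2, 3)]
        track = merge_cnv_track(segs, [], 5000, 20)
        np.testing.assert_array_equal(track.values, [2] * 10 + [3] * 10)

    def test_fa_overrides_parent(self):
        segs = [Segment(0, 100_000, 2.0, 2)]
        fas = [FocalAlteration(25_000, 50_000, 5.0, 2)]
        track = merge_cnv_track(segs, fas, 5000, 20)
        assert set(track.values[5:10]) == {5.0}
        assert set(np.delete(track.values, np.s_[5:10])) == {2.0}

    def test_homozygous_deletion_floored(self):
        segs = [Segment(0, 100_000, 2.0, 2)]
        fas = [FocalAlteration(25_000, 50_000, 0.0, 2)]
        track = merge_cnv_track(segs, fas, 5000, 20)
        assert set(track.values[5:10]) == {0.5}

    def test_overlapping_fas_rejected(self):
        segs = [Segment(0, 100_000, 2.0, 2)]
        fas = [
            FocalAlteration(25_000, 50_000, 5.0, 2),
            FocalAlteration(40_000, 60_000, 4.0, 2),
        ]
        with pytest.raises(ValueError, match="overlap"):
            merge_cnv_track(segs, fas, 5000, 20)


class TestCallerEstimator:
    def test_sklearn_protocol(self):
        caller = CopyNumberCaller(ploidy_hint=4, min_lcv_size=5e5)
        params = caller.get_params()
        assert params["ploidy_hint"] == 4
        cloned = clone(caller)
        assert cloned.get_params() == params

    def test_fit_recovers_planted_profile(self):
        states = np.r_[np.full(400, 2), np.full(300, 3), np.full(300, 1)]
        rd = _simulated_rd(states, unit=40.0, seed=12)
        caller = CopyNumberCaller(min_lcv_size=5e5).fit(rd)
        assert caller.distribution_fit_.reference_rd == pytest.approx(80, rel=0.05)
        assert [s.state for s in caller.segments_] == [2, 3, 1]
        assert len(caller.lcvs_) == 2
        assert len(caller.cnv_track_) == len(rd)

    def test_track_constant_inside_fa_free_segment(self):
        states = np.r_[np.full(500, 2), np.full(500, 4)]
        rd = _simulated_rd(states, seed=13)
        caller = CopyNumberCaller(min_lcv_size=5e5).fit(rd)
        for seg in caller.segments_:
            a, b = seg.start // 5000, seg.end // 5000
            fa_bins = set()
            for fa in caller.focal_alterations_:
                fa_bins.update(range(fa.start // 5000, fa.end // 5000))
            seg_bins = [i for i in range(a, b) if i not in fa_bins]
            assert len(set(caller.cnv_track_.values[seg_bins])) == 1

    def test_normal_karyotype_nearly_lcv_free(self):
        for seed in range(5):
            rd = _simulated_rd(np.full(800, 2), sigma_copies=0.15, seed=seed)
            caller = CopyNumberCaller().fit(rd)
            assert len(caller.lcvs_) <= 3


def backbone_profile(seed, n_bins=1200, backbone=2, alt_states=(1, 3), min_bins=150):
    """Aneuploid truth with a dominant `backbone` state: [b, a1, b, a2, b].

    The backbone is kept at >= 2/3 of the genome so it is unambiguously the
    modal ploidy (the premise of the ploidy hint).
    """
    rng = np.random.default_rng(seed)

    def draw():
        return np.sort(rng.choice(np.arange(min_bins, n_bins - min_bins), 4, replace=False))

    cuts = draw()
    while (
        np.any(np.diff(cuts) < min_bins)
        or cuts[0] + (cuts[2] - cuts[1]) + (n_bins - cuts[3]) < 2 * n_bins // 3
    ):
        cuts = draw()
    alts = rng.choice(alt_states, size=2)
    states = [backbone, int(alts[0]), backbone, int(alts[1]), backbone]
    bounds = [0, *cuts.tolist(), n_bins]
    values = np.empty(n_bins)
    segs = []
    for (a, b), s in zip(zip(bounds[:-1], bounds[1:]), states):
        values[a:b] = s
        segs.append((a, b, s))
    return values, _merge_equal_states(segs)


class TestParameterRecovery:
    def test_reference_breakpoints_states_over_seeds(self):
        for seed in range(10):
            truth_values, truth_merged = backbone_profile(seed)
            rd = _simulated_rd(truth_values, unit=40.0, seed=100 + seed)
            caller = CopyNumberCaller(min_lcv_size=5e5).fit(rd)
            assert caller.distribution_fit_.reference_rd == pytest.approx(80.0, rel=0.05)
            called = [(s.start // 5000, s.end // 5000, s.state) for s in caller.segments_]
            assert len(called) == len(truth_merged)
            for (ca, cb, cs), (ta, tb, ts) in zip(called, truth_merged):
                assert cs == ts
                assert abs(ca - ta) <= 5 and abs(cb - tb) <= 5

    def test_hypotetraploid_recovery(self):
        for seed in range(5):
            truth_values, truth_merged = backbone_profile(
                seed, backbone=4, alt_states=(2, 3, 6)
            )
            rd = _simulated_rd(truth_values, unit=40.0, seed=200 + seed)
            caller = CopyNumberCaller(ploidy_hint=4, min_lcv_size=5e5).fit(rd)
            assert caller.distribution_fit_.reference_rd == pytest.approx(80.0, rel=0.05)
            called = [(s.start // 5000, s.end // 5000, s.state) for s in caller.segments_]
            assert [c[2] for c in called] == [t[2] for t in truth_merged]


def _merge_equal_states(segs):
    out = []
    for a, b, s in segs:
        if out and out[-1][2] == s:
            out[-1] = (out[-1][0], b, s)
        else:
            out.append((a, b, s))
    return out
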