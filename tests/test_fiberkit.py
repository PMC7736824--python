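"""Combing measurements: track grammar, unit conversion and recovery of
generator parameters."""

from __future__ import annotations

import numpy as np
import pytest

from replidyn import fiberkit
from replidyn.fiberkit import CLDU, IDU
from replidyn.synthgen import FiberSimConfig, simulate_fibers


class TestClassifyTracks:
    def test_single_progressing_fork(self, fiber_factory):
        f = fiber_factory([(IDU, 10, 12), (CLDU, 12, 15)])
        forks = fiberkit.classify_tracks([f])
        assert len(forks) == 1
        fk = forks[0]
        assert fk.valid and fk.direction == "right"
        assert fk.cldu_length_um == pytest.approx(3.0)

    def test_bidirectional_origin(self, fiber_factory):
        f = fiber_factory(
            [(CLDU, 10, 13), (IDU, 13, 15), (IDU, 15, 17), (CLDU, 17, 20)]
        )
        forks = fiberkit.classify_tracks([f])
        assert len(forks) == 2
        assert forks[0].origin_id == forks[1].origin_id
        assert forks[0].origin_pos_um == pytest.approx(15.0)
        origins = fiberkit.call_origins(forks)
        assert len(origins) == 1 and origins[0].kind == "bidirectional"

    def test_merged_idu_origin(self, fiber_factory):
        # single IdU segment spanning both forks still reads as one origin
        f = fiber_factory([(CLDU, 10, 13), (IDU, 13, 17), (CLDU, 17, 20)])
        origins = fiberkit.call_origins(fiberkit.classify_tracks([f]))
        assert len(origins) == 1 and origins[0].kind == "bidirectional"
        assert origins[0].position_um == pytest.approx(15.0)

    def test_track_at_fiber_end_is_excluded(self, fiber_factory):
        # no ssDNA downstream of the CldU track: not a measurable fork
        f = fiber_factory([(IDU, 95, 97), (CLDU, 97, 100)], extent=(0, 100))
        forks = fiberkit.classify_tracks([f])
        assert len(forks) == 1 and not forks[0].valid
        assert forks[0].invalid_reason == "no flanking ssDNA"

    def test_leftward_fork_direction(self, fiber_factory):
        f = fiber_factory([(CLDU, 10, 13), (IDU, 13, 15)])
        forks = fiberkit.classify_tracks([f])
        assert forks[0].direction == "left"
        assert forks[0].unidirectional

    def test_lone_fork_near_other_track_is_ambiguous(self, fiber_factory):
        f = fiber_factory(
            [(IDU, 10, 12), (CLDU, 12, 15), (IDU, 18, 20), (CLDU, 20, 23)]
        )
        origins = fiberkit.call_origins(fiberkit.classify_tracks([f]))
        # the second fork's IdU edge is 3 μm from the first CldU: ambiguous
        kinds = sorted(o.kind for o in origins)
        assert kinds == ["ambiguous", "unidirectional"]

    def test_overlapping_segments_rejected(self, fiber_factory):
        with pytest.raises(ValueError, match="overlap"):
            fiber_factory([(IDU, 10, 14), (CLDU, 12, 15)])


class TestForkSpeed:
    def test_definition(self, fiber_factory):
        f = fiber_factory([(IDU, 10, 20), (CLDU, 20, 32.525)])
        fk = fiberkit.classify_tracks([f])[0]
        assert fiberkit.fork_speed(fk, 15.0, 2.0) == pytest.approx(1.67)

    def test_invalid_fork_raises(self, fiber_factory):
        f = fiber_factory([(IDU, 95, 97), (CLDU, 97, 100)], extent=(0, 100))
        fk = fiberkit.classify_tracks([f])[0]
        with pytest.raises(ValueError):
            fiberkit.fork_speed(fk, 15.0)

    def test_conversion_consistency(self, sparse_fiber_run):
        # halving the stretching factor halves every kb-valued output
        _, fibers, _ = sparse_fiber_run
        forks = fiberkit.classify_tracks(fibers)
        origins = fiberkit.call_origins(forks)
        s2 = fiberkit.summarize_combing(forks, origins, 15.0, 2.0)
        s1 = fiberkit.summarize_combing(forks, origins, 15.0, 1.0)
        assert s1.rfs_mean == pytest.approx(s2.rfs_mean / 2)
        assert s1.iod_mean == pytest.approx(s2.iod_mean / 2)


class TestInterOriginDistances:
    def test_two_origins(self, fiber_factory):
        segs = [
            (CLDU, 8, 9), (IDU, 9, 10), (IDU, 10, 11), (CLDU, 11, 12),
            (CLDU, 53, 54), (IDU, 54, 55), (IDU, 55, 56), (CLDU, 56, 57),
        ]
        origins = fiberkit.call_origins(fiberkit.classify_tracks([fiber_factory(segs)]))
        dists = fiberkit.inter_origin_distances(origins, 2.0)
        assert dists == pytest.approx([90.0])

    def test_single_origin_fibers_give_empty_list(self, fiber_factory):
        f = fiber_factory([(CLDU, 10, 11), (IDU, 11, 12), (IDU, 12, 13), (CLDU, 13, 14)])
        origins = fiberkit.call_origins(fiberkit.classify_tracks([f]))
        with pytest.warns(UserWarning, match="IOD"):
            assert fiberkit.inter_origin_distances(origins) == []


class TestAsymmetry:
    def _origin(self, fiber_factory, left_len, right_len):
        segs = [
            (CLDU, 20 - 2 - left_len, 20 - 2), (IDU, 18, 20),
            (IDU, 20, 22), (CLDU, 22, 22 + right_len),
        ]
        return fiberkit.call_origins(
            fiberkit.classify_tracks([fiber_factory(segs)])
        )

    def test_ratio_two(self, fiber_factory):
        ratios, excluded = fiberkit.fork_asymmetry(self._origin(fiber_factory, 3, 6))
        assert ratios == pytest.approx([2.0]) and excluded == 0

    def test_symmetric_ratio_one(self, fiber_factory):
        ratios, _ = fiberkit.fork_asymmetry(self._origin(fiber_factory, 4, 4))
        assert ratios == pytest.approx([1.0])

    def test_thirty_five_percent_threshold(self, fiber_factory):
        ratios, _ = fiberkit.fork_asymmetry(self._origin(fiber_factory, 4, 5.4))
        assert ratios == pytest.approx([1.35])


class TestUnidirectionalFraction:
    def test_structure_counting(self):
        origins = [
            fiberkit.OriginCall("f", f"o{i}", 0.0, "unidirectional") for i in range(2)
        ] + [
            fiberkit.OriginCall("f", f"b{i}", 0.0, "bidirectional") for i in range(14)
        ]
        assert fiberkit.unidirectional_fraction(origins) == pytest.approx(12.5)

    def test_no_unidirectional(self):
        origins = [fiberkit.OriginCall("f", "b", 0.0, "bidirectional")]
        assert fiberkit.unidirectional_fraction(origins) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fiberkit.unidirectional_fraction([])


class TestSummaries:
    def test_single_fork_sem_absent(self, fiber_factory):
        f = fiber_factory([(IDU, 10, 12), (CLDU, 12, 15)])
        forks = fiberkit.classify_tracks([f])
        s = fiberkit.summarize_combing(forks, fiberkit.call_origins(forks), 15.0)
        assert s.n_forks == 1 and s.rfs_sem is None

    def test_deterministic_sim_gives_zero_sem(self):
        cfg = FiberSimConfig(
            n_fibers=30, speed_sd=0.0, iod_mean_kb=500.0,
            fiber_len_mean_um=1000.0, fiber_len_sd=0.0, seed=6,
        )
        fibers, _ = simulate_fibers(cfg)
        forks = fiberkit.classify_tracks(fibers)
        s = fiberkit.summarize_combing(forks, fiberkit.call_origins(forks), 15.0)
        assert s.rfs_sem == pytest.approx(0.0, abs=1e-9)
        assert s.rfs_mean == pytest.approx(1.67)


class TestRecovery:
    def test_speed_recovery_within_three_sem(self, sparse_fiber_run):
        cfg, fibers, _ = sparse_fiber_run
        forks = [f for f in fiberkit.classify_tracks(fibers) if f.valid]
        assert len(forks) >= 500
        speeds = [fiberkit.fork_speed(f, cfg.pulse2_min, cfg.stretch_kb_per_um) for f in forks]
        sem = np.std(speeds, ddof=1) / np.sqrt(len(speeds))
        assert abs(np.mean(speeds) - cfg.speed_mean_kb_min) < 3 * sem

    def test_classification_matches_ground_truth_exactly(self, sparse_fiber_run):
        # clean regime: precision and recall of fork calls are both 1
        _, fibers, gt = sparse_fiber_run
        forks = fiberkit.classify_tracks(fibers)
        valid = [f for f in forks if f.valid]
        # a measurable fork needs flanking ssDNA around its whole structure:
        # exclude origins where either sibling merged with a neighbor
        origin_clean = ~gt.groupby("origin_id").truncated.transform("any")
        expected = gt[(~gt.stalled) & origin_clean]
        assert len(valid) == len(expected)
        called = {(f.fiber_id, round(f.origin_pos_um, 4), f.direction) for f in valid}
        truth = {
            (r.fiber_id, round(r.origin_pos_um, 4), r.direction)
            for r in expected.itertuples()
        }
        assert called == truth

    def test_unidirectional_fraction_matches_brute_force(self):
        cfg = FiberSimConfig(
            n_fibers=150, p_fork_stall=0.0684, iod_mean_kb=400.0,
            iod_sd_kb=16.0, fiber_len_mean_um=2000.0, fiber_len_sd=100.0, seed=17,
        )
        fibers, gt = simulate_fibers(cfg)
        origins = fiberkit.call_origins(fiberkit.classify_tracks(fibers))
        measured = fiberkit.unidirectional_fraction(origins)
        per_origin = gt.groupby("origin_id").n_sibling_tracks.first()
        visible = per_origin[per_origin >= 1]
        brute = 100.0 * (visible == 1).sum() / len(visible)
        assert measured == pytest.approx(brute, abs=0.5)
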