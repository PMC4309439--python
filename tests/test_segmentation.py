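"""Domain calling: seeding, extension, merging, intersection, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vlincscan as v
from vlincscan.segmentation import _Extender
from vlincscan.types import ACTIVATED, REPRESSED

from conftest import extend_oracle, make_track, refine_oracle, seed_oracle


def _seed_tuples(domains):
    return sorted((d.first_probe, d.last_probe, d.direction) for d in domains)


class TestSeedDetection:
    def test_flat_track_yields_nothing(self):
        assert v.detect_seed_domains(make_track(np.zeros(100))) == []

    def test_block_example(self):
        # probes 10-29 at +0.5: window starts 8..20 have >= 10 in-block
        # probes, so the seed covers probes 8..31
        vals = np.zeros(40)
        vals[10:30] = 0.5
        seeds = v.detect_seed_domains(make_track(vals))
        assert _seed_tuples(seeds) == [(8, 31, ACTIVATED)]
        assert seeds[0].start == 8 * 25 and seeds[0].end == 31 * 25 + 25

    def test_sign_symmetry_of_block(self):
        vals = np.zeros(40)
        vals[10:30] = 0.5
        neg = v.detect_seed_domains(make_track(-vals))
        assert _seed_tuples(neg) == [(8, 31, REPRESSED)]

    def test_track_shorter_than_window(self):
        assert v.detect_seed_domains(make_track([1.0] * 5)) == []

    def test_threshold_is_strict(self):
        # values exactly at 0.35 never qualify
        seeds = v.detect_seed_domains(make_track(np.full(50, 0.35)))
        assert seeds == []
        assert len(v.detect_seed_domains(make_track(np.full(50, 0.3501)))) == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        vals = rng.normal(0, 0.45, 1000)
        # sprinkle a few shifted blocks so seeds of both directions occur
        for _ in range(rng.integers(0, 4)):
            s = rng.integers(0, 960)
            vals[s : s + rng.integers(12, 40)] += rng.choice([-0.6, 0.6])
        track = make_track(vals)
        assert _seed_tuples(v.detect_seed_domains(track)) == seed_oracle(vals)

    def test_raising_threshold_shrinks_coverage(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 0.6, 2000)
        low = v.detect_seed_domains(make_track(vals), v.ParameterSet(seed_threshold=0.35))
        high = v.detect_seed_domains(make_track(vals), v.ParameterSet(seed_threshold=0.5))
        for direction in (ACTIVATED, REPRESSED):
            lo_cover = set()
            for d in low:
                if d.direction == direction:
                    lo_cover.update(range(d.first_probe, d.last_probe + 1))
            hi_cover = set()
            for d in high:
                if d.direction == direction:
                    hi_cover.update(range(d.first_probe, d.last_probe + 1))
            assert hi_cover <= lo_cover
            # every high-threshold seed is nested in one low-threshold seed
            for d in high:
                if d.direction == direction:
                    assert any(
                        l.first_probe <= d.first_probe and d.last_probe <= l.last_probe
                        for l in low
                        if l.direction == direction
                    )


class TestExtension:
    def test_hostile_flanks_leave_domain_unchanged(self):
        vals = np.concatenate([np.full(30, -1.0), np.full(20, 0.5), np.full(30, -1.0)])
        track = make_track(vals)
        (seed,) = [d for d in v.detect_seed_domains(track) if d.direction == ACTIVATED]
        assert v.extend_domain(seed, track) == seed

    def test_gradual_shoulder_matches_step_oracle(self):
        vals = np.concatenate([np.full(20, 0.5), np.full(200, 0.2), np.full(100, -1.0)])
        track = make_track(vals)
        seeds = [d for d in v.detect_seed_domains(track) if d.direction == ACTIVATED]
        ext = v.extend_domain(seeds[0], track)
        oracle = extend_oracle(seeds[0].first_probe, seeds[0].last_probe, ACTIVATED, vals)
        assert (ext.first_probe, ext.last_probe) == oracle
        assert ext.last_probe > seeds[0].last_probe  # it did advance

    def test_domain_at_track_edge(self):
        vals = np.concatenate([np.zeros(50), np.full(20, 0.6)])
        track = make_track(vals)
        (seed,) = v.detect_seed_domains(track)
        ext = v.extend_domain(seed, track)
        assert ext.last_probe == len(vals) - 1

    def test_outside_track_rejected(self):
        track = make_track(np.zeros(10))
        dom = v.TranscriptDomain.from_probes(
            make_track(np.full(30, 0.5)).probe_map, 5, 20, ACTIVATED, np.full(30, 0.5)
        )
        with pytest.raises(v.ValidationError):
            v.extend_domain(dom, track)

    @pytest.mark.parametrize("seed", range(10))
    def test_vectorized_extender_equals_walk(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 0.8, 600)
        track = make_track(vals)
        extender = _Extender(track, v.ParameterSet())
        for s in v.detect_seed_domains(track):
            try:
                walk = v.extend_domain(s, track)
                walk_key = (walk.first_probe, walk.last_probe)
            except v.ValidationError:
                walk_key = None
            fast = extender.extend(s)
            fast_key = None if fast is None else (fast.first_probe, fast.last_probe)
            assert walk_key == fast_key


class TestMerge:
    def _doms(self, track, spans_dirs):
        return [
            v.TranscriptDomain.from_probes(track.probe_map, a, b, d, track.values)
            for a, b, d in spans_dirs
        ]

    def test_disjoint_unchanged(self):
        track = make_track(np.full(100, 0.5))
        doms = self._doms(track, [(0, 10, ACTIVATED), (50, 60, ACTIVATED)])
        assert _seed_tuples(v.merge_domains(doms, track)) == _seed_tuples(doms)

    def test_overlapping_same_direction_merged(self):
        track = make_track(np.full(100, 0.5))
        doms = self._doms(track, [(0, 30, ACTIVATED), (20, 60, ACTIVATED)])
        merged = v.merge_domains(doms, track)
        assert _seed_tuples(merged) == [(0, 60, ACTIVATED)]
        assert merged[0].mean_ratio == pytest.approx(0.5)

    def test_touching_runs_merged(self):
        track = make_track(np.full(100, 0.5))
        doms = self._doms(track, [(0, 10, ACTIVATED), (11, 20, ACTIVATED)])
        assert _seed_tuples(v.merge_domains(doms, track)) == [(0, 20, ACTIVATED)]

    def test_opposite_directions_kept_apart(self):
        vals = np.concatenate([np.full(50, 0.5), np.full(50, -0.5)])
        track = make_track(vals)
        doms = self._doms(track, [(0, 49, ACTIVATED), (50, 99, REPRESSED)])
        assert len(v.merge_domains(doms, track)) == 2

    def test_mixed_chrom_rejected(self):
        t1 = make_track(np.full(20, 0.5), chrom="chr1")
        t2 = make_track(np.full(20, 0.5), chrom="chr2")
        doms = self._doms(t1, [(0, 5, ACTIVATED)]) + self._doms(t2, [(0, 5, ACTIVATED)])
        with pytest.raises(v.ValidationError):
            v.merge_domains(doms, t1)

    @given(st.lists(st.tuples(st.integers(0, 80), st.integers(1, 19)), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_order_independent(self, spans, rnd):
        track = make_track(np.full(100, 0.5))
        doms = self._doms(track, [(a, a + l, ACTIVATED) for a, l in spans])
        once = v.merge_domains(doms, track)
        assert _seed_tuples(v.merge_domains(once, track)) == _seed_tuples(once)
        shuffled = list(doms)
        rnd.shuffle(shuffled)
        assert _seed_tuples(v.merge_domains(shuffled, track)) == _seed_tuples(once)


class TestVirtualTrack:
    def test_identical_replicates(self):
        t = make_track(np.array([0.1, 0.2, 0.3]))
        virt = v.make_virtual_track([t, t])
        assert np.array_equal(virt.values, t.values)

    def test_opposite_values_cancel(self):
        t1 = make_track(np.array([0.4, -0.2]))
        t2 = make_track(np.array([-0.4, 0.2]))
        assert np.array_equal(v.make_virtual_track([t1, t2]).values, [0.0, 0.0])

    def test_plain_average(self):
        t1 = make_track(np.array([0.2]))
        t2 = make_track(np.array([0.6]))
        assert v.make_virtual_track([t1, t2]).values[0] == pytest.approx(0.4)

    def test_mismatched_maps_rejected(self):
        t1 = make_track(np.zeros(5))
        t2 = make_track(np.zeros(6))
        with pytest.raises(v.ValidationError):
            v.make_virtual_track([t1, t2])


class TestIntersectReplicates:
    def _dom(self, a, b, direction):
        track = make_track(np.full(200, 0.5 if direction == ACTIVATED else -0.5))
        return v.TranscriptDomain.from_probes(track.probe_map, a, b, direction, track.values)

    def test_identical_lists_unchanged(self):
        doms = [self._dom(0, 10, ACTIVATED), self._dom(50, 80, REPRESSED)]
        assert v.intersect_replicates(doms, doms) == doms

    def test_singleton_eliminated(self):
        a = [self._dom(0, 10, ACTIVATED)]
        assert v.intersect_replicates(a, []) == []
        assert v.intersect_replicates(a, [self._dom(100, 120, ACTIVATED)]) == []

    def test_direction_must_match(self):
        a = [self._dom(0, 10, ACTIVATED)]
        b = [self._dom(5, 15, REPRESSED)]
        assert v.intersect_replicates(a, b) == []

    def test_single_shared_probe_suffices_and_keeps_a_coords(self):
        a = [self._dom(0, 10, ACTIVATED)]
        b = [self._dom(10, 30, ACTIVATED)]
        assert v.intersect_replicates(a, b) == a


class TestRefineBoundaries:
    def test_uniform_track_expands_to_ends(self):
        track = make_track(np.full(200, 0.5))
        dom = v.TranscriptDomain.from_probes(track.probe_map, 90, 110, ACTIVATED, track.values)
        refined = v.refine_boundaries(dom, track)
        assert (refined.first_probe, refined.last_probe) == (0, 199)

    def test_zero_mean_rejected(self):
        track = make_track(np.zeros(100))
        dom = v.TranscriptDomain.from_probes(track.probe_map, 40, 60, ACTIVATED, track.values)
        with pytest.raises(v.ValidationError):
            v.refine_boundaries(dom, track)

    @pytest.mark.parametrize("direction,level", [(ACTIVATED, 0.5), (REPRESSED, -0.5)])
    def test_crisp_domain_matches_step_oracle(self, direction, level):
        vals = np.zeros(400)
        vals[100:300] = level
        track = make_track(vals)
        dom = v.TranscriptDomain.from_probes(track.probe_map, 100, 299, direction, vals)
        refined = v.refine_boundaries(dom, track)
        oracle = refine_oracle(100, 299, direction, vals)
        assert (refined.first_probe, refined.last_probe) == oracle
        # and the result sits within a flank of the true edges
        assert abs(refined.first_probe - 100) <= 15
        assert abs(refined.last_probe - 299) <= 15

    @pytest.mark.parametrize("seed", range(8))
    def test_noisy_domains_match_step_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        vals = rng.normal(0, 0.2, 500)
        vals[150:350] += 0.6
        track = make_track(vals)
        dom = v.TranscriptDomain.from_probes(track.probe_map, 152, 347, ACTIVATED, vals)
        refined = v.refine_boundaries(dom, track)
        oracle = refine_oracle(152, 347, ACTIVATED, vals)
        assert (refined.first_probe, refined.last_probe) == oracle


class TestRunSegmentation:
    def test_all_zero_tracks(self):
        tracks = [make_track(np.zeros(500)) for _ in range(2)]
        assert v.run_segmentation(tracks) == []

    def test_single_replicate_rejected(self):
        with pytest.raises(v.ValidationError):
            v.run_segmentation([make_track(np.zeros(100))])

    def test_noiseless_planted_domain_recovered(self):
        pm = v.generate_probe_map("chr1", "+", 200_000, 25)
        truth = v.TruthSet(
            domains=(v.TruthDomain("chr1", "+", 50_000, 60_000, ACTIVATED, 0.6),),
            noise_sd=0.0,
            n_replicates=2,
        )
        tracks = v.simulate_ratio_tracks(pm, truth, seed=0)
        (dom,) = v.run_segmentation(tracks)
        assert dom.direction == ACTIVATED
        i0 = int(np.searchsorted(pm.positions, 50_000))
        i1 = int(np.searchsorted(pm.positions, 60_000)) - 1
        assert abs(dom.first_probe - i0) <= 15 and abs(dom.last_probe - i1) <= 15

    def test_domain_in_one_replicate_only_is_dropped(self):
        pm = v.generate_probe_map("chr1", "+", 100_000, 25)
        profile = np.zeros(pm.n_probes)
        profile[1000:1400] = 0.6
        t1 = v.RatioTrack(pm, profile)
        t2 = v.RatioTrack(pm, np.zeros(pm.n_probes))
        assert v.run_segmentation([t1, t2]) == []

    def test_sign_symmetry_end_to_end(self):
        rng = np.random.default_rng(42)
        pm = v.generate_probe_map("chr1", "+", 100_000, 25)
        profile = np.zeros(pm.n_probes)
        profile[500:900] = 0.6
        profile[2000:2600] = -0.7
        tracks = [v.RatioTrack(pm, profile + rng.normal(0, 0.2, pm.n_probes)) for _ in range(2)]
        flipped = [v.RatioTrack(pm, -t.values) for t in tracks]
        orig = v.run_segmentation(tracks)
        neg = v.run_segmentation(flipped)
        assert [(d.first_probe, d.last_probe) for d in orig] == [
            (d.first_probe, d.last_probe) for d in neg
        ]
        assert [d.direction for d in neg] == [
            REPRESSED if d.direction == ACTIVATED else ACTIVATED for d in orig
        ]

    def test_final_domains_well_formed(self):
        rng = np.random.default_rng(10)
        pm = v.generate_probe_map("chr1", "+", 250_000, 25)
        profile = np.zeros(pm.n_probes)
        for s in (500, 3000, 7000):
            profile[s : s + 400] = rng.choice([-0.6, 0.6])
        tracks = [v.RatioTrack(pm, profile + rng.normal(0, 0.25, pm.n_probes)) for _ in range(2)]
        for dom in v.run_segmentation(tracks):
            assert dom.n_probes >= 2
            assert abs(dom.mean_ratio) > 0
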