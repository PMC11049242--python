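import numpy as np
import pytest
from skimage import measure as skmeasure

from gliaquant import synthdata
from gliaquant.synthdata import CalciumTruth, LfpTruth, ShapeTruth


class TestShapeGeneration:
    def test_degenerate_amoeboid_is_single_ball(self):
        truth = ShapeTruth(soma_radius=6.0, n_processes=0, process_lengths=[])
        vol, realized = synthdata.gen_microglia(truth, seed=0)
        labels = skmeasure.label(vol.voxels > 0, connectivity=3)
        assert labels.max() == 1
        assert realized.n_processes == 0
        # voxelized ball volume close to 4/3 π r³
        assert vol.voxels.sum() == pytest.approx(4 / 3 * np.pi * 6**3, rel=0.1)

    def test_volume_is_single_connected_component(self, branched_cell):
        vol, _ = branched_cell
        labels = skmeasure.label(vol.voxels > 0, connectivity=3)
        assert labels.max() == 1

    def test_same_seed_voxel_identical(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=4, process_lengths=[20.0] * 4)
        v1, t1 = synthdata.gen_microglia(truth, seed=7)
        v2, t2 = synthdata.gen_microglia(truth, seed=7)
        assert np.array_equal(v1.voxels, v2.voxels)
        assert t1.process_lengths == t2.process_lengths

    def test_realized_lengths_match_requested_within_one_step(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=6, process_lengths=[18.0] * 6)
        _, realized = synthdata.gen_microglia(truth, seed=3)
        for req, real in zip(truth.process_lengths, realized.process_lengths):
            assert real == pytest.approx(req, abs=1.8)  # one voxel diagonal

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError):
            ShapeTruth(soma_radius=0.0, n_processes=0, process_lengths=[])
        with pytest.raises(ValueError):
            ShapeTruth(soma_radius=5.0, n_processes=2, process_lengths=[10.0])
        with pytest.raises(ValueError):
            ShapeTruth(soma_radius=5.0, n_processes=1, process_lengths=[-3.0])


class TestPopulation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synthdata.gen_population({"amoeboid": 0.5, "branched": 0.4}, 10)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            synthdata.gen_population({"amoeboid": 1.0}, 0)

    def test_pure_mix_yields_intended_truths(self):
        from gliaquant import classify

        cells = synthdata.gen_population({"branched": 1.0}, 5, seed=2)
        for _, truth in cells:
            m = synthdata.truth_morphology(truth)
            assert classify.classify_cell(m).label == "branched"

    def test_class_draw_reproducible(self):
        mix = {"amoeboid": 0.3, "transitional": 0.6, "branched": 0.1}
        a = synthdata.gen_population(mix, 20, seed=11)
        b = synthdata.gen_population(mix, 20, seed=11)
        assert [t.intended_class for _, t in a] == [t.intended_class for _, t in b]


class TestCalciumTrace:
    def test_flat_trace_without_noise_or_events(self):
        truth = CalciumTruth([], [], baseline=50.0)
        trace, _ = synthdata.gen_calcium_trace(100, truth, seed=0)
        assert np.allclose(trace.raw, 50.0)

    def test_noiseless_events_appear_as_local_maxima(self):
        truth = CalciumTruth([10, 30, 50, 70, 90], [0.1] * 5, baseline=100.0)
        trace, _ = synthdata.gen_calcium_trace(120, truth, seed=0)
        # each onset jumps by peak*baseline then decays
        for onset in truth.event_onsets:
            assert trace.raw[onset] > trace.raw[onset - 1]
            assert trace.raw[onset] == pytest.approx(
                trace.raw[onset - 1] + 0.1 * 100.0, rel=0.05
            )

    def test_bitwise_reproducible(self):
        truth = CalciumTruth([5], [0.08], noise_sigma=1.0)
        a, _ = synthdata.gen_calcium_trace(200, truth, seed=9)
        b, _ = synthdata.gen_calcium_trace(200, truth, seed=9)
        assert np.array_equal(a.raw, b.raw)

    def test_onsets_must_increase(self):
        with pytest.raises(ValueError):
            CalciumTruth([10, 10], [0.1, 0.1])


class TestLfp:
    def test_silent_trace_is_zero(self):
        rec, _ = synthdata.gen_lfp(1.0, 1e-3, LfpTruth([], [], []), seed=0)
        assert np.all(rec.samples == 0)

    def test_deflection_depth_equals_requested(self):
        truth = LfpTruth([0.4], [200.0], [-0.5])
        rec, _ = synthdata.gen_lfp(1.0, 1e-3, truth, seed=0)
        assert rec.samples.min() == pytest.approx(-0.5, abs=1e-9)

    def test_seeded_noise_reproducible(self):
        truth = LfpTruth([], [], [], noise_sigma_mv=0.1)
        a, _ = synthdata.gen_lfp(1.0, 1e-3, truth, seed=4)
        b, _ = synthdata.gen_lfp(1.0, 1e-3, truth, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError):
            LfpTruth([0.0, 0.1], [200.0, 200.0], [-0.5, -0.5])

    def test_duration_must_cover_events(self):
        truth = LfpTruth([5.0], [500.0], [-0.5])
        with pytest.raises(ValueError):
            synthdata.gen_lfp(2.0, 1e-3, truth, seed=0)


class TestTrajectory:
    def test_constant_speed_step_lengths(self):
        traj = synthdata.gen_trajectory([(60.0, 10.0)], dt_s=1.0, seed=0)
        steps = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm))
        assert steps.size == 60
        assert np.allclose(steps, 10.0)

    def test_zero_speed_freezes_position(self):
        traj = synthdata.gen_trajectory([(10.0, 0.0)], dt_s=1.0, seed=0)
        assert np.allclose(np.diff(traj.x_mm), 0)
        assert np.allclose(np.diff(traj.y_mm), 0)

    def test_total_path_length_is_sum_of_segment_products(self):
        segs = [(30.0, 2.0), (30.0, 6.0), (30.0, 10.0)]
        traj = synthdata.gen_trajectory(segs, dt_s=1.0, seed=5)
        total = np.hypot(np.diff(traj.x_mm), np.diff(traj.y_mm)).sum()
        assert total == pytest.approx(sum(d * v for d, v in segs), rel=1e-12)

    def test_empty_segments_error(self):
        with pytest.raises(ValueError):
            synthdata.gen_trajectory([], dt_s=1.0)
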