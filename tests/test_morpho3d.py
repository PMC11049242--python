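import numpy as np
import pytest

from gliaquant import morpho3d, synthdata
from gliaquant.synthdata import ShapeTruth
from gliaquant.volume import LabeledVolume


class TestSegmentation:
    def test_all_zero_volume_yields_no_cells(self):
        with pytest.warns(UserWarning):
            lab = morpho3d.segment_cells(np.zeros((10, 10, 10)))
        assert lab.cell_ids.size == 0

    def test_two_separated_cells_get_two_labels(self):
        vol = np.zeros((30, 30, 30))
        vol[3:9, 3:9, 3:9] = 100.0
        vol[20:26, 20:26, 20:26] = 100.0
        lab = morpho3d.segment_cells(vol)
        assert lab.cell_ids.size == 2

    def test_small_components_dropped(self):
        vol = np.zeros((20, 20, 20))
        vol[5:9, 5:9, 5:9] = 100.0  # 64 voxels
        lab40 = morpho3d.segment_cells(vol, min_voxels=50)
        assert lab40.cell_ids.size == 1
        lab100 = morpho3d.segment_cells(vol, min_voxels=100)
        assert lab100.cell_ids.size == 0


class TestSphericity:
    def test_ball_sphericity_near_one(self, ball_volume):
        m = morpho3d.measure_cell(ball_volume, 1)
        assert 0.97 <= m.sphericity <= 1.03
        assert m.volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.02)
        assert m.n_processes == 0

    def test_cube_sphericity_matches_closed_form(self, cube_volume):
        m = morpho3d.measure_cell(cube_volume, 1)
        expected = (np.pi / 6) ** (1 / 3)
        assert m.sphericity == pytest.approx(expected, rel=0.05)
        assert m.volume == pytest.approx(8000.0)

    def test_missing_cell_id_raises(self, ball_volume):
        with pytest.raises(KeyError):
            morpho3d.measure_cell(ball_volume, 99)


class TestSkeleton:
    def test_ball_has_no_processes(self, ball_volume):
        skel = morpho3d.skeletonize_cell(ball_volume.voxels > 0)
        np_, tl, mean, ri = morpho3d.process_stats(skel)
        assert (np_, tl, mean, ri) == (0, 0.0, 0.0, 0.0)

    def test_single_straight_tube_length_recovered(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=1, process_lengths=[30.0])
        vol, realized = synthdata.gen_microglia(truth, seed=0, jitter=0.0)
        skel = morpho3d.skeletonize_cell(vol.voxels > 0)
        np_, tl, _, ri = morpho3d.process_stats(skel)
        assert np_ == 1
        assert tl == pytest.approx(30.0, abs=2.5)
        assert ri == 1.0

    def test_y_shaped_process_counts_one_primary_two_terminals(self):
        # hand-built: straight primary along +z splitting into two at 12 µm
        prim = np.stack([np.linspace(5, 17, 13), np.full(13, 0.0), np.full(13, 0.0)], 1)
        b1 = prim[-1] + np.stack(
            [np.linspace(0, 8, 9), np.linspace(0, 6, 9), np.zeros(9)], 1
        )
        b2 = prim[-1] + np.stack(
            [np.linspace(0, 8, 9), -np.linspace(0, 6, 9), np.zeros(9)], 1
        )
        half = np.full(3, 35.0)
        mask = synthdata._rasterize([prim, b1, b2], 5.0, (1, 1, 1), half, 1.5)
        skel = morpho3d.skeletonize_cell(mask)
        np_, tl, _, ri = morpho3d.process_stats(skel)
        assert np_ == 1
        assert len(skel.terminal_nodes) == 2
        assert ri == 2.0

    def test_synthetic_cell_process_count(self, branched_cell):
        vol, realized = branched_cell
        m = morpho3d.measure_cell(vol, 1)
        assert abs(m.n_processes - realized.n_processes) <= 1
        assert m.ramification_index >= 1.0

    def test_four_unbranched_primaries_stats(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=4, process_lengths=[25.0] * 4)
        vol, realized = synthdata.gen_microglia(truth, seed=2, jitter=0.0)
        skel = morpho3d.skeletonize_cell(vol.voxels > 0)
        np_, tl, mean, ri = morpho3d.process_stats(skel)
        assert np_ == 4
        assert tl == pytest.approx(100.0, rel=0.1)
        assert mean == pytest.approx(tl / 4)
        assert ri == 1.0


class TestSholl:
    def test_radial_processes_cross_each_sphere_once(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=3, process_lengths=[30.0] * 3)
        vol, _ = synthdata.gen_microglia(truth, seed=1, jitter=0.0)
        skel = morpho3d.skeletonize_cell(vol.voxels > 0)
        prof = dict(morpho3d.sholl_profile(skel, r_step=5.0, r_max=50.0))
        for r in (10.0, 15.0, 20.0, 25.0, 30.0):
            assert prof[r] == 3
        assert prof[45.0] == 0
        assert prof[50.0] == 0

    def test_sholl_just_outside_soma_equals_np_for_unbranched(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=5, process_lengths=[20.0] * 5)
        vol, _ = synthdata.gen_microglia(truth, seed=4, jitter=0.0)
        skel = morpho3d.skeletonize_cell(vol.voxels > 0)
        prof = dict(morpho3d.sholl_profile(skel, r_step=5.0, r_max=20.0))
        assert prof[10.0] == 5

    def test_empty_skeleton_all_zero(self, ball_volume):
        skel = morpho3d.skeletonize_cell(ball_volume.voxels > 0)
        prof = morpho3d.sholl_profile(skel)
        assert all(n == 0 for _, n in prof)

    def test_rejects_nonpositive_step(self, ball_volume):
        skel = morpho3d.skeletonize_cell(ball_volume.voxels > 0)
        with pytest.raises(ValueError):
            morpho3d.sholl_profile(skel, r_step=0.0)


class TestScaleAndRotation:
    def test_scale_equivariance(self, branched_cell):
        vol, _ = branched_cell
        m1 = morpho3d.measure_cell(vol, 1)
        m2 = morpho3d.measure_cell(
            LabeledVolume(vol.voxels, (2.0, 2.0, 2.0)), 1, sholl_max=200.0
        )
        assert m2.volume == pytest.approx(8 * m1.volume, rel=1e-9)
        assert m2.surface_area == pytest.approx(4 * m1.surface_area, rel=0.02)
        assert m2.total_length == pytest.approx(2 * m1.total_length, rel=0.02)
        assert m2.sphericity == pytest.approx(m1.sphericity, rel=0.02)
        assert m2.n_processes == m1.n_processes

    def test_rotation_invariance(self, branched_cell):
        vol, _ = branched_cell
        m1 = morpho3d.measure_cell(vol, 1)
        rot = LabeledVolume(np.rot90(vol.voxels, axes=(0, 2)).copy(), vol.voxel_size)
        m2 = morpho3d.measure_cell(rot, 1)
        assert m2.volume == m1.volume
        assert m2.surface_area == pytest.approx(m1.surface_area, rel=1e-3)
        assert abs(m2.n_processes - m1.n_processes) <= 1

    def test_anisotropic_voxels_measured_in_physical_units(self):
        truth = ShapeTruth(soma_radius=5.0, n_processes=2, process_lengths=[20.0] * 2)
        vol_iso, _ = synthdata.gen_microglia(truth, seed=6, jitter=0.0)
        vol_aniso, _ = synthdata.gen_microglia(
            truth, voxel_size=(2.0, 1.0, 1.0), seed=6, jitter=0.0
        )
        m_iso = morpho3d.measure_cell(vol_iso, 1)
        m_aniso = morpho3d.measure_cell(vol_aniso, 1)
        # resampling staircase inflates skeleton arcs; topology and the
        # broad length scale must survive (see the methods note)
        assert m_aniso.n_processes == m_iso.n_processes
        assert m_aniso.total_length == pytest.approx(m_iso.total_length, rel=0.3)


class TestTables:
    def test_measure_all_and_sholl_long_format(self):
        vol = np.zeros((20, 20, 40))
        vol[5:15, 5:15, 3:13] = 100.0
        vol[5:15, 5:15, 25:35] = 100.0
        lab = morpho3d.segment_cells(vol)
        table = morpho3d.measure_all(lab)
        assert len(table) == 2
        assert {"cell_id", "sphericity", "n_processes", "total_length",
                "surface_area", "volume"} <= set(table.columns)
        sholl = morpho3d.sholl_long_table(lab, sholl_max=20.0)
        assert set(sholl["cell_id"]) == {1, 2}
        assert (sholl["intersections"] >= 0).all()


class TestCoexpression:
    def _three_cells(self):
        lab = np.zeros((10, 10, 30), np.int32)
        lab[3:7, 3:7, 2:8] = 1
        lab[3:7, 3:7, 12:18] = 2
        lab[3:7, 3:7, 22:28] = 3
        return LabeledVolume(lab)

    def test_zero_reporter_gives_zero_percent(self):
        cells = self._three_cells()
        assert morpho3d.coexpression_fraction(cells, np.zeros(cells.voxels.shape)) == 0.0

    def test_one_of_three_positive(self):
        cells = self._three_cells()
        rep = np.zeros(cells.voxels.shape)
        rep[cells.voxels == 2] = 100.0
        frac = morpho3d.coexpression_fraction(cells, rep)
        assert frac == pytest.approx(100 / 3, abs=0.1)

    def test_all_cells_high_is_hundred_under_fraction_rule(self):
        cells = self._three_cells()
        rep = np.where(cells.voxels > 0, 100.0, 0.0)
        frac = morpho3d.coexpression_fraction(cells, rep, rule="fraction", threshold=0.5)
        assert frac == 100.0

    def test_no_cells_raises(self):
        empty = LabeledVolume(np.zeros((5, 5, 5), np.int32))
        with pytest.raises(ValueError):
            morpho3d.coexpression_fraction(empty, np.zeros((5, 5, 5)))

    def test_shape_mismatch_raises(self):
        cells = self._three_cells()
        with pytest.raises(ValueError):
            morpho3d.coexpression_fraction(cells, np.zeros((2, 2, 2)))
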