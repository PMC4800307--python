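"""Phantom generator: analytic ground truth, optics, fusion schedules."""

import math

import numpy as np
import pytest

from nci3d import phantom as ph
from nci3d.restoration import PSFModel


def _bath_spec(objects, shape=(24, 60, 60), voxel=(0.1, 0.04, 0.04), **kw):
    kw.setdefault("poisson_gain", 0.0)
    kw.setdefault("gaussian_sd", 0.0)
    return ph.PhantomSpec(field_shape=shape, voxel_size=voxel, objects=objects, **kw)


class TestGroundTruth:
    @pytest.mark.parametrize("d", [0.5, 0.75, 1.0, 1.3])
    def test_sphere_volume_is_analytic(self, d):
        obj = ph.PlantedObject(id=0, shape_kind="sphere",
                               center=(1, 1, 1), diameter=d)
        assert obj.true_volume() == pytest.approx((math.pi / 6) * d**3, abs=0, rel=1e-15)

    def test_bead_phantom_rows_match_objects(self):
        spec = ph.bead_grid_spec(12, 1.0, seed=7)
        _, gt = ph.make_bead_phantom(spec)
        assert len(gt.objects) == 12
        assert (gt.objects.diameter_um == 1.0).all()
        assert gt.objects.volume_um3.iloc[0] == pytest.approx(math.pi / 6)

    def test_full_exclusion_must_stay_below_one(self):
        with pytest.raises(ValueError, match="exclusion"):
            ph.PlantedObject(id=0, shape_kind="sphere", center=(1, 1, 1),
                             diameter=0.8, exclusion=1.0)

    def test_voxelised_volume_unbiased(self, single_bead):
        spec, _, gt = single_bead
        cov = ph.total_object_coverage(spec)
        v = cov.sum() * np.prod(spec.voxel_size)
        assert v == pytest.approx(gt.objects.volume_um3.iloc[0], rel=1e-3)

    def test_string_volume_counts_all_beads(self):
        obj = ph.PlantedObject(id=0, shape_kind="string", center=(3, 2, 2),
                               diameter=0.6, n_beads=3)
        assert obj.true_volume() == pytest.approx(3 * (math.pi / 6) * 0.6**3)


class TestBeadPhantom:
    def test_overlapping_beads_rejected(self):
        objs = [
            ph.PlantedObject(id=0, shape_kind="sphere", center=(1.0, 1.0, 1.0),
                             diameter=1.0),
            ph.PlantedObject(id=1, shape_kind="sphere", center=(1.0, 1.0, 2.2),
                             diameter=1.0),
        ]
        with pytest.raises(ValueError, match="bead diameter"):
            ph.make_bead_phantom(_bath_spec(objs))

    def test_center_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside field"):
            _bath_spec([ph.PlantedObject(id=0, shape_kind="sphere",
                                         center=(99.0, 1.0, 1.0), diameter=0.5)])

    def test_two_channels_dark_and_bright(self):
        spec = _bath_spec([ph.PlantedObject(
            id=0, shape_kind="sphere", center=(1.2, 1.2, 1.2), diameter=1.0,
            marker_level=500.0)])
        stack, _ = ph.make_bead_phantom(spec)
        gfp, marker = stack.channel("GFP"), stack.channel("marker")
        assert gfp.max() == pytest.approx(spec.cytoplasm_level)
        assert gfp.min() == pytest.approx(0.0, abs=1e-6)
        assert marker.max() == pytest.approx(500.0, rel=1e-6)


class TestCellPhantom:
    def test_ground_truth_echoes_cell_volume(self, small_cell):
        spec, _, gt = small_cell
        assert gt.cell_volume_um3 == pytest.approx(spec.cell.volume())
        assert len(gt.objects) == 12

    def test_object_outside_cell_rejected(self):
        cell = ph.EllipsoidSpec(center=(3, 3, 3), semiaxes=(2, 2, 2))
        obj = ph.PlantedObject(id=0, shape_kind="sphere", center=(3, 3, 4.9),
                               diameter=0.8)
        spec = ph.PhantomSpec(field_shape=(30, 80, 80),
                              voxel_size=(0.2, 0.08, 0.08),
                              objects=[obj], cell=cell)
        with pytest.raises(ValueError, match="outside the cell"):
            ph.make_cell_phantom(spec)

    def test_marked_fraction_reflected_in_ground_truth(self):
        spec = ph.random_cell_spec(150.0, 20, seed=11, marked_fraction=0.8)
        _, gt = ph.make_cell_phantom(spec)
        negative = (~gt.objects.marker_positive).mean()
        # seeded draw: close to 20% marker-negative
        assert 0.0 <= negative <= 0.45

    def test_sg_count_tracks_cell_volume_in_cohort(self):
        vols = [150, 200, 250, 300, 350, 400, 450]
        counts = [round(0.08 * v) for v in vols]
        rows = []
        for i, (v, n) in enumerate(zip(vols, counts)):
            spec = ph.random_cell_spec(v, n, seed=20 + i)
            _, gt = ph.make_cell_phantom(spec)
            rows.append((gt.cell_volume_um3, len(gt.objects)))
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        assert np.corrcoef(x, y)[0, 1] > 0.95


class TestOptics:
    def test_delta_psf_no_noise_is_identity(self, single_bead):
        spec, stack, _ = single_bead
        out = ph.apply_optics(stack, PSFModel.delta(), spec)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_deterministic_given_seed(self):
        spec = ph.bead_grid_spec(2, 0.75, seed=5)
        stack, _ = ph.make_bead_phantom(spec)
        psf = PSFModel.gaussian()
        a = ph.apply_optics(stack, psf, spec)
        b = ph.apply_optics(stack, psf, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unit_kernel_conserves_intensity(self, single_bead):
        spec, stack, _ = single_bead
        out = ph.apply_optics(stack, PSFModel.gaussian(), spec)
        total_in = stack.channel("GFP").sum()
        total_out = out.channel("GFP").sum()
        assert total_out == pytest.approx(total_in, rel=0.01)

    def test_blurred_void_center_partially_fills(self, single_bead):
        spec, stack, gt = single_bead
        out = ph.apply_optics(stack, PSFModel.gaussian(), spec)
        row = gt.objects.iloc[0]
        iz = int(row.center_z_um / spec.voxel_size[0])
        iy = int(row.center_y_um / spec.voxel_size[1])
        ix = int(row.center_x_um / spec.voxel_size[2])
        center = out.channel("GFP")[iz, iy, ix]
        assert 0.0 < center < 0.5 * spec.cytoplasm_level

    def test_kernel_larger_than_field_rejected(self):
        spec = _bath_spec(
            [ph.PlantedObject(id=0, shape_kind="sphere", center=(0.2, 0.2, 0.2),
                              diameter=0.3)],
            shape=(3, 10, 10),
        )
        stack, _ = ph.make_bead_phantom(spec)
        with pytest.raises(ValueError, match="larger than field"):
            ph.apply_optics(stack, PSFModel.gaussian(fwhm_axial=5.0), spec)

    def test_shadow_dims_column_above_object(self):
        spec = _bath_spec(
            [ph.PlantedObject(id=0, shape_kind="sphere", center=(0.8, 1.2, 1.2),
                              diameter=1.0)],
            object_attenuation=0.6, scatter_spread=0.0,
        )
        stack, _ = ph.make_bead_phantom(spec)
        out = ph.apply_optics(stack, PSFModel.delta(), spec)
        gfp = out.channel("GFP")
        iy = ix = 30  # through the bead center
        above = gfp[20, iy, ix]  # 2.05 μm: above the bead
        aside = gfp[20, iy, 5]
        assert above == pytest.approx(
            spec.cytoplasm_level * math.exp(-0.6 * 1.0), rel=0.05)
        assert aside == pytest.approx(spec.cytoplasm_level, rel=0.01)


class TestFusionSeries:
    def _pair_spec(self, m1=500.0, m2=0.0, d=0.8):
        objs = [
            ph.PlantedObject(id=0, shape_kind="sphere", center=(2.2, 2.0, 2.0),
                             diameter=d, marker_level=m1),
            ph.PlantedObject(id=1, shape_kind="sphere", center=(3.9, 2.0, 2.0),
                             diameter=d, marker_level=m2),
        ]
        return ph.PhantomSpec(field_shape=(30, 50, 50),
                              voxel_size=(0.2, 0.08, 0.08), objects=objs,
                              poisson_gain=0.0, gaussian_sd=0.0, seed=4)

    def test_equal_volume_fusion_halves_marker_density(self):
        frames, gt = ph.make_timelapse_fusion(
            self._pair_spec(), [(3, (0, 1), 2)], n_frames=5)
        sched = gt.fusion_schedule[0]
        assert sched["dilution_ratio"] == pytest.approx(0.5)
        assert sched["child_marker_level"] == pytest.approx(250.0)
        child = gt.objects[gt.objects.id == 2].iloc[0]
        parents = gt.objects[gt.objects.id.isin([0, 1])]
        assert child.volume_um3 == pytest.approx(parents.volume_um3.sum())

    def test_z_stacked_parents_make_z_elongated_child(self):
        frames, gt = ph.make_timelapse_fusion(
            self._pair_spec(), [(3, (0, 1), 2)], n_frames=4)
        child = gt.objects[gt.objects.id == 2].iloc[0]
        # spheroid long axis (pole to pole of the pair) exceeds its width
        assert gt.fusion_schedule[0]["axis_zyx"][0] == pytest.approx(1.0)
        assert child.shape_kind == "spheroid"

    def test_marker_integral_conserved_across_event(self):
        frames, _ = ph.make_timelapse_fusion(
            self._pair_spec(), [(3, (0, 1), 2)], n_frames=5)
        before = frames[2].channel("marker").sum() * frames[2].voxel_volume
        after = frames[3].channel("marker").sum() * frames[3].voxel_volume
        assert after == pytest.approx(before, rel=0.02)

    def test_empty_schedule_gives_static_series(self):
        frames, gt = ph.make_timelapse_fusion(self._pair_spec(), [], n_frames=3)
        assert len(frames) == 3
        np.testing.assert_array_equal(frames[0].data, frames[2].data)
        assert gt.fusion_schedule == []

    def test_unreachable_parents_rejected(self):
        spec = self._pair_spec()
        spec.objects[1] = ph.PlantedObject(
            id=1, shape_kind="sphere", center=(3.9, 2.0, 3.8),
            diameter=0.8, marker_level=0.0)
        with pytest.raises(ValueError, match="not adjacent"):
            ph.make_timelapse_fusion(spec, [(1, (0, 1), 2)], n_frames=3)
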