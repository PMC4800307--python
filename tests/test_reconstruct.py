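"""Contour linking, lamination volumetry, shape metrics, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point

from nci3d.reconstruct import (
    Organelle3D,
    classify_compartment,
    laminate_volume,
    link_contours,
    objects_to_table,
    shape_metrics,
)
from nci3d.segmentation import CellMask, Contour


def circle_contour(z, cy, cx, radius, n_vertices=128):
    """Contour whose polygon is a regular approximation of a circle."""
    poly = Point(cy, cx).buffer(radius, quad_segs=n_vertices // 4)
    return Contour.from_polygon(z, poly, center_intensity=0.0,
                                periphery_intensity=1000.0, fraction=0.925)


def sphere_contours(radius=0.5, dz=0.2, center=(0.9, 2.0, 2.0)):
    """Circle sections of a sphere centred on a slice midplane (the default
    z places the centre exactly on slice 4 at dz = 0.2)."""
    cz, cy, cx = center
    out = []
    z0 = int(round(cz / dz - 0.5))
    for k in range(-5, 6):
        z = z0 + k
        off = (z + 0.5) * dz - cz
        r2 = radius**2 - off**2
        if r2 > 1e-12:
            out.append(circle_contour(z, cy, cx, math.sqrt(r2)))
    return out


class TestLamination:
    def test_hand_computed_sphere_slab_volume(self):
        """r = 0.5 μm sphere sampled at z offsets 0, ±0.2, ±0.4:
        areas π(0.25 − z²) sum to 2.67035 μm², so V = 0.534071 μm³."""
        areas = [math.pi * (0.25 - z**2) for z in (-0.4, -0.2, 0.0, 0.2, 0.4)]
        v = laminate_volume(areas, dz=0.2)
        assert v == pytest.approx(0.2 * sum(areas), abs=1e-12)
        assert v == pytest.approx(0.5340707, abs=1e-4)

    def test_slab_bias_vanishes_as_dz_shrinks(self):
        dz = 0.02
        offsets = np.arange(-0.49, 0.50, dz)
        areas = [math.pi * max(0.25 - z**2, 0.0) for z in offsets]
        v = laminate_volume(areas, dz=dz)
        assert v == pytest.approx(math.pi / 6, rel=0.01)

    def test_single_contour_is_area_times_dz(self):
        assert laminate_volume([0.7], dz=0.2) == pytest.approx(0.14)

    def test_linear_in_dz(self):
        areas = [0.3, 0.5, 0.3]
        assert laminate_volume(areas, 0.4) == pytest.approx(
            2 * laminate_volume(areas, 0.2))

    def test_no_contours_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            laminate_volume([], dz=0.2)


class TestLinking:
    def test_sphere_sections_link_to_one_organelle(self):
        contours = sphere_contours()
        assert len(contours) == 5  # z offsets 0, ±0.2, ±0.4
        orgs = link_contours(contours, dz=0.2)
        assert len(orgs) == 1
        assert orgs[0].n_contours == 5

    def test_laterally_separated_spheres_stay_apart(self):
        a = sphere_contours(center=(1.0, 2.0, 2.0))
        b = sphere_contours(center=(1.0, 2.0, 5.0))
        orgs = link_contours(a + b, dz=0.2)
        assert len(orgs) == 2

    def test_string_of_touching_spheres_is_one_organelle(self):
        # three tangent spheres strung along z
        contours = []
        for i in range(3):
            contours += sphere_contours(radius=0.5,
                                        center=(0.9 + i * 1.0, 2.0, 2.0))
        orgs = link_contours(contours, dz=0.2)
        assert len(orgs) == 1

    def test_linking_symmetric_under_slice_reversal(self):
        contours = sphere_contours() + sphere_contours(center=(1.0, 2.0, 4.0))
        nz = 12
        fwd = link_contours(contours, dz=0.2, n_slices=nz)
        flipped = [
            Contour.from_polygon(nz - 1 - c.z_index, c.polygon,
                                 c.center_intensity, c.periphery_intensity,
                                 c.fraction)
            for c in contours
        ]
        rev = link_contours(flipped, dz=0.2, n_slices=nz)
        fwd_parts = sorted(sorted(c.area for c in o.contours) for o in fwd)
        rev_parts = sorted(sorted(c.area for c in o.contours) for o in rev)
        assert fwd_parts == rev_parts

    def test_low_overlap_does_not_link(self):
        a = circle_contour(0, 2.0, 2.0, 0.4)
        b = circle_contour(1, 2.0, 2.75, 0.4)  # thin sliver of overlap
        orgs = link_contours([a, b], dz=0.2)
        assert len(orgs) == 2

    def test_truncated_objects_flagged_at_stack_borders(self):
        touching = [circle_contour(0, 2.0, 2.0, 0.3),
                    circle_contour(1, 2.0, 2.0, 0.3)]
        interior = [circle_contour(5, 4.0, 4.0, 0.3),
                    circle_contour(6, 4.0, 4.0, 0.3)]
        orgs = link_contours(touching + interior, dz=0.2, n_slices=12)
        flags = {round(o.centroid[1], 1): o.truncated for o in orgs}
        assert flags[2.0] is True
        assert flags[4.0] is False

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=7),      # z index
            st.floats(min_value=1.0, max_value=7.0),    # cy
            st.floats(min_value=1.0, max_value=7.0),    # cx
            st.floats(min_value=0.2, max_value=0.6),    # radius
        ),
        min_size=1, max_size=8,
    ))
    def test_partition_invariant_under_reversal(self, circles):
        """Property: reversing slice order never changes which contours
        are grouped into one organelle."""
        contours = [circle_contour(z, cy, cx, r) for z, cy, cx, r in circles]
        nz = 8
        fwd = link_contours(contours, dz=0.2, n_slices=nz)
        flipped = [
            Contour.from_polygon(nz - 1 - c.z_index, c.polygon,
                                 c.center_intensity, c.periphery_intensity,
                                 c.fraction)
            for c in contours
        ]
        rev = link_contours(flipped, dz=0.2, n_slices=nz)
        key = lambda o: sorted(
            (round(c.area, 9), round(c.centroid[0], 6), round(c.centroid[1], 6))
            for c in o.contours
        )
        assert sorted(key(o) for o in fwd) == sorted(key(o) for o in rev)

    def test_noncontiguous_z_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            Organelle3D(id=0, contours=[circle_contour(0, 1, 1, 0.3),
                                        circle_contour(2, 1, 1, 0.3)], dz=0.2)


class TestShapeMetrics:
    def test_sphere_elongation_near_unity(self):
        org = link_contours(sphere_contours(), dz=0.2)[0]
        assert org.elongation == pytest.approx(1.0, abs=0.2)

    def test_z_cylinder_elongation(self):
        # 2.0 μm long, 0.6 μm wide cylinder sampled every 0.2 μm
        contours = [circle_contour(z, 2.0, 2.0, 0.3) for z in range(10)]
        org = link_contours(contours, dz=0.2)[0]
        assert org.elongation == pytest.approx(2.0 / 0.6, rel=0.1)
        assert shape_metrics(org)["shape_class"] == "elongated"

    def test_equivalent_diameter_from_lamination_volume(self):
        org = link_contours(sphere_contours(), dz=0.2)[0]
        v = org.lamination_volume
        assert org.equivalent_diameter == pytest.approx((6 * v / math.pi) ** (1 / 3))

    def test_single_contour_flagged_thin(self):
        org = link_contours([circle_contour(3, 1.0, 1.0, 0.3)], dz=0.2)[0]
        assert org.thin
        assert org.z_extent == pytest.approx(0.2)

    def test_voxel_volume_close_to_lamination(self):
        org = link_contours(sphere_contours(), dz=0.2)[0]
        assert org.voxel_volume((0.04, 0.04)) == pytest.approx(
            org.lamination_volume, rel=0.05)


class TestClassification:
    def _mask(self, nucleus_box=None):
        shape = (20, 60, 60)
        cell = np.ones(shape, bool)
        nucleus = np.zeros(shape, bool)
        if nucleus_box:
            nucleus[nucleus_box] = True
        return CellMask(cell=cell, nucleus=nucleus, voxel_size=(0.2, 0.1, 0.1))

    def test_cytoplasmic_sphere_is_sg(self):
        org = link_contours(sphere_contours(radius=0.4), dz=0.2)[0]
        assert classify_compartment(org, self._mask()) == "SG"

    def test_void_inside_nucleus_is_nuclear(self):
        org = link_contours(sphere_contours(radius=0.4), dz=0.2)[0]
        mask = self._mask(nucleus_box=(slice(0, 12), slice(0, 40), slice(0, 40)))
        assert classify_compartment(org, mask) == "nuclear"

    def test_thin_z_tube_is_mitochondrion_like(self):
        contours = [circle_contour(z, 2.0, 2.0, 0.15) for z in range(10)]
        org = link_contours(contours, dz=0.2)[0]
        assert classify_compartment(org, self._mask()) == "mitochondrion-like"

    def test_thin_inplane_tube_is_mitochondrion_like(self):
        from shapely.geometry import Polygon

        rect = Polygon([(1.0, 1.0), (1.0, 3.0), (1.3, 3.0), (1.3, 1.0)])
        contours = [
            Contour.from_polygon(z, rect, 0.0, 1000.0, 0.925) for z in (4, 5)
        ]
        org = link_contours(contours, dz=0.2)[0]
        assert classify_compartment(org, self._mask()) == "mitochondrion-like"

    def test_oversized_void_unclassified(self):
        org = link_contours(sphere_contours(radius=1.2,
                                            center=(1.4, 3.0, 3.0)), dz=0.2)[0]
        assert classify_compartment(org, self._mask()) == "unclassified"


class TestObjectsTable:
    def test_table_has_fixed_header_and_rows(self):
        orgs = [link_contours(sphere_contours(), dz=0.2)[0]]
        orgs[0].class_label = "SG"
        table = objects_to_table(orgs, voxel_size_yx=(0.04, 0.04))
        assert len(table) == 1
        assert table.loc[0, "class"] == "SG"
        assert table.loc[0, "volume_lamination_um3"] > 0
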