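"""3D organelle reconstruction from per-slice contours.

Contours in adjacent z-slices that overlap in-plane are linked into one
organelle; the organelle's volume is obtained by lamination — the sum of
contour areas times the z-interval (a serial-section slab model).  The
slab model carries a small positive bias for spheres (~+2% at dz = 0.2 μm
for a 1 μm sphere) that vanishes as dz → 0; the voxel-count volume is
reported alongside for QC.  Shape metrics capture the axial stretching
that the anisotropic confocal PSF imposes on small organelles, and a rule
set assigns compartment classes (secretory granule, mitochondrion-like
tubule, nuclear substructure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .imageio import OBJECT_TABLE_COLUMNS
from .segmentation import CellMask, Contour


@dataclass
class Organelle3D:
    """A z-contiguous stack of linked contours."""

    id: int
    contours: list[Contour]
    dz: float
    class_label: str = "unclassified"
    marker_mean: float = float("nan")
    marker_positive: bool | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.contours = sorted(self.contours, key=lambda c: c.z_index)
        zs = [c.z_index for c in self.contours]
        if any(b - a != 1 for a, b in zip(zs, zs[1:])):
            raise ValueError(f"organelle {self.id}: z indices not contiguous: {zs}")

    # -- geometry ---------------------------------------------------------

    @property
    def n_contours(self) -> int:
        return len(self.contours)

    @property
    def z_indices(self) -> list[int]:
        return [c.z_index for c in self.contours]

    @property
    def lamination_volume(self) -> float:
        """Slab-model volume: dz × Σ contour areas (μm³)."""
        return laminate_volume([c.area for c in self.contours], self.dz)

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the sphere with the lamination volume, (6V/π)^(1/3)."""
        return (6.0 * self.lamination_volume / math.pi) ** (1.0 / 3.0)

    @property
    def centroid(self) -> tuple[float, float, float]:
        """Area-weighted centroid (z, y, x) in μm."""
        areas = np.array([c.area for c in self.contours])
        zc = np.array([(c.z_index + 0.5) * self.dz for c in self.contours])
        yx = np.array([c.centroid for c in self.contours])
        w = areas / areas.sum()
        return (float(w @ zc), float(w @ yx[:, 0]), float(w @ yx[:, 1]))

    @property
    def z_extent(self) -> float:
        """Axial extent under the slab model: one dz per contour (μm)."""
        return self.n_contours * self.dz

    @property
    def max_lateral_extent(self) -> float:
        """Largest in-plane Feret diameter over all contours (μm)."""
        best = 0.0
        for c in self.contours:
            hull = np.asarray(c.polygon.convex_hull.exterior.coords)
            d = np.linalg.norm(hull[:, None, :] - hull[None, :, :], axis=-1)
            best = max(best, float(d.max()))
        return best

    @property
    def max_lateral_diameter(self) -> float:
        """Largest equivalent circle diameter over all contours (μm)."""
        return max(c.equivalent_diameter for c in self.contours)

    @property
    def mean_lateral_diameter(self) -> float:
        return float(np.mean([c.equivalent_diameter for c in self.contours]))

    @property
    def elongation(self) -> float:
        """Axial stretching: z-extent / largest lateral equivalent diameter."""
        return self.z_extent / self.max_lateral_diameter

    @property
    def thin(self) -> bool:
        """Single-contour object: z-extent is only the dz floor."""
        return self.n_contours == 1

    def voxel_volume(self, voxel_size_yx) -> float:
        """Voxel-count volume: pixels inside each contour × voxel volume."""
        dy, dx = voxel_size_yx
        total_px = 0
        for c in self.contours:
            poly = c.polygon
            miny, minx, maxy, maxx = poly.bounds
            ys = np.arange(math.floor(miny / dy), math.ceil(maxy / dy) + 1)
            xs = np.arange(math.floor(minx / dx), math.ceil(maxx / dx) + 1)
            if ys.size == 0 or xs.size == 0:
                continue
            yy, xx = np.meshgrid((ys + 0.5) * dy, (xs + 0.5) * dx, indexing="ij")
            inside = shapely.contains_xy(poly, yy.ravel(), xx.ravel())
            total_px += int(inside.sum())
        return total_px * dy * dx * self.dz


def laminate_volume(areas, dz: float) -> float:
    """Serial-section lamination: volume = dz × Σ areas.

    ``areas`` may be a sequence of contour areas (μm²) or an
    :class:`Organelle3D`.
    """
    if isinstance(areas, Organelle3D):
        areas = [c.area for c in areas.contours]
    areas = list(areas)
    if not areas:
        raise ValueError("lamination needs at least one contour")
    return float(dz) * float(np.sum(areas))


def link_contours(contours, dz: float, overlap_threshold: float = 0.5,
                  n_slices: int | None = None) -> list[Organelle3D]:
    """Link contours at the same position in neighbouring slices.

    Two contours in adjacent slices belong to one organelle iff their
    polygon overlap area is at least ``overlap_threshold`` × the smaller
    area.  Ambiguities are resolved by largest overlap, then smallest
    centroid distance; each contour joins at most one organelle and
    unmatched contours open or close objects.  Objects whose contours touch
    the first or last slice are flagged truncated (their volumes are
    underestimates) when ``n_slices`` is given.
    """
    by_z: dict[int, list[Contour]] = {}
    for c in contours:
        by_z.setdefault(c.z_index, []).append(c)
    if not by_z:
        return []

    open_objects: list[list[Contour]] = []
    finished: list[list[Contour]] = []
    for z in range(min(by_z), max(by_z) + 1):
        slice_contours = by_z.get(z, [])
        eligible = [o for o in open_objects
                    if o[-1].z_index == z - 1]
        pairs = []
        for oi, obj in enumerate(open_objects):
            if obj[-1].z_index != z - 1:
                continue
            pa = obj[-1].polygon
            ca = obj[-1].centroid
            for ci, cont in enumerate(slice_contours):
                inter = pa.intersection(cont.polygon).area
                if inter >= overlap_threshold * min(pa.area, cont.polygon.area):
                    cb = cont.centroid
                    dist = math.hypot(ca[0] - cb[0], ca[1] - cb[1])
                    pairs.append((-inter, dist, oi, ci))
        pairs.sort()
        used_obj, used_cont = set(), set()
        for neg_inter, dist, oi, ci in pairs:
            if oi in used_obj or ci in used_cont:
                continue
            open_objects[oi].append(slice_contours[ci])
            used_obj.add(oi)
            used_cont.add(ci)
        # close objects that found no continuation
        still_open = []
        for oi, obj in enumerate(open_objects):
            if obj[-1].z_index < z - 1 or (
                obj[-1].z_index == z - 1 and oi not in used_obj
            ):
                finished.append(obj)
            else:
                still_open.append(obj)
        open_objects = still_open
        for ci, cont in enumerate(slice_contours):
            if ci not in used_cont:
                open_objects.append([cont])
    finished.extend(open_objects)

    def sort_key(obj):
        c0 = obj[0]
        cy, cx = c0.centroid
        return (c0.z_index, round(cy, 6), round(cx, 6))

    organelles = []
    for oid, obj in enumerate(sorted(finished, key=sort_key)):
        org = Organelle3D(id=oid, contours=obj, dz=dz)
        if n_slices is not None:
            zs = org.z_indices
            org.truncated = (zs[0] == 0) or (zs[-1] == n_slices - 1)
        organelles.append(org)
    return organelles


def shape_metrics(org: Organelle3D) -> dict:
    """Shape summary of one organelle."""
    return {
        "lamination_volume_um3": org.lamination_volume,
        "equivalent_diameter_um": org.equivalent_diameter,
        "z_extent_um": org.z_extent,
        "max_lateral_extent_um": org.max_lateral_extent,
        "mean_lateral_diameter_um": org.mean_lateral_diameter,
        "elongation": org.elongation,
        "shape_class": "elongated" if org.elongation > 1.5 else "spheroid",
        "thin": org.thin,
    }


def classify_compartment(org: Organelle3D, cell_mask: CellMask | None = None,
                         sg_diameter_range=(0.3, 1.5),
                         tube_max_width: float = 0.4,
                         tube_min_elongation: float = 2.0) -> str:
    """Assign a compartment class from position and shape.

    Rules, in order: centroid inside the nucleus → ``nuclear``; thin tube
    in any axis (width < ``tube_max_width`` μm, elongation >
    ``tube_min_elongation``) → ``mitochondrion-like``; equivalent diameter
    inside ``sg_diameter_range`` → ``SG``; otherwise ``unclassified``.
    """
    if cell_mask is not None and cell_mask.nucleus.any():
        cz, cy, cx = org.centroid
        dz, dy, dx = cell_mask.voxel_size
        iz = min(max(int(cz / dz), 0), cell_mask.nucleus.shape[0] - 1)
        iy = min(max(int(cy / dy), 0), cell_mask.nucleus.shape[1] - 1)
        ix = min(max(int(cx / dx), 0), cell_mask.nucleus.shape[2] - 1)
        if cell_mask.nucleus[iz, iy, ix]:
            return "nuclear"
    # z-aligned tubule
    if (org.max_lateral_diameter < tube_max_width
            and org.elongation > tube_min_elongation):
        return "mitochondrion-like"
    # in-plane tubule: effective width from area and Feret length
    ext = org.max_lateral_extent
    if ext > 0:
        mean_area = float(np.mean([c.area for c in org.contours]))
        width = 4.0 * mean_area / (math.pi * ext)
        if width < tube_max_width and ext / max(width, 1e-9) > tube_min_elongation:
            return "mitochondrion-like"
    lo, hi = sg_diameter_range
    if lo <= org.equivalent_diameter <= hi:
        return "SG"
    return "unclassified"


def measure_marker(org: Organelle3D, marker: np.ndarray, voxel_size) -> float:
    """Mean marker intensity inside the organelle's contours."""
    dz, dy, dx = voxel_size
    vals = []
    for c in org.contours:
        z = c.z_index
        if not 0 <= z < marker.shape[0]:
            continue
        poly = c.polygon
        miny, minx, maxy, maxx = poly.bounds
        ys = np.arange(max(math.floor(miny / dy), 0),
                       min(math.ceil(maxy / dy) + 1, marker.shape[1]))
        xs = np.arange(max(math.floor(minx / dx), 0),
                       min(math.ceil(maxx / dx) + 1, marker.shape[2]))
        if ys.size == 0 or xs.size == 0:
            continue
        yy, xx = np.meshgrid((ys + 0.5) * dy, (xs + 0.5) * dx, indexing="ij")
        inside = shapely.contains_xy(poly, yy.ravel(), xx.ravel())
        if inside.any():
            block = marker[z][np.ix_(ys, xs)].ravel()
            vals.append(block[inside])
    if not vals:
        return float("nan")
    return float(np.concatenate(vals).mean())


@dataclass
class CellReconstruction:
    """Everything recovered from one cell: body, nucleus, organelles."""

    cell_volume: float
    organelles: list[Organelle3D]
    cell_mask: CellMask | None = None
    table: pd.DataFrame | None = None
    logs: dict = field(default_factory=dict)

    @property
    def sg_objects(self) -> list[Organelle3D]:
        return [o for o in self.organelles if o.class_label == "SG"]

    @property
    def sg_count(self) -> int:
        return len(self.sg_objects)


def objects_to_table(organelles, voxel_size_yx=None) -> pd.DataFrame:
    """Flatten organelles into the fixed-header inventory table."""
    rows = []
    for org in organelles:
        cz, cy, cx = org.centroid
        rows.append({
            "id": org.id,
            "class": org.class_label,
            "volume_lamination_um3": org.lamination_volume,
            "volume_voxel_um3": (
                org.voxel_volume(voxel_size_yx) if voxel_size_yx else float("nan")
            ),
            "equivalent_diameter_um": org.equivalent_diameter,
            "centroid_z_um": cz,
            "centroid_y_um": cy,
            "centroid_x_um": cx,
            "z_extent_um": org.z_extent,
            "max_lateral_extent_um": org.max_lateral_extent,
            "elongation": org.elongation,
            "n_contours": org.n_contours,
            "truncated": org.truncated,
            "marker_mean": org.marker_mean,
            "marker_positive": org.marker_positive,
        })
    return pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS)
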