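"""Slice-wise detection of negatively stained voids and contour extraction.

The boundary of a void is drawn by a relative-intensity rule: with the void
center set to 0% and the surrounding cytoplasm ("periphery") to 100%, the
contour is the iso-intensity curve at 90–95% (default 92.5%).  The
periphery reference is local — the median intensity in an annulus 0.2–0.4
μm outside the void's support — so the rule self-calibrates against depth
attenuation and local shading; the support/annulus pair is refined
iteratively so that the annulus sits on the intensity plateau rather than
in the blur skirt.  Contour vertices come from marching squares with
linear interpolation, giving sub-voxel accuracy at 40 nm pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


@dataclass
class Contour:
    """A closed void boundary in one z-slice.

    Vertices are (y, x) pairs in micrometres; ``center_intensity`` and
    ``periphery_intensity`` are the 0% / 100% references of the relative
    rule and ``fraction`` the level actually used.
    """

    z_index: int
    vertices: np.ndarray  # (N, 2) μm, (y, x)
    area: float
    center_intensity: float
    periphery_intensity: float
    fraction: float
    seed_yx: tuple[int, int] | None = None
    _polygon: Polygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.area <= 0:
            raise ValueError("contour area must be positive")
        if not self.periphery_intensity > self.center_intensity:
            raise ValueError("periphery intensity must exceed center intensity")

    @classmethod
    def from_polygon(cls, z_index, polygon: Polygon, center_intensity,
                     periphery_intensity, fraction, seed_yx=None):
        verts = np.asarray(polygon.exterior.coords)
        c = cls(z_index=z_index, vertices=verts, area=polygon.area,
                center_intensity=center_intensity,
                periphery_intensity=periphery_intensity,
                fraction=fraction, seed_yx=seed_yx)
        c._polygon = polygon
        return c

    @property
    def polygon(self) -> Polygon:
        if self._polygon is None:
            p = Polygon(self.vertices)
            if not p.is_valid:
                p = p.buffer(0)
            self._polygon = p
        return self._polygon

    @property
    def centroid(self) -> tuple[float, float]:
        """(y, x) area centroid in μm."""
        c = self.polygon.centroid
        return (c.x, c.y)  # vertices are stored (y, x), so .x is the row coord

    @property
    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the same area, μm."""
        return 2.0 * math.sqrt(self.area / math.pi)


@dataclass
class CellMask:
    """Binary cell-body region with nucleus subregion."""

    cell: np.ndarray  # bool (Z, Y, X)
    nucleus: np.ndarray  # bool (Z, Y, X), subset of cell
    voxel_size: tuple[float, float, float]
    n_components_found: int = 1

    @property
    def cell_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return float(self.cell.sum()) * dz * dy * dx

    @property
    def nucleus_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return float(self.nucleus.sum()) * dz * dy * dx


def full_field_mask(stack) -> CellMask:
    """Mask covering the whole field — for bead baths with no cell body."""
    shape = stack.shape_zyx
    return CellMask(
        cell=np.ones(shape, dtype=bool),
        nucleus=np.zeros(shape, dtype=bool),
        voxel_size=stack.voxel_size,
    )


def segment_cell_body(stack, channel: str | int = 0,
                      smooth_sigma: float = 1.0,
                      nucleus_level_fraction: float = 0.75,
                      min_nucleus_volume: float = 20.0) -> CellMask:
    """Outline the cell body (and nucleus) from the GFP channel.

    The cell is the largest connected above-background component, with
    holes (voids, nucleus) filled slice by slice; its volume is the voxel
    count times the voxel volume.  The nucleus is recovered as the largest
    dim region inside the cell exceeding ``min_nucleus_volume`` μm³ —
    organelle-scale voids are orders of magnitude smaller and never
    qualify.

    Raises
    ------
    ValueError
        If no foreground is found.
    """
    img = np.asarray(stack.channel(channel), dtype=np.float32)
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    if sm.max() <= 0:
        raise ValueError("empty field: no foreground signal")
    try:
        thr = threshold_otsu(sm)
    except ValueError as exc:
        raise ValueError("empty field: cannot threshold") from exc
    fg = sm > thr
    if not fg.any():
        raise ValueError("empty field: no foreground above threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        logger.info("segment_cell_body: %d components found, keeping largest", n)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    cell = labels == (1 + int(np.argmax(sizes)))
    for z in range(cell.shape[0]):
        cell[z] = ndimage.binary_fill_holes(cell[z])

    interior = img[cell]
    med = float(np.median(interior))
    dim = cell & (sm < nucleus_level_fraction * med)
    nucleus = np.zeros_like(cell)
    if dim.any():
        dz, dy, dx = stack.voxel_size
        lab, m = ndimage.label(dim)
        if m:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, m + 1))
            vols = sizes * dz * dy * dx
            big = np.flatnonzero(vols >= min_nucleus_volume)
            if big.size:
                keep = big[np.argmax(vols[big])] + 1
                nucleus = lab == keep
                for z in range(nucleus.shape[0]):
                    nucleus[z] = ndimage.binary_fill_holes(nucleus[z])
    return CellMask(cell=cell, nucleus=nucleus, voxel_size=stack.voxel_size,
                    n_components_found=max(int(n), 1))


def detect_void_seeds(slice_img, cytoplasm_level: float, voxel_size_yx,
                      cell_mask_slice=None, min_contrast: float = 0.6,
                      merge_distance: float = 0.25,
                      smooth_sigma: float = 1.0) -> np.ndarray:
    """Regional intensity minima deep enough to be void centers.

    A seed must be darker than ``min_contrast`` of the cytoplasm level;
    minima closer than ``merge_distance`` μm are merged.  Returns an
    ``(n, 2)`` array of (row, col) voxel indices (possibly empty).
    """
    img = np.asarray(slice_img, dtype=np.float32)
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    inv = cytoplasm_level - sm
    min_dist_px = max(1, int(round(merge_distance / min(voxel_size_yx))))
    peaks = peak_local_max(
        inv,
        min_distance=min_dist_px,
        threshold_abs=(1.0 - min_contrast) * cytoplasm_level,
        exclude_border=False,
    )
    if peaks.size and cell_mask_slice is not None:
        mask = np.asarray(cell_mask_slice, dtype=bool)
        keep = mask[peaks[:, 0], peaks[:, 1]]
        peaks = peaks[keep]
    return peaks


def _closed_contour_around(level_contours, seed_rc):
    """Pick the closed marching-squares contour containing the seed."""
    pt = Point(seed_rc[0], seed_rc[1])
    best = None
    for verts in level_contours:
        if len(verts) < 4 or not np.allclose(verts[0], verts[-1]):
            continue
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if poly.contains(pt):
            if best is None or poly.area < best.area:
                best = poly  # innermost enclosing curve
    return best


def _polygon_px_to_um(poly_px: Polygon, voxel_size_yx) -> Polygon:
    dy, dx = voxel_size_yx
    verts = np.asarray(poly_px.exterior.coords)
    return Polygon(np.column_stack([verts[:, 0] * dy, verts[:, 1] * dx]))


def _mask_to_polygon(mask: np.ndarray) -> Polygon | None:
    sm = ndimage.gaussian_filter(mask.astype(np.float32), 0.5)
    conts = find_contours(sm, 0.5)
    best = None
    for verts in conts:
        if len(verts) < 4 or not np.allclose(verts[0], verts[-1]):
            continue
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if best is None or poly.area > best.area:
            best = poly
    return best


def extract_contour(slice_img, seed, cytoplasm_level: float, voxel_size_yx,
                    fraction: float = 0.925, cell_mask_slice=None,
                    min_diameter: float = 0.3, smooth_sigma: float = 0.75,
                    annulus=(0.2, 0.4), n_refine: int = 2,
                    binarize: bool = False, center_intensity: float | None = None,
                    z_index: int = 0) -> Contour | None:
    """Extract the 90–95%-rule contour around one seed.

    The iso-level is ``L = I_center + fraction · (I_periphery − I_center)``
    with the periphery measured as the median in an annulus
    ``annulus[0]``–``annulus[1]`` μm outside the void support (global
    cytoplasm level as fallback when the annulus is unusable).  Returns
    ``None`` when no closed iso-curve encloses the seed, when the contour
    is below the ``min_diameter`` floor, or when it escapes the cell mask.

    With ``binarize=True`` the slice is first converted black/white per
    void — the threshold sits midway between the 0% and 100% references,
    as an isodata-style conversion puts it — and the contour is the
    boundary of the binarized support (traced sub-voxel on the intensity
    image at that threshold).  On deconvolved data this localises the true
    edge of a sharp void, where the relative level applied to the raw blur
    skirt would bias the boundary outward; on an already-binary slice both
    modes trace the same region, so re-extraction is idempotent.
    """
    if not 0.90 <= fraction <= 0.95:
        raise ValueError("contour fraction must lie in [0.90, 0.95]")
    img = np.asarray(slice_img, dtype=np.float32)
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    dy, dx = voxel_size_yx
    r, c = int(seed[0]), int(seed[1])
    if center_intensity is None:
        win = sm[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        center = float(win.min())
    else:
        # the structure's 0% reference (e.g. its 3D minimum), supplied by
        # the caller; near the poles of a void the in-plane minimum is
        # already half-filled by axial blur and would misplace the level
        center = float(center_intensity)
    center = min(center, float(sm[r, c]))

    periphery = float(cytoplasm_level)
    for _ in range(max(n_refine, 1)):
        level = center + fraction * (periphery - center)
        if level <= center:
            return None
        low = sm < level
        lab, _ = ndimage.label(low)
        support_label = lab[r, c]
        if support_label == 0:
            return None
        support = lab == support_label
        dist = ndimage.distance_transform_edt(~support, sampling=(dy, dx))
        ring = (dist >= annulus[0]) & (dist <= annulus[1])
        if cell_mask_slice is not None:
            ring &= np.asarray(cell_mask_slice, dtype=bool)
        # exclude neighbouring voids from the reference
        ring &= ~low
        ring &= sm >= 0.5 * (center + periphery)
        if ring.sum() < 16:
            periphery = float(cytoplasm_level)  # global fallback
            break
        periphery = float(np.median(sm[ring]))

    if not periphery > center:
        return None
    level_fraction = 0.5 if binarize else fraction
    level = center + level_fraction * (periphery - center)
    conts = find_contours(sm, level)
    poly_px = _closed_contour_around(conts, (r, c))
    if poly_px is None:
        logger.debug("discard seed (%d,%d) z=%d: open iso-curve at border",
                     r, c, z_index)
        return None
    poly = _polygon_px_to_um(poly_px, (dy, dx))
    if poly.area <= 0:
        return None
    eq_d = 2.0 * math.sqrt(poly.area / math.pi)
    if eq_d < min_diameter:
        logger.debug("discard seed (%d,%d) z=%d: below minimum diameter",
                     r, c, z_index)
        return None
    if cell_mask_slice is not None:
        mask = np.asarray(cell_mask_slice, dtype=bool)
        verts = np.asarray(poly_px.exterior.coords)
        rows = np.clip(np.rint(verts[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cols = np.clip(np.rint(verts[:, 1]).astype(int), 0, mask.shape[1] - 1)
        if mask[rows, cols].mean() < 0.95:
            logger.debug("discard seed (%d,%d) z=%d: contour escapes cell mask",
                         r, c, z_index)
            return None
    return Contour.from_polygon(z_index, poly, center, periphery, fraction,
                                seed_yx=(r, c))


def extract_contours_for_slice(slice_img, seeds, cytoplasm_level: float,
                               voxel_size_yx, fraction: float = 0.925,
                               cell_mask_slice=None, min_diameter: float = 0.3,
                               smooth_sigma: float = 0.75, binarize: bool = False,
                               center_intensities=None,
                               z_index: int = 0) -> list[Contour]:
    """Extract one contour per seed; seeds sharing one iso-region are split
    along the intensity ridge by a seeded watershed.

    ``center_intensities`` optionally supplies a per-seed 0% reference
    (the 3D minimum of the void the seed belongs to)."""
    results: dict[int, Contour] = {}
    for i, seed in enumerate(seeds):
        ct = extract_contour(
            slice_img, seed, cytoplasm_level, voxel_size_yx,
            fraction=fraction, cell_mask_slice=cell_mask_slice,
            min_diameter=min_diameter, smooth_sigma=smooth_sigma,
            binarize=binarize,
            center_intensity=(
                None if center_intensities is None else center_intensities[i]
            ),
            z_index=z_index,
        )
        if ct is not None:
            results[i] = ct

    # group seeds whose contours cover essentially the same region
    idx = list(results)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos, a in enumerate(idx):
        for b in idx[a_pos + 1:]:
            pa, pb = results[a].polygon, results[b].polygon
            inter = pa.intersection(pb).area
            if inter > 0.5 * min(pa.area, pb.area):
                parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in idx:
        groups.setdefault(find(i), []).append(i)

    out: list[Contour] = []
    img = np.asarray(slice_img, dtype=np.float32)
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img

    def _ridge_between(i, j) -> float:
        """Highest intensity along the straight line between two seeds."""
        a, b = np.asarray(seeds[i], dtype=float), np.asarray(seeds[j], dtype=float)
        npts = max(int(np.hypot(*(b - a))) * 2, 2)
        t = np.linspace(0.0, 1.0, npts)
        rr = np.clip(np.rint(a[0] + t * (b[0] - a[0])).astype(int), 0, sm.shape[0] - 1)
        cc = np.clip(np.rint(a[1] + t * (b[1] - a[1])).astype(int), 0, sm.shape[1] - 1)
        return float(sm[rr, cc].max())

    for members in groups.values():
        if len(members) == 1:
            out.append(results[members[0]])
            continue
        # seeds on one flat minimum plateau are duplicates of a single void:
        # drop all but one unless a genuine intensity ridge separates them
        deduped: list[int] = []
        for i in members:
            ct = results[i]
            ridge_level = (ct.center_intensity
                           + 0.3 * (ct.periphery_intensity - ct.center_intensity))
            dup_of = None
            for j in deduped:
                if _ridge_between(i, j) < ridge_level:
                    dup_of = j
                    break
            if dup_of is None:
                deduped.append(i)
        members = deduped
        if len(members) == 1:
            out.append(results[members[0]])
            continue
        # shared iso-region: watershed on intensity with the seeds as markers
        level_fraction = 0.5 if binarize else fraction
        level = max(
            results[i].center_intensity
            + level_fraction
            * (results[i].periphery_intensity - results[i].center_intensity)
            for i in members
        )
        low = sm < level
        markers = np.zeros(sm.shape, dtype=np.int32)
        for k, i in enumerate(members, start=1):
            rr, cc = seeds[i]
            markers[int(rr), int(cc)] = k
        lab, _ = ndimage.label(low)
        region = np.isin(lab, [lab[int(seeds[i][0]), int(seeds[i][1])]
                               for i in members])
        ws = watershed(sm, markers, mask=region)
        for k, i in enumerate(members, start=1):
            piece = ws == k
            if not piece.any():
                continue
            poly_px = _mask_to_polygon(piece)
            if poly_px is None:
                continue
            poly = _polygon_px_to_um(poly_px, voxel_size_yx)
            eq_d = 2.0 * math.sqrt(max(poly.area, 0.0) / math.pi)
            if poly.area <= 0 or eq_d < min_diameter:
                continue
            src = results[i]
            out.append(Contour.from_polygon(
                z_index, poly, src.center_intensity, src.periphery_intensity,
                src.fraction, seed_yx=tuple(int(v) for v in seeds[i]),
            ))
    return out


def contours_to_geojson(contours) -> dict:
    """Per-slice contour dump as a GeoJSON-like FeatureCollection (μm)."""
    feats = []
    for ct in contours:
        feats.append({
            "type": "Feature",
            "properties": {
                "z_index": ct.z_index,
                "area_um2": ct.area,
                "center_intensity": ct.center_intensity,
                "periphery_intensity": ct.periphery_intensity,
                "fraction": ct.fraction,
            },
            "geometry": {
                "type": "Polygon",
                "coordinates": [np.asarray(ct.vertices)[:, ::-1].tolist()],
            },
        })
    return {"type": "FeatureCollection", "features": feats}
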