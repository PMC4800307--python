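"""Population statistics, marker colocalization, tracking and fusion.

Covers the downstream questions asked of a reconstruction: how granule
volumes are distributed, whether granule number scales with cell volume,
which granules carry a second marker, and — in time-lapse series — where
granule–granule fusion occurs and by how much it dilutes the marker per
unit volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reconstruct import CellReconstruction, Organelle3D, measure_marker

#: Cell-volume cutoffs (μm³) separating small and large cells.
SMALL_CELL_CUTOFF = 1500.0
LARGE_CELL_CUTOFF = 2500.0


# --------------------------------------------------------------------------
# size distributions
# --------------------------------------------------------------------------

@dataclass
class SizeDistribution:
    """Histogram of granule volumes with summary statistics."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    median: float
    iqr: tuple[float, float]
    strata: dict = field(default_factory=dict)  # e.g. {"small": ..., "large": ...}

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n:
            raise ValueError("histogram counts must sum to n")


def size_distribution(volumes, bin_edges=None, bins: int = 20,
                      cell_volume: float | None = None) -> SizeDistribution:
    """Histogram granule volumes (μm³).

    ``volumes`` may be an array, a list of :class:`Organelle3D` (lamination
    volumes are used) or a :class:`CellReconstruction` (SG-class objects
    only).  ``cell_volume`` tags the distribution as coming from a small
    (< 1,500 μm³) or large (> 2,500 μm³) cell.
    """
    if isinstance(volumes, CellReconstruction):
        if cell_volume is None:
            cell_volume = volumes.cell_volume
        volumes = [o.lamination_volume for o in volumes.sg_objects]
    elif len(volumes) and isinstance(volumes[0], Organelle3D):
        volumes = [o.lamination_volume for o in volumes]
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("no volumes to histogram")
    if bin_edges is None:
        counts, bin_edges = np.histogram(v, bins=bins)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        counts, _ = np.histogram(v, bins=bin_edges)
    strata = {}
    if cell_volume is not None:
        if cell_volume < SMALL_CELL_CUTOFF:
            strata["cell_class"] = "small"
        elif cell_volume > LARGE_CELL_CUTOFF:
            strata["cell_class"] = "large"
        else:
            strata["cell_class"] = "intermediate"
    q1, q3 = np.percentile(v, [25, 75])
    return SizeDistribution(
        bin_edges=np.asarray(bin_edges), counts=counts, n=int(counts.sum()),
        median=float(np.median(v)), iqr=(float(q1), float(q3)), strata=strata,
    )


# --------------------------------------------------------------------------
# cell volume vs granule number
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    r_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    spearman_rho: float
    n: int


def cell_sg_correlation(cells, n_boot: int = 1000, seed: int = 0) -> CorrelationResult:
    """Pearson correlation between cell volume and granule count.

    ``cells`` is a sequence of :class:`CellReconstruction` or of
    ``(cell_volume, sg_count)`` pairs; at least 3 cells are required.
    Confidence intervals (95%) come from a seeded bootstrap over cells;
    Spearman's rho is reported alongside as a rank-based check.
    """
    pairs = []
    for c in cells:
        if isinstance(c, CellReconstruction):
            pairs.append((c.cell_volume, c.sg_count))
        else:
            pairs.append((float(c[0]), float(c[1])))
    if len(pairs) < 3:
        raise ValueError("correlation needs at least 3 cells")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate cohort: constant volume or count")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    rs, slopes = [], []
    n = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.allclose(xb, xb[0]) or np.allclose(yb, yb[0]):
            continue
        rs.append(stats.pearsonr(xb, yb).statistic)
        slopes.append(stats.linregress(xb, yb).slope)
    r_ci = tuple(np.percentile(rs, [2.5, 97.5])) if rs else (math.nan, math.nan)
    s_ci = tuple(np.percentile(slopes, [2.5, 97.5])) if slopes else (math.nan, math.nan)
    return CorrelationResult(
        r=float(r), p_value=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), r_ci=r_ci, slope_ci=s_ci,
        spearman_rho=float(rho), n=n,
    )


# --------------------------------------------------------------------------
# marker colocalization
# --------------------------------------------------------------------------

def marker_colocalization(organelles, marker: np.ndarray, voxel_size,
                          background: tuple[float, float] | np.ndarray,
                          sigma_factor: float = 3.0):
    """Flag organelles whose interior carries marker signal.

    An organelle is marker-positive iff its mean interior marker intensity
    exceeds ``background mean + 3·SD``.  ``background`` is either a
    ``(mean, sd)`` pair or a boolean mask over marker-free voxels.

    Returns
    -------
    (flags, fraction)
        Per-organelle booleans (in input order) and the positive fraction
        among SG-class organelles.
    """
    if marker is None:
        raise ValueError("marker channel missing")
    marker = np.asarray(marker)
    if isinstance(background, tuple):
        bg_mean, bg_sd = background
    else:
        bg = marker[np.asarray(background, dtype=bool)]
        if bg.size == 0:
            raise ValueError("empty background region")
        bg_mean, bg_sd = float(bg.mean()), float(bg.std())
    thr = bg_mean + sigma_factor * bg_sd
    flags = []
    for org in organelles:
        if not np.isfinite(org.marker_mean):
            org.marker_mean = measure_marker(org, marker, voxel_size)
        positive = bool(np.isfinite(org.marker_mean) and org.marker_mean > thr)
        org.marker_positive = positive
        flags.append(positive)
    sg = [o for o in organelles if o.class_label == "SG"] or list(organelles)
    fraction = (
        sum(bool(o.marker_positive) for o in sg) / len(sg) if sg else math.nan
    )
    return flags, float(fraction)


# --------------------------------------------------------------------------
# tracking and fusion
# --------------------------------------------------------------------------

@dataclass
class Track:
    """One organelle followed through consecutive frames."""

    id: int
    entries: list[tuple[int, Organelle3D]]  # (frame, organelle)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.entries]

    @property
    def first_frame(self) -> int:
        return self.entries[0][0]

    @property
    def last_frame(self) -> int:
        return self.entries[-1][0]

    def at(self, frame: int) -> Organelle3D | None:
        for f, o in self.entries:
            if f == frame:
                return o
        return None


def track_objects(frames, gate_radius: float = 1.0) -> list[Track]:
    """Greedy nearest-centroid tracking across frames.

    ``frames`` is a list (per time point) of organelle lists with the same
    calibration.  Pairs are matched in order of increasing centroid
    distance, gated at ``gate_radius`` μm per frame; unmatched organelles
    open or close tracks.
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}
    next_id = 0
    for t, organelles in enumerate(frames):
        if t == 0:
            for org in organelles:
                tr = Track(id=next_id, entries=[(0, org)])
                open_tracks[next_id] = tr
                tracks.append(tr)
                next_id += 1
            continue
        cands = []
        for tid, tr in open_tracks.items():
            prev = tr.entries[-1][1]
            pc = np.asarray(prev.centroid)
            for oi, org in enumerate(organelles):
                d = float(np.linalg.norm(pc - np.asarray(org.centroid)))
                if d <= gate_radius:
                    cands.append((d, tid, oi))
        cands.sort()
        used_t, used_o = set(), set()
        for d, tid, oi in cands:
            if tid in used_t or oi in used_o:
                continue
            open_tracks[tid].entries.append((t, organelles[oi]))
            used_t.add(tid)
            used_o.add(oi)
        # tracks missing this frame are closed
        open_tracks = {tid: tr for tid, tr in open_tracks.items() if tid in used_t}
        for oi, org in enumerate(organelles):
            if oi not in used_o:
                tr = Track(id=next_id, entries=[(t, org)])
                open_tracks[next_id] = tr
                tracks.append(tr)
                next_id += 1
    return tracks


@dataclass
class FusionEvent:
    """Two granules merging into one between frame and frame+1."""

    frame: int
    parent_ids: tuple[int, int]
    child_id: int
    conservation_ratio: float  # V_child / (V_p1 + V_p2)
    dilution_ratio: float  # child per-volume marker / max parent per-volume
    axis: tuple[float, float, float]  # unit approach vector (z, y, x)

    def __post_init__(self) -> None:
        if self.conservation_ratio <= 0:
            raise ValueError("conservation ratio must be positive")


def detect_fusion_events(tracks, conservation_window=(0.6, 1.4),
                         centroid_gate: float = 1.5) -> list[FusionEvent]:
    """Find granule–granule fusion in a tracked series.

    An event is declared when two tracks both terminate at frame ``t`` and
    a track begins (or one of the parents continues) at ``t + 1`` near the
    parents, with a child volume between ``conservation_window`` times the
    summed parent volume.  The dilution ratio is reported when exactly one
    parent carries marker signal; the approach axis is the unit vector
    between the parent centroids at frame ``t``.
    """
    events: list[FusionEvent] = []
    if not tracks:
        return events
    last = max(tr.last_frame for tr in tracks)
    for t in range(last):
        continuing = [tr for tr in tracks
                      if tr.at(t) is not None and tr.at(t + 1) is not None]
        ended = [tr for tr in tracks if tr.last_frame == t]
        started = [tr for tr in tracks if tr.first_frame == t + 1]
        # candidate parent pairs: both end at t, or one ends and one continues
        pairs = []
        for i, a in enumerate(ended):
            for b in ended[i + 1:]:
                for child in started:
                    pairs.append((a, b, child))
            for b in continuing:
                pairs.append((a, b, b))
        for a, b, child_tr in pairs:
            pa, pb = a.at(t), b.at(t)
            child = child_tr.at(t + 1)
            va, vb = pa.lamination_volume, pb.lamination_volume
            vc = child.lamination_volume
            ratio = vc / (va + vb)
            if not conservation_window[0] <= ratio <= conservation_window[1]:
                continue
            ca = np.asarray(pa.centroid)
            cb = np.asarray(pb.centroid)
            cc = np.asarray(child.centroid)
            mid = (ca * va + cb * vb) / (va + vb)
            if np.linalg.norm(cc - mid) > centroid_gate:
                continue
            delta = cb - ca
            norm = np.linalg.norm(delta)
            axis = tuple(delta / norm) if norm > 0 else (1.0, 0.0, 0.0)
            ma = pa.marker_mean if np.isfinite(pa.marker_mean) else 0.0
            mb = pb.marker_mean if np.isfinite(pb.marker_mean) else 0.0
            mc = child.marker_mean if np.isfinite(child.marker_mean) else 0.0
            top = max(ma, mb)
            dilution = mc / top if top > 0 else math.nan
            events.append(FusionEvent(
                frame=t, parent_ids=(a.id, b.id), child_id=child_tr.id,
                conservation_ratio=float(ratio), dilution_ratio=float(dilution),
                axis=axis,
            ))
    return events


def events_to_table(events) -> pd.DataFrame:
    rows = [{
        "frame": e.frame,
        "parent_id_1": e.parent_ids[0],
        "parent_id_2": e.parent_ids[1],
        "child_id": e.child_id,
        "conservation_ratio": e.conservation_ratio,
        "dilution_ratio": e.dilution_ratio,
        "axis_z": e.axis[0],
        "axis_y": e.axis[1],
        "axis_x": e.axis[2],
    } for e in events]
    return pd.DataFrame(rows, columns=[
        "frame", "parent_id_1", "parent_id_2", "child_id",
        "conservation_ratio", "dilution_ratio", "axis_z", "axis_y", "axis_x",
    ])


def plot_size_distribution(sd: SizeDistribution, path) -> None:
    """Save a bar plot of a granule volume histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    widths = np.diff(sd.bin_edges)
    ax.bar(sd.bin_edges[:-1], sd.counts, width=widths, align="edge",
           edgecolor="k", linewidth=0.5)
    ax.set_xlabel("SG volume (μm³)")
    ax.set_ylabel("count")
    ax.set_title(f"n = {sd.n}, median {sd.median:.2f} μm³")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
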