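"""Calibrated image-stack and result-table I/O.

Stacks are carried in memory as :class:`VoxelStack` — a float array indexed
``(channel, z, y, x)`` with physical voxel dimensions in micrometres — and on
disk as OME-TIFF with the calibration embedded in the metadata.  Organelle
inventories are flat CSV tables with a fixed header.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

#: Fixed column order of the organelle inventory CSV.
OBJECT_TABLE_COLUMNS = [
    "id",
    "class",
    "volume_lamination_um3",
    "volume_voxel_um3",
    "equivalent_diameter_um",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "z_extent_um",
    "max_lateral_extent_um",
    "elongation",
    "n_contours",
    "truncated",
    "marker_mean",
    "marker_positive",
]


@dataclass
class VoxelStack:
    """A multichannel 3D intensity grid with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(C, Z, Y, X)`` (a 3D array is promoted to one
        channel).  Stored as float32; values must be nonnegative.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel_names
        One name per channel, e.g. ``["GFP", "marker"]``.
    time_index
        Optional frame number for time-lapse series.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)
    time_index: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={arr.ndim}")
        if arr.size and arr.min() < 0:
            raise ValueError("intensities must be nonnegative")
        self.data = arr
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {vs}")
        self.voxel_size = vs
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(arr.shape[0])]
        if len(self.channel_names) != arr.shape[0]:
            raise ValueError("channel_names length must match channel count")

    # -- convenience accessors -------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a ``(Z, Y, X)`` view."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"no channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.data[idx]

    def with_channel(self, name_or_index: str | int, new: np.ndarray) -> "VoxelStack":
        """Return a copy with one channel replaced."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        data = self.data.copy()
        data[idx] = np.clip(np.asarray(new, dtype=np.float32), 0.0, None)
        return VoxelStack(data, self.voxel_size, list(self.channel_names), self.time_index)


def write_stack(stack: VoxelStack, path, dtype=np.uint16) -> None:
    """Write a stack as OME-TIFF with voxel size in the metadata.

    Intensities are rounded to 16-bit unsigned by default (the on-disk
    convention); pass ``dtype=np.float32`` to keep continuous values, e.g.
    for deconvolved output.
    """
    arr = stack.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
    else:
        arr = arr.astype(dtype)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        arr,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _ome_calibration(ome_xml: str):
    """Extract ((dz, dy, dx), channel names) from OME-XML; sizes may be None."""
    root = ET.fromstring(ome_xml)
    pixels = None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            pixels = el
            break
    if pixels is None:
        return None, None
    get = pixels.attrib.get
    try:
        vs = (
            float(get("PhysicalSizeZ")),
            float(get("PhysicalSizeY")),
            float(get("PhysicalSizeX")),
        )
    except (TypeError, ValueError):
        vs = None
    names = [
        el.attrib.get("Name", f"ch{i}")
        for i, el in enumerate(e for e in pixels.iter() if e.tag.endswith("Channel"))
    ]
    return vs, names or None


def read_stack(path, voxel_size=None, channel_names=None) -> VoxelStack:
    """Read a TIFF / OME-TIFF stack into a calibrated :class:`VoxelStack`.

    Calibration is taken from the OME metadata; ``voxel_size`` overrides it
    and is required for plain TIFFs without physical-size metadata.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
            meta_vs = meta_names = None
            if tf.ome_metadata:
                meta_vs, meta_names = _ome_calibration(tf.ome_metadata)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise ValueError(f"cannot read image stack from {path}: {exc}") from exc

    # normalise axis order to CZYX; unlabelled page axes are z-slices
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if "T" in axes:
        i = axes.index("T")
        if arr.shape[i] != 1:
            raise ValueError("multi-timepoint series: read frames individually")
        arr = np.take(arr, 0, axis=i)
        axes = axes.replace("T", "")
    if arr.ndim == 2:
        arr = arr[None, None]
        axes = "CZYX"
    elif arr.ndim == 3:
        if "C" in axes and "Z" not in axes:
            order = [axes.index(a) for a in "CYX"]
            arr = np.transpose(arr, order)[:, None]
        else:
            arr = arr[None]
        axes = "CZYX"
    elif arr.ndim == 4:
        order = [axes.index(a) for a in "CZYX"]
        arr = np.transpose(arr, order)
    else:
        raise ValueError(f"unsupported stack dimensionality {arr.shape}")

    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        raise ValueError(
            f"{path} carries no pixel-size metadata; pass voxel_size=(dz, dy, dx)"
        )
    names = list(channel_names) if channel_names else (meta_names or [])
    return VoxelStack(arr.astype(np.float32), tuple(vs), names)


def write_objects_table(table: pd.DataFrame, path) -> None:
    """Write an organelle inventory CSV with the fixed header, sorted by id.

    Raises
    ------
    ValueError
        If ids are duplicated or required columns are missing.
    """
    missing = [c for c in OBJECT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"object table missing columns: {missing}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate object ids: {dupes}")
    out = table[OBJECT_TABLE_COLUMNS].sort_values("id").reset_index(drop=True)
    out.to_csv(path, index=False, float_format="%.6g")


def read_objects_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
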