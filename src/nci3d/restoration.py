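"""Image restoration: Richardson–Lucy deconvolution and background levels.

Confocal stacks are blurred by an anisotropic point spread function (PSF)
that stretches small objects along z and fills negatively stained voids
with out-of-focus light.  Richardson–Lucy (RL) deconvolution with a known
parametric PSF restores contrast and edge sharpness while conserving total
intensity — the property the downstream relative-intensity contour rule
relies on.  The cytoplasmic reference level (the "100%" of the contour
rule) is estimated robustly from the cell interior with voids excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter  # noqa: F401  (re-export convenience)
from scipy.signal import fftconvolve

from .imageio import VoxelStack

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PSFModel:
    """Parametric (Gaussian) or measured 3D point spread function.

    Gaussian defaults — lateral FWHM 0.25 μm, axial FWHM 0.6 μm — are
    typical of a 1.4 NA oil objective at GFP wavelengths.
    """

    kind: str = "gaussian"
    fwhm_lateral: float = 0.25
    fwhm_axial: float = 0.60
    kernel: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.fwhm_lateral <= 0 or self.fwhm_axial <= 0:
                raise ValueError("PSF FWHM must be positive")
        elif self.kind in ("measured", "delta"):
            pass
        else:
            raise ValueError(f"unknown PSF kind {self.kind!r}")

    @classmethod
    def gaussian(cls, fwhm_lateral: float = 0.25, fwhm_axial: float = 0.60):
        return cls(kind="gaussian", fwhm_lateral=fwhm_lateral,
                   fwhm_axial=fwhm_axial)

    @classmethod
    def delta(cls):
        """Identity PSF (no blur) — useful for noiseless phantoms."""
        return cls(kind="delta")

    @classmethod
    def from_kernel(cls, kernel: np.ndarray):
        k = np.asarray(kernel, dtype=np.float64)
        if k.ndim != 3:
            raise ValueError("measured kernel must be 3D")
        if k.min() < 0:
            raise ValueError("kernel must be nonnegative")
        s = k.sum()
        if abs(s - 1.0) > 1e-6:
            if s <= 0:
                raise ValueError("kernel must have positive mass")
            k = k / s
        return cls(kind="measured", kernel=k)

    def sigmas(self) -> tuple[float, float]:
        """(sigma_axial, sigma_lateral) in μm."""
        return (self.fwhm_axial * FWHM_TO_SIGMA,
                self.fwhm_lateral * FWHM_TO_SIGMA)

    def kernel_for(self, voxel_size) -> np.ndarray:
        """Sample the PSF on the voxel grid; normalised to sum 1."""
        if self.kind == "delta":
            return np.ones((1, 1, 1))
        if self.kind == "measured":
            return self.kernel
        dz, dy, dx = voxel_size
        sz, sxy = self.sigmas()
        axes = []
        for sigma, d in ((sz, dz), (sxy, dy), (sxy, dx)):
            half = max(1, int(np.ceil(4.0 * sigma / d)))
            x = np.arange(-half, half + 1) * d
            axes.append(np.exp(-0.5 * (x / sigma) ** 2))
        k = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        return k / k.sum()


def _rl_iterate(observed: np.ndarray, kernel: np.ndarray, n_iter: int,
                accelerate: bool = True, eps: float = 1e-12,
                x0: np.ndarray | None = None) -> np.ndarray:
    """Richardson–Lucy multiplicative updates, optionally with
    Biggs–Andrews vector extrapolation.

    The acceleration predicts each iterate from the direction of the two
    previous update steps, giving roughly the restoration of several times
    as many plain iterations — the device used by commercial constrained
    iterative packages.  With ``accelerate=False`` this is the textbook
    update ``x ← x · (K' ⊗ (obs / (K ⊗ x)))``.
    """
    mirror = kernel[::-1, ::-1, ::-1]
    x = observed.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    x_prev = None
    g_prev = None
    g_prev2 = None
    for _ in range(n_iter):
        if accelerate and g_prev is not None and g_prev2 is not None:
            denom = float(np.sum(g_prev2 * g_prev2))
            alpha = float(np.sum(g_prev * g_prev2)) / denom if denom > 0 else 0.0
            alpha = min(max(alpha, 0.0), 0.999)
            y = x + alpha * (x - x_prev)
            np.clip(y, 0.0, None, out=y)
        else:
            y = x
        conv = fftconvolve(y, kernel, mode="same")
        relative = observed / np.maximum(conv, eps)
        x_new = y * fftconvolve(relative, mirror, mode="same")
        np.clip(x_new, 0.0, None, out=x_new)
        g_prev2 = g_prev
        g_prev = x_new - y
        x_prev = x
        x = x_new
    return x


def deconvolve_rl(stack: VoxelStack, psf: PSFModel, iterations: int = 30,
                  channel: str | int = 0, accelerate: bool = False) -> VoxelStack:
    """Richardson–Lucy deconvolution of one channel.

    The channel is reflect-padded by half a kernel extent so edge voxels do
    not darken, deconvolved for ``iterations`` multiplicative updates, and
    cropped back.  Output is nonnegative and conserves total intensity to
    within ~1%.  Biggs–Andrews acceleration is available but off by
    default: on photon-limited data it amplifies shot noise into deep
    spurious dips faster than it sharpens the axial edge.

    Raises
    ------
    ValueError
        If ``iterations < 1`` or the channel contains non-finite voxels.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    img = np.asarray(stack.channel(channel), dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite voxels in input")
    kernel = psf.kernel_for(stack.voxel_size)
    if kernel.size == 1:
        return stack.with_channel(channel, img)
    pad = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(img, pad, mode="reflect")
    # scale into O(1) range for numerical headroom, undo afterwards
    scale = max(padded.max(), 1e-12)
    est = _rl_iterate(padded / scale, kernel, int(iterations),
                      accelerate=accelerate)
    est = est * scale
    crop = tuple(slice(p[0], est.shape[i] - p[1]) for i, p in enumerate(pad))
    out = np.clip(est[crop], 0.0, None)
    return stack.with_channel(channel, out)


@dataclass(frozen=True)
class CytoplasmStats:
    """Robust reference level of the fluorescent cytoplasm."""

    median: float
    robust_sd: float  # 1.4826 * MAD
    n_voxels: int


def estimate_cytoplasm_level(stack: VoxelStack, cell_mask: np.ndarray,
                             channel: str | int = 0,
                             exclude_fraction: float = 0.5,
                             n_iter: int = 2) -> CytoplasmStats:
    """Median / robust SD of the cytoplasmic GFP level inside a mask.

    Voids bias a plain median downward, so the estimate is iterated:
    voxels below ``exclude_fraction`` of the current median are excluded
    and the statistics recomputed.
    """
    img = stack.channel(channel)
    mask = np.asarray(cell_mask, dtype=bool)
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("empty cell mask")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("masked region has no signal")
    for _ in range(n_iter):
        keep = vals >= exclude_fraction * med
        if not keep.any():
            break
        vals = vals[keep]
        med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return CytoplasmStats(median=med, robust_sd=1.4826 * mad, n_voxels=vals.size)
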