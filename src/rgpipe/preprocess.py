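"""Intensity normalization, derived channels, and lesion-image cutting.

Two normalization dialects feed the handcrafted radiomic branch:

* ``radiomics_clip`` — the top 0.1% of the intensity histogram is treated as
  high-signal noise; the surviving 99.9% of the range is reallocated linearly
  to ``n_levels`` (default 256) gray levels, with the flagged voxels pinned to
  the top level so the grid stays dense.  Used for T1W, GdT1W and FLAIR.
* ``radiomics_fullrange`` — 100% of the data range reallocated to 256 levels,
  no deletion.  Used for T2W.

The convolutional branch uses ``cnn_percentile``: the 2.5th and 97.5th
percentiles of the volume become 0 and 1, values outside are clipped.

Derived channels: ``T2Edge`` (per-slice Prewitt gradient magnitude of the
normalized T2W volume) and ``Gdzscore`` (brain-masked z-score of the voxelwise
GdT1W - T1W difference, a simple voxelwise contrast-enhancement measure;
pluggable via the ``gdzscore_strategy`` hook).

Registration is out of scope: cohorts are assumed pre-aligned, and
``register`` is an identity hook kept so real, unaligned data has a seam to
plug a registration tool into.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import convolve1d
from skimage.transform import resize

from .core import MRVolume, VOIMask

DIALECTS = ("radiomics_clip", "radiomics_fullrange", "cnn_percentile")

#: Dialect used per acquired sequence in the radiomic branch.
RADIOMICS_DIALECT = {
    "T1W": "radiomics_clip",
    "GdT1W": "radiomics_clip",
    "FLAIR": "radiomics_clip",
    "T2W": "radiomics_fullrange",
}

LESION_IMAGE_SIZE = 243


@dataclass
class NormalizationParams:
    dialect: str
    n_levels: int = 256

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass
class LesionImage:
    """The 243x243 resized crop of the VOI bounding box on its center slice."""

    pixels: np.ndarray
    patient_id: str
    sequence: str
    slice_index: int
    source_bbox: tuple[int, int, int, int]  # (x0, x1, y0, y1), half-open

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (LESION_IMAGE_SIZE, LESION_IMAGE_SIZE):
            raise ValueError("lesion image must be 243x243")


def flag_noise(volume: MRVolume) -> np.ndarray:
    """Boolean mask of the top-0.1% high-signal-noise voxels (clip dialect)."""
    thr = np.quantile(volume.data, 0.999)
    return volume.data > thr


def _quantize(data: np.ndarray, lo: float, hi: float, n_levels: int) -> np.ndarray:
    if hi <= lo:
        # Constant (or degenerate) range: everything maps to level 0.
        return np.zeros_like(data, dtype=np.float32)
    levels = np.floor((data - lo) * n_levels / (hi - lo))
    return np.clip(levels, 0, n_levels - 1).astype(np.float32)


def normalize_volume(volume: MRVolume, params: NormalizationParams) -> MRVolume:
    """Apply one normalization dialect; monotone in the input intensities."""
    data = np.asarray(volume.data, dtype=np.float64)
    n = params.n_levels
    if params.dialect == "radiomics_fullrange":
        out = _quantize(data, data.min(), data.max(), n)
    elif params.dialect == "radiomics_clip":
        thr = np.quantile(data, 0.999)
        out = _quantize(data, data.min(), thr, n)
        out[data > thr] = n - 1  # deleted voxels pinned to the top level
    else:  # cnn_percentile
        lo, hi = np.quantile(data, [0.025, 0.975])
        if hi <= lo:
            out = np.zeros_like(data, dtype=np.float32)
        else:
            out = np.clip((data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    return MRVolume(out, volume.spacing, volume.sequence)


def t2edge(t2: MRVolume) -> MRVolume:
    """Per-axial-slice 2D Prewitt gradient magnitude of the T2W volume.

    Each axial slice (axes x, y) is convolved with the 3x3 Prewitt kernels;
    image borders use replicate padding.  Slices are independent: no gradient
    component crosses the slice axis.
    """
    data = np.asarray(t2.data, dtype=np.float64)
    deriv = np.array([-1.0, 0.0, 1.0])
    smooth = np.array([1.0, 1.0, 1.0])
    gx = convolve1d(data, deriv, axis=0, mode="nearest")
    gx = convolve1d(gx, smooth, axis=1, mode="nearest")
    gy = convolve1d(data, deriv, axis=1, mode="nearest")
    gy = convolve1d(gy, smooth, axis=0, mode="nearest")
    return MRVolume(np.sqrt(gx**2 + gy**2), t2.spacing, "T2Edge")


def gdzscore_difference(t1: np.ndarray, gdt1: np.ndarray, brain: np.ndarray):
    """Default contrast-enhancement strategy: z-score of the Gd-T1 difference.

    mu and sigma are the mean and SD of the voxelwise difference within the
    brain mask.  Returns the z-scored difference field (zero everywhere when
    sigma is zero).
    """
    diff = gdt1 - t1
    mu = diff[brain].mean()
    sd = diff[brain].std()
    if sd == 0:
        warnings.warn("gdzscore: zero-variance difference field, returning zeros")
        return np.zeros_like(diff)
    return (diff - mu) / sd


def gdzscore(
    t1: MRVolume,
    gdt1: MRVolume,
    brain_mask: VOIMask | np.ndarray | None = None,
    strategy: Callable[..., np.ndarray] = gdzscore_difference,
) -> MRVolume:
    """Voxelwise contrast-enhancement z-score channel from T1W and GdT1W."""
    if t1.data.shape != gdt1.data.shape:
        raise ValueError("T1W and GdT1W volumes must be aligned")
    if brain_mask is None:
        brain = np.ones(t1.data.shape, dtype=bool)
    else:
        brain = brain_mask.mask if isinstance(brain_mask, VOIMask) else np.asarray(
            brain_mask, dtype=bool
        )
    out = strategy(
        np.asarray(t1.data, dtype=np.float64),
        np.asarray(gdt1.data, dtype=np.float64),
        brain,
    )
    return MRVolume(out, t1.spacing, "Gdzscore")


def voi_center_slice(voi: VOIMask, axial_axis: int = 2) -> int:
    """Middle occupied slice of the VOI along the axial axis, ties broken low."""
    occupied = np.unique(np.nonzero(voi.mask)[axial_axis])
    if occupied.size == 0:
        raise ValueError("VOI is empty")
    return int((occupied.min() + occupied.max()) // 2)


def cut_lesion_image(
    volume: MRVolume,
    voi: VOIMask,
    patient_id: str = "",
    axial_axis: int = 2,
) -> LesionImage:
    """Cut the VOI bounding box on the VOI's center axial slice, resize to 243x243.

    The crop is the tight 2D bounding box of the VOI on that slice, bilinearly
    resampled to 243x243 regardless of aspect ratio (each lesion is a
    different size).
    """
    if not voi.mask.any():
        raise ValueError("VOI is empty")
    if volume.data.shape != voi.mask.shape:
        raise ValueError("volume and VOI shapes differ")
    z = voi_center_slice(voi, axial_axis)
    sl = [slice(None)] * 3
    sl[axial_axis] = z
    plane = volume.data[tuple(sl)]
    mask2d = voi.mask[tuple(sl)]
    xs, ys = np.nonzero(mask2d)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    crop = np.asarray(plane[x0:x1, y0:y1], dtype=np.float64)
    pixels = resize(
        crop,
        (LESION_IMAGE_SIZE, LESION_IMAGE_SIZE),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return LesionImage(pixels, patient_id, volume.sequence, z, (x0, x1, y0, y1))


def register(volume: MRVolume, reference: MRVolume | None = None) -> MRVolume:
    """Identity registration hook (synthetic cohorts are generated aligned)."""
    return volume
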