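"""Conventional radiomic features: first-order histogram, shape, location.

The default registry produces 61 radiomic values + 3 location values per
patient: 9 first-order statistics on each of 6 image channels (the four
acquired sequences plus the derived T2Edge and Gdzscore channels, all
quantized to 256 gray levels), 7 shape descriptors of the lesion VOI, and the
VOI weight-center coordinates in world (mm) space.  The registry is
declarative so an alternative feature list can be dropped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .core import FeatureVector, MRVolume, PatientRecord, VOIMask
from .preprocess import (
    RADIOMICS_DIALECT,
    NormalizationParams,
    gdzscore,
    normalize_volume,
    t2edge,
)

RadiomicFeatureSet = FeatureVector

FIRST_ORDER_STATS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "median",
    "p10",
    "p90",
    "entropy",
    "uniformity",
)

DEFAULT_CHANNELS = ("T1W", "T2W", "GdT1W", "FLAIR", "T2Edge", "Gdzscore")

SHAPE_FEATURES = (
    "volume_ml",
    "surface_area_mm2",
    "sphericity",
    "max_diameter_mm",
    "elongation",
    "flatness",
    "surface_to_volume",
)

LOCATION_FEATURES = ("location_x", "location_y", "location_z")


def first_order_features(
    volume: MRVolume, voi: VOIMask, n_levels: int = 256
) -> dict[str, float]:
    """First-order histogram statistics over the in-VOI voxels.

    The volume is expected to hold integer gray levels in [0, n_levels).
    Moment-based statistics use population (biased) estimators; kurtosis is
    the Pearson (non-excess) form.  Degenerate regions (fewer than two voxels
    or zero spread) have their spread-dependent statistics flagged as 0.
    """
    values = np.asarray(volume.data[voi.mask], dtype=np.float64)
    if values.size == 0:
        raise ValueError("VOI is empty")
    out: dict[str, float] = {}
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    out["mean"] = mean
    out["median"] = float(np.median(values))
    out["p10"] = float(np.percentile(values, 10))
    out["p90"] = float(np.percentile(values, 90))
    if values.size < 2 or sd == 0:
        if values.size < 2:
            warnings.warn("VOI has <2 voxels; spread statistics flagged as 0")
        out["sd"] = 0.0
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        z = (values - mean) / sd
        out["sd"] = sd
        out["skewness"] = float((z**3).mean())
        out["kurtosis"] = float((z**4).mean())
    hist, _ = np.histogram(values, bins=np.arange(n_levels + 1))
    p = hist[hist > 0] / values.size
    out["entropy"] = float(-(p * np.log2(p)).sum())
    out["uniformity"] = float((p**2).sum())
    return out


def _surface_mesh_area(mask: np.ndarray, spacing, smooth_sigma: float = 0.5) -> float:
    # Marching cubes on a lightly smoothed mask: a raw binary isosurface
    # overestimates curved areas by a staircase factor.  Tiny masks whose
    # smoothed peak falls below the 0.5 level fall back to the binary surface.
    padded = np.pad(mask, 2).astype(np.float64)
    smoothed = gaussian_filter(padded, smooth_sigma)
    level_field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = marching_cubes(level_field, 0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def _max_diameter(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = coords_mm
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # flat/degenerate cloud: brute force below
    return float(pdist(pts).max())


def shape_features(voi: VOIMask, spacing) -> dict[str, float]:
    """Shape descriptors of the lesion mask in physical units.

    Sphericity is pi^(1/3) (6V)^(2/3) / A with V the voxel-count volume and A
    the marching-cubes mesh surface area.  Elongation and flatness are
    sqrt(l2/l1) and sqrt(l3/l1) of the principal-axis eigenvalues of the voxel
    coordinate cloud (1.0 for degenerate/isotropic masks).
    """
    mask = voi.mask
    if not mask.any():
        raise ValueError("VOI is empty")
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    n_vox = int(mask.sum())
    volume_mm3 = n_vox * voxel_vol
    area = _surface_mesh_area(mask, spacing)
    sphericity = np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area

    # boundary voxels suffice for the maximum 3D diameter
    boundary = mask & ~binary_erosion(mask)
    coords = np.argwhere(boundary) * spacing
    diameter = _max_diameter(coords)

    all_coords = np.argwhere(mask) * spacing
    if len(all_coords) < 2:
        elongation = flatness = 1.0
    else:
        cov = np.cov(all_coords.T)
        eig = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
        if eig[0] <= 0:
            elongation = flatness = 1.0
        else:
            elongation = float(np.sqrt(eig[1] / eig[0]))
            flatness = float(np.sqrt(eig[2] / eig[0]))
    return {
        "volume_ml": volume_mm3 / 1000.0,
        "surface_area_mm2": area,
        "sphericity": float(sphericity),
        "max_diameter_mm": diameter,
        "elongation": elongation,
        "flatness": flatness,
        "surface_to_volume": area / volume_mm3,
    }


def location_features(voi: VOIMask, spacing) -> dict[str, float]:
    """Weight center of the VOI in world coordinates (mm), 3 values."""
    if not voi.mask.any():
        raise ValueError("VOI is empty")
    spacing = np.asarray(spacing, dtype=float)
    center = np.argwhere(voi.mask).mean(axis=0) * spacing
    return dict(zip(LOCATION_FEATURES, (float(c) for c in center)))


@dataclass
class RadiomicsRegistry:
    """Declarative definition of the radiomic feature vector.

    The default (9 first-order stats x 6 channels + 7 shape + 3 location = 64)
    matches the printed feature count of the analysis this pipeline
    re-implements; a different composition can be configured if an authentic
    feature list is available.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    stats: tuple[str, ...] = FIRST_ORDER_STATS
    include_shape: bool = True
    include_location: bool = True
    n_levels: int = 256

    def names(self) -> list[str]:
        names = [f"{ch}_{st}" for ch in self.channels for st in self.stats]
        if self.include_shape:
            names += list(SHAPE_FEATURES)
        if self.include_location:
            names += list(LOCATION_FEATURES)
        return names


def derived_channels(patient: PatientRecord, n_levels: int = 256) -> dict[str, MRVolume]:
    """Quantized image channels for the radiomic branch of one patient.

    The four acquired sequences are quantized with their per-sequence dialect;
    T2Edge and Gdzscore are built from the quantized inputs and re-quantized
    (full range) so histogram features see discrete levels.
    """
    fullrange = NormalizationParams("radiomics_fullrange", n_levels)
    channels: dict[str, MRVolume] = {}
    for seq, vol in ((s, patient.volumes[s]) for s in RADIOMICS_DIALECT):
        channels[seq] = normalize_volume(
            vol, NormalizationParams(RADIOMICS_DIALECT[seq], n_levels)
        )
    channels["T2Edge"] = normalize_volume(t2edge(channels["T2W"]), fullrange)
    channels["Gdzscore"] = normalize_volume(
        gdzscore(channels["T1W"], channels["GdT1W"]), fullrange
    )
    return channels


def compute_radiomic_features(
    patient: PatientRecord, registry: RadiomicsRegistry | None = None
) -> RadiomicFeatureSet:
    """Full radiomic feature vector for one patient (default length 64)."""
    registry = registry or RadiomicsRegistry()
    channels = derived_channels(patient, registry.n_levels)
    spacing = patient.volumes["T2W"].spacing
    values: list[float] = []
    for ch in registry.channels:
        fo = first_order_features(channels[ch], patient.lesion_voi, registry.n_levels)
        values += [fo[st] for st in registry.stats]
    if registry.include_shape:
        sf = shape_features(patient.lesion_voi, spacing)
        values += [sf[k] for k in SHAPE_FEATURES]
    if registry.include_location:
        lf = location_features(patient.lesion_voi, spacing)
        values += [lf[k] for k in LOCATION_FEATURES]
    return FeatureVector(registry.names(), np.asarray(values), patient.patient_id)
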