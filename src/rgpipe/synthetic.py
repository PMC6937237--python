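"""Synthetic multi-sequence MR cohort generator.

Real lower-grade glioma imaging cohorts are not redistributable, so the
pipeline ships a generator that emulates their structure: three molecular
subtypes (IDH wild type, IDH+pTERT co-mutated, IDH mutant / pTERT wild type)
with class-dependent lesion texture and age distributions, four pre-aligned MR
sequences per patient, an ellipsoidal lesion VOI, and a sagittally mirrored
"normal tissue" VOI that is occasionally impossible to place without
overlapping the lesion (those patients are flagged as excluded, mimicking the
midline-crossing exclusions seen in real cohorts).

Lesion texture model
--------------------
The lesion interior is a Gaussian random field: white noise convolved with an
isotropic Gaussian kernel, rescaled to a target standard deviation (contrast)
and shifted by a class-specific mean offset.  Its two knobs — contrast and
correlation length — move first-order histogram features and convolutional
texture features alike.  All class-dependent deltas are proportional to
``texture_effect`` (and ``age_effect`` for age), so setting both to zero
yields an exact null cohort in which genotype is independent of every image
and clinical covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    GENOTYPES,
    SCANNERS,
    SEQUENCES,
    MRVolume,
    PatientRecord,
    VOIMask,
    child_seed,
)

# Per-sequence background intensity and additive lesion mean shift, in
# arbitrary synthetic intensity units.  T2W/FLAIR lesions are hyperintense,
# T1W hypointense, GdT1W mildly enhancing.
_SEQ_BACKGROUND = {"T1W": 90.0, "T2W": 110.0, "GdT1W": 95.0, "FLAIR": 100.0}
_SEQ_LESION_SHIFT = {"T1W": -15.0, "T2W": 30.0, "GdT1W": 10.0, "FLAIR": 25.0}

# Direction of the class effect for (mean, contrast, correlation length),
# one scalar per genotype in GENOTYPES order.  Scaled by texture_effect.
_CLASS_DIRECTION = {"IDHwt": 1.0, "IDHmut_pTERTmut": 0.0, "IDHmut_pTERTwt": -1.0}

_BASE_CONTRAST = 8.0       # lesion GRF standard deviation, intensity units
_BASE_CORR_LEN = 2.0       # lesion GRF correlation length, voxels
_MEAN_PER_EFFECT = 2.0     # lesion mean shift per unit texture_effect
_REL_PER_EFFECT = 0.12     # relative contrast / corr-length shift per unit
_AGE_BASE_MEAN = 46.0      # years; IDH wild type skews older
_AGE_SD = 11.0
_BACKGROUND_TEXTURE_SD = 4.0
_BACKGROUND_CORR_LEN = 1.5


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``texture_effect`` and ``age_effect`` are the between-class effect sizes;
    both at zero define the null cohort.  ``scanner_class_association``
    (default 0, off) biases scanner assignment by genotype so the cohort
    homogeneity chi-squared test can be exercised under the alternative.
    """

    n_patients: int = 164
    class_proportions: tuple[float, float, float] = (56 / 164, 54 / 164, 54 / 164)
    texture_effect: float = 1.0
    age_effect: float = 5.0
    volume_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_radius_range: tuple[float, float] = (8.0, 16.0)
    noise_sd: float = 1.0
    scanner_class_association: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("class_proportions must be a 3-vector summing to 1")
        if len(self.volume_shape) != 3 or any(int(s) <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must satisfy 0 < lo <= hi")
        if self.texture_effect < 0 or self.age_effect < 0 or self.noise_sd < 0:
            raise ValueError("effects and noise_sd must be nonnegative")


def mirror_voi(lesion_voi: VOIMask, midline_axis: int = 0) -> Optional[VOIMask]:
    """Mirror a lesion VOI across the volume midline to define normal tissue.

    Returns a ``role='normal'`` mask, or ``None`` when the mirrored mask
    overlaps the lesion by at least one voxel (midline-crossing lesion), in
    which case the patient is excluded from the lesion-vs-normal analysis.
    """
    if not lesion_voi.mask.any():
        raise ValueError("lesion VOI is empty")
    if not (0 <= midline_axis < lesion_voi.mask.ndim):
        raise ValueError(f"midline_axis {midline_axis} out of range")
    mirrored = np.flip(lesion_voi.mask, axis=midline_axis)
    if np.any(mirrored & lesion_voi.mask):
        return None
    return VOIMask(mirrored, role="normal")


def _ellipsoid_mask(shape, center, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _gaussian_random_field(rng, shape, corr_len_vox, sd) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), sigma=corr_len_vox)
    s = field.std()
    if s > 0:
        field *= sd / s
    return field


def _generate_patient(i: int, genotype: str, cfg: SyntheticConfig) -> PatientRecord:
    rng = np.random.default_rng(child_seed(cfg.seed, f"patient:{i}"))
    shape = tuple(int(s) for s in cfg.volume_shape)
    spacing = cfg.voxel_spacing
    d = _CLASS_DIRECTION[genotype] * cfg.texture_effect

    # Clinical covariates.
    age_mean = _AGE_BASE_MEAN + _CLASS_DIRECTION[genotype] * cfg.age_effect
    age = float(np.clip(rng.normal(age_mean, _AGE_SD), 20.0, 85.0))
    p_15 = np.clip(
        0.55 + cfg.scanner_class_association * _CLASS_DIRECTION[genotype], 0.05, 0.95
    )
    scanner = SCANNERS[0] if rng.random() < p_15 else SCANNERS[1]

    # Lesion geometry: ellipsoid, center drawn across the full width so some
    # lesions cross the sagittal midline (their mirrored VOI then overlaps).
    radii_mm = rng.uniform(*cfg.lesion_radius_range, size=3)
    radii_vox = np.maximum(radii_mm / np.asarray(spacing), 1.0)
    center = [
        rng.uniform(r + 1, s - r - 2) if s - r - 2 > r + 1 else (s - 1) / 2
        for s, r in zip(shape, radii_vox)
    ]
    lesion = _ellipsoid_mask(shape, center, radii_vox)
    if not lesion.any():  # degenerate tiny volume: force one voxel
        lesion[tuple(int(round(c)) for c in center)] = True
    lesion_voi = VOIMask(lesion, role="lesion")

    # Class-dependent lesion texture parameters.
    mean_shift = _MEAN_PER_EFFECT * d
    contrast = _BASE_CONTRAST * max(1.0 + _REL_PER_EFFECT * d, 0.05)
    corr_len = _BASE_CORR_LEN * max(1.0 + _REL_PER_EFFECT * d, 0.05)

    volumes: dict[str, MRVolume] = {}
    for seq in SEQUENCES:
        bg = _SEQ_BACKGROUND[seq] + _gaussian_random_field(
            rng, shape, _BACKGROUND_CORR_LEN, _BACKGROUND_TEXTURE_SD
        )
        lesion_field = _gaussian_random_field(rng, shape, corr_len, contrast)
        data = bg.copy()
        data[lesion] = (
            _SEQ_BACKGROUND[seq]
            + _SEQ_LESION_SHIFT[seq]
            + mean_shift
            + lesion_field[lesion]
        )
        if cfg.noise_sd > 0:
            data += rng.normal(0.0, cfg.noise_sd, size=shape)
        volumes[seq] = MRVolume(data.astype(np.float32), spacing, seq)

    normal_voi = mirror_voi(lesion_voi, midline_axis=0)
    return PatientRecord(
        patient_id=f"P{i:04d}",
        age=age,
        genotype=genotype,
        scanner=scanner,
        volumes=volumes,
        lesion_voi=lesion_voi,
        normal_voi=normal_voi,
        excluded_from_normal_analysis=normal_voi is None,
    )


def generate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Generate a synthetic cohort; bitwise deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "genotypes"))
    genotypes = rng.choice(
        len(GENOTYPES), size=config.n_patients, p=np.asarray(config.class_proportions)
    )
    return [
        _generate_patient(i, GENOTYPES[g], config) for i, g in enumerate(genotypes)
    ]
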