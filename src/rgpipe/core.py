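"""Core containers shared across the pipeline.

The pipeline operates on aligned 3D MR volumes with a binary lesion volume of
interest (VOI) per patient.  Axes are ordered (x, y, z) with x the left-right
(sagittal) axis and z the slice (axial) axis; world coordinates are voxel index
times spacing in millimetres.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Acquired MR sequences, in the fixed order used for feature concatenation.
SEQUENCES = ("T1W", "T2W", "GdT1W", "FLAIR")

#: Derived image channels added by preprocessing.
DERIVED_SEQUENCES = ("T2Edge", "Gdzscore")

#: Molecular subtype labels: IDH wild type, IDH+pTERT co-mutated,
#: IDH mutant with pTERT wild type.
GENOTYPES = ("IDHwt", "IDHmut_pTERTmut", "IDHmut_pTERTwt")

SCANNERS = ("1.5T", "3.0T")


def child_seed(seed: int, tag: str) -> int:
    """Derive a per-stage seed from a global seed and a string tag.

    Deterministic and documented so every stage of an experiment can be
    reproduced in isolation.  The result is always below 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class MRVolume:
    """A 3D intensity grid with voxel spacing and a sequence tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    sequence: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("MRVolume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("MRVolume data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class VOIMask:
    """Binary 3D mask aligned to a volume; role is 'lesion' or 'normal'."""

    mask: np.ndarray
    role: str = "lesion"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("VOIMask must be 3D")
        if self.role not in ("lesion", "normal"):
            raise ValueError(f"unknown VOI role: {self.role!r}")
        if self.role == "lesion" and not self.mask.any():
            raise ValueError("lesion VOI must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatientRecord:
    """One patient: aligned multi-sequence volumes, VOIs and clinical data."""

    patient_id: str
    age: float
    genotype: str
    scanner: str
    volumes: dict[str, MRVolume]
    lesion_voi: VOIMask
    normal_voi: Optional[VOIMask] = None
    excluded_from_normal_analysis: bool = False

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype: {self.genotype!r}")
        missing = [s for s in SEQUENCES if s not in self.volumes]
        if missing:
            raise ValueError(f"patient {self.patient_id} missing sequences: {missing}")
        if self.excluded_from_normal_analysis != (self.normal_voi is None):
            raise ValueError(
                "excluded_from_normal_analysis must be set exactly when "
                "the mirrored normal VOI is absent"
            )


@dataclass
class FeatureVector:
    """Named, ordered real-valued features for one patient or sample."""

    names: list[str]
    values: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("names and values must be 1D and the same length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
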