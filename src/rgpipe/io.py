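"""On-disk cohort layout: NIfTI volumes/masks plus a clinical CSV.

Layout::

    cohort_dir/
      clinical.csv                  # patient_id, age, genotype, scanner,
                                    # excluded_from_normal_analysis
      P0000/T1W.nii.gz  T2W.nii.gz  GdT1W.nii.gz  FLAIR.nii.gz
            lesion.nii.gz  [normal.nii.gz]
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import SEQUENCES, MRVolume, PatientRecord, VOIMask


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        pdir = out / rec.patient_id
        pdir.mkdir(exist_ok=True)
        for seq, vol in rec.volumes.items():
            img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing))
            nib.save(img, pdir / f"{seq}.nii.gz")
        spacing = rec.volumes["T2W"].spacing
        nib.save(
            nib.Nifti1Image(rec.lesion_voi.mask.astype(np.uint8), _affine(spacing)),
            pdir / "lesion.nii.gz",
        )
        if rec.normal_voi is not None:
            nib.save(
                nib.Nifti1Image(rec.normal_voi.mask.astype(np.uint8), _affine(spacing)),
                pdir / "normal.nii.gz",
            )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "genotype": rec.genotype,
                "scanner": rec.scanner,
                "excluded_from_normal_analysis": rec.excluded_from_normal_analysis,
            }
        )
    pd.DataFrame(rows).to_csv(out / "clinical.csv", index=False)
    return out


def read_cohort(cohort_dir: str | Path) -> list[PatientRecord]:
    root = Path(cohort_dir)
    clinical = pd.read_csv(root / "clinical.csv")
    records = []
    for _, row in clinical.iterrows():
        pdir = root / str(row.patient_id)
        volumes = {}
        for seq in SEQUENCES:
            path = pdir / f"{seq}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"patient {row.patient_id}: missing {seq} volume")
            img = nib.load(path)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            volumes[seq] = MRVolume(np.asanyarray(img.dataobj, dtype=np.float32), spacing, seq)
        lesion_path = pdir / "lesion.nii.gz"
        if not lesion_path.exists():
            raise FileNotFoundError(f"patient {row.patient_id}: missing lesion mask")
        lesion = VOIMask(np.asanyarray(nib.load(lesion_path).dataobj) > 0, "lesion")
        normal = None
        normal_path = pdir / "normal.nii.gz"
        if normal_path.exists():
            normal = VOIMask(np.asanyarray(nib.load(normal_path).dataobj) > 0, "normal")
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                age=float(row.age),
                genotype=str(row.genotype),
                scanner=str(row.scanner),
                volumes=volumes,
                lesion_voi=lesion,
                normal_voi=normal,
                excluded_from_normal_analysis=bool(row.excluded_from_normal_analysis),
            )
        )
    return records
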