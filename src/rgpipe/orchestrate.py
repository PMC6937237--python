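"""End-to-end experiment runner.

Runs the full grid — feature sets (age, radiomics, cnn, all) crossed with the
three genotype tasks — from one config, with a shared fold plan per task so
fold accuracies are paired across feature sets, a shuffled-label chance run,
and the statistics layer (Welch vs chance per feature set; ANOVA with
Tukey-Kramer across feature sets, Bonferroni-corrected over tasks).  A single
global seed fans out to per-stage seeds through ``core.child_seed``, so every
stage is independently reproducible and a re-run is bit-identical apart from
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cnn import NeuronSample, RandomConvExtractor, patient_cnn_matrix, select_layer
from .core import SEQUENCES, PatientRecord, child_seed
from .classify import (
    Sample,
    TASKS,
    ClassificationResult,
    chance_run,
    make_folds,
    nested_cv,
)
from .preprocess import NormalizationParams, cut_lesion_image, normalize_volume
from .radiomics import RadiomicsRegistry, compute_radiomic_features
from .stats import StatReport, anova_tukey, welch_one_tailed
from .synthetic import SyntheticConfig, generate_cohort

FEATURE_SETS = ("age", "radiomics", "cnn", "all")


@dataclass
class ExperimentConfig:
    cohort: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort_dir: Optional[str] = None  # load instead of generating when set
    tasks: tuple[str, ...] = ("three_subtype", "idh", "ptert_in_idh_mut")
    feature_sets: tuple[str, ...] = FEATURE_SETS
    extractor_kind: str = "random_conv"
    extractor_seed: int = 0
    layer: str = "conv5"
    k_neurons: int = 1000
    m_select: int = 4000
    outer_k: int = 10
    inner_k: int = 5
    cost_grid: Optional[tuple[float, ...]] = None
    augment_cnn: bool = True
    n_chance_repeats: int = 1
    seed: int = 0


@dataclass
class ExperimentReport:
    per_task: dict
    layer_selection: Optional[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "per_task": self.per_task,
            "layer_selection": self.layer_selection,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stat_dict(r: StatReport) -> dict:
    return {
        "test": r.test_name,
        "statistic": r.statistic,
        "df": r.df,
        "p": r.p_value,
        "adjusted_p": r.adjusted_p,
        "raw_adjusted_p": r.raw_adjusted_p,
        "pairwise": r.pairwise,
    }


def make_extractor(config: ExperimentConfig):
    if config.extractor_kind == "random_conv":
        return RandomConvExtractor(seed=config.extractor_seed)
    raise ValueError(f"unknown extractor kind {config.extractor_kind!r}")


def validate_cohort(cohort: Sequence[PatientRecord]) -> None:
    """Fail with a named error before any computation if inputs are incomplete."""
    problems = []
    for rec in cohort:
        missing = [s for s in SEQUENCES if s not in rec.volumes]
        if missing:
            problems.append(f"{rec.patient_id}: missing sequences {missing}")
        if not rec.lesion_voi.mask.any():
            problems.append(f"{rec.patient_id}: empty lesion VOI")
    if problems:
        raise ValueError("cohort validation failed: " + "; ".join(problems))


def lesion_images_for(
    rec: PatientRecord, voi=None
) -> dict[str, "LesionImage"]:
    """CNN-branch lesion images: percentile-normalize each sequence, cut VOI."""
    voi = voi if voi is not None else rec.lesion_voi
    params = NormalizationParams("cnn_percentile")
    return {
        seq: cut_lesion_image(
            normalize_volume(rec.volumes[seq], params), voi, rec.patient_id
        )
        for seq in SEQUENCES
    }


def build_feature_samples(
    cohort: Sequence[PatientRecord],
    config: ExperimentConfig,
    feature_sets: Sequence[str] | None = None,
) -> dict[str, dict[str, Sample]]:
    """Per-feature-set map of patient id -> Sample (labels filled per task later)."""
    feature_sets = tuple(feature_sets or config.feature_sets)
    out: dict[str, dict[str, Sample]] = {fs: {} for fs in feature_sets}
    need_radiomics = "radiomics" in feature_sets or "all" in feature_sets
    need_cnn = "cnn" in feature_sets or "all" in feature_sets
    extractor = make_extractor(config) if need_cnn else None
    sample_idx = None
    if need_cnn:
        sample_idx = NeuronSample.draw(
            config.layer,
            extractor.layer_dims[config.layer],
            config.k_neurons,
            child_seed(config.seed, "neurons"),
        )
    registry = RadiomicsRegistry()
    for rec in cohort:
        age_row = np.array([[rec.age]])
        if "age" in feature_sets:
            out["age"][rec.patient_id] = Sample(rec.patient_id, rec.patient_id, None, age_row)
        radio = None
        if need_radiomics:
            radio = compute_radiomic_features(rec, registry).values[None, :]
            if "radiomics" in feature_sets:
                out["radiomics"][rec.patient_id] = Sample(
                    rec.patient_id, rec.patient_id, None, radio
                )
        if need_cnn:
            images = lesion_images_for(rec)
            cnn_mat, center = patient_cnn_matrix(
                images, extractor, config.layer, sample_idx, config.augment_cnn
            )
            if "cnn" in feature_sets:
                out["cnn"][rec.patient_id] = Sample(
                    rec.patient_id, rec.patient_id, None, cnn_mat, center
                )
            if "all" in feature_sets:
                n = cnn_mat.shape[0]
                block = np.hstack(
                    [
                        cnn_mat,
                        np.repeat(radio, n, axis=0),
                        np.repeat(age_row, n, axis=0),
                    ]
                )
                out["all"][rec.patient_id] = Sample(
                    rec.patient_id, rec.patient_id, None, block, center
                )
    return out


def _with_labels(samples: dict[str, Sample], labels: dict[str, object]) -> list[Sample]:
    return [
        Sample(s.uid, s.patient_id, labels[pid], s.matrix, s.center_row)
        for pid, s in samples.items()
        if pid in labels
    ]


def run_task(
    task_name: str,
    cohort: Sequence[PatientRecord],
    feature_samples: dict[str, dict[str, Sample]],
    config: ExperimentConfig,
) -> dict:
    """One genotype task: every feature set on a shared fold plan, plus stats."""
    task = TASKS[task_name]
    in_task = [r for r in cohort if task.in_cohort(r.genotype)]
    labels = {r.patient_id: task.label_map[r.genotype] for r in in_task}
    pids = [r.patient_id for r in in_task]
    plan = make_folds(
        pids,
        [labels[p] for p in pids],
        k=config.outer_k,
        seed=child_seed(config.seed, f"folds:{task_name}"),
        inner_k=config.inner_k,
    )
    cell_results: dict[str, ClassificationResult] = {}
    for fs in config.feature_sets:
        cell_results[fs] = nested_cv(
            _with_labels(feature_samples[fs], labels),
            plan,
            m_select=config.m_select,
            cost_grid=config.cost_grid,
        )
    # chance level is always estimated from the age feature with shuffled labels
    age_samples = [
        Sample(r.patient_id, r.patient_id, labels[r.patient_id], np.array([[r.age]]))
        for r in in_task
    ]
    chance = chance_run(
        age_samples,
        n_repeats=config.n_chance_repeats,
        seed=child_seed(config.seed, f"chance:{task_name}"),
        k=config.outer_k,
        inner_k=config.inner_k,
        cost_grid=config.cost_grid,
    )
    chance_accs = chance.ravel()
    welch = {
        fs: _stat_dict(welch_one_tailed(cell_results[fs].fold_accuracies, chance_accs))
        for fs in config.feature_sets
    }
    anova = None
    if len(config.feature_sets) >= 2:
        anova = _stat_dict(
            anova_tukey(
                [cell_results[fs].fold_accuracies for fs in config.feature_sets],
                n_comparisons=len(config.tasks),
            )
        )
        anova["group_order"] = list(config.feature_sets)
    return {
        "n_patients": len(in_task),
        "per_feature_set": {fs: r.to_dict() for fs, r in cell_results.items()},
        "chance": {
            "fold_accuracies": chance_accs.tolist(),
            "mean_accuracy": float(chance_accs.mean()),
        },
        "welch_vs_chance": welch,
        "anova": anova,
    }


def run_layer_selection(
    cohort: Sequence[PatientRecord], config: ExperimentConfig
) -> dict:
    """Lesion-vs-normal layer-selection experiment on non-excluded patients."""
    extractor = make_extractor(config)
    lesion_imgs, normal_imgs = {}, {}
    for rec in cohort:
        if rec.normal_voi is None:
            continue
        lesion_imgs[rec.patient_id] = lesion_images_for(rec)
        normal_imgs[rec.patient_id] = lesion_images_for(rec, rec.normal_voi)
    best, report = select_layer(
        lesion_imgs,
        normal_imgs,
        extractor,
        k_neurons=config.k_neurons,
        seed=child_seed(config.seed, "layer-selection"),
        outer_k=config.outer_k,
        inner_k=config.inner_k,
        cost_grid=config.cost_grid,
        use_augmentation=config.augment_cnn,
    )
    return {
        "selected_layer": best,
        "n_patients": len(lesion_imgs),
        "n_excluded": sum(1 for r in cohort if r.normal_voi is None),
        "per_layer": report,
    }


def run_experiment(
    config: ExperimentConfig, include_layer_selection: bool = False
) -> ExperimentReport:
    """Execute the full grid and return the report (deterministic under seed)."""
    if config.cohort_dir is not None:
        from .io import read_cohort

        cohort = read_cohort(config.cohort_dir)
    else:
        cohort = generate_cohort(config.cohort)
    validate_cohort(cohort)
    feature_samples = build_feature_samples(cohort, config)
    per_task = {
        t: run_task(t, cohort, feature_samples, config) for t in config.tasks
    }
    layer_sel = run_layer_selection(cohort, config) if include_layer_selection else None
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    provenance = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return ExperimentReport(per_task, layer_sel, provenance)
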