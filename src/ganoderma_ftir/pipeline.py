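"""End-to-end two-track experiment: chemometrics and CNN on one dataset.

``run_experiment`` wires the stages together: generate (or load) spectra ->
preprocessing chain -> track 1 (60/40 split, PCA, PCA-class, OPLS-DA with
permutation test) and track 2 (group A/B half-split, SMOTE to a common
per-class target, CNN k-fold cross-validation, repeated random-segregation
evaluation).  Every stage derives its own seed from the master seed and the
stage name, so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import chemometrics as chem
from .balance import GroupAssignment, SmoteConfig, balance_groups, split_groups
from .cnn import CnnArchitecture, TrainConfig, train_cv
from .dataset import SpectraSet, WavenumberGrid
from .evaluation import random_segregation_test
from .preprocess import PreprocessConfig, run_chain
from .spectra_io import read_spectra_csv, stratified_split
from .synthetic import default_band_library, generate_dataset

__all__ = ["ExperimentConfig", "run_experiment", "stage_seed"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (kept below 2**31)."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ExperimentConfig:
    """Every knob of the two-track experiment in one place."""

    input_csv: str | None = None  # load spectra instead of generating
    use_generator: bool = True
    noise_sd: float = 0.005
    baseline_order: int = 2
    baseline_scale: float = 0.1
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split_fraction: float = 0.6
    n_permutations: int = 100
    pca_components: int = 3
    pca_class_components: int = 2
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    arch: CnnArchitecture | None = None  # input_length filled from the data
    train: TrainConfig = field(default_factory=TrainConfig)
    n_runs: int = 10
    downsample_cnn: int = 2
    master_seed: int = 0

    def validate(self) -> None:
        if not self.use_generator and self.input_csv is None:
            raise ValueError("either enable the generator or provide input_csv")


def _track_chemometrics(spectra: SpectraSet, config: ExperimentConfig) -> dict:
    split = stratified_split(
        spectra, fraction=config.split_fraction, seed=stage_seed(config.master_seed, "split")
    )
    cal = spectra.select_ids(split.calibration_ids)
    val = spectra.select_ids(split.validation_ids)

    pca = chem.fit_pca_nipals(cal.absorbance, n_components=config.pca_components)
    q2 = chem.q2_cross_validation(
        cal.absorbance,
        component_range=range(1, config.pca_components + 1),
        seed=stage_seed(config.master_seed, "pca-cv"),
    )

    class_mats = {c: cal.absorbance[cal.labels == c] for c in cal.classes}
    pca_class = chem.fit_pca_class(class_mats, n_components=config.pca_class_components)
    pc_labels, _, _ = chem.classify_pca_class(pca_class, val.absorbance)
    from .evaluation import confusion_matrix, core_metrics, ovr_counts

    cm_pc = confusion_matrix(val.labels, pc_labels, tuple(cal.classes))
    _, pooled_pc = ovr_counts(cm_pc)
    pc_triple = core_metrics(pooled_pc)

    oplsda = chem.fit_oplsda(
        cal.absorbance, cal.labels, cv_seed=stage_seed(config.master_seed, "oplsda-cv")
    )
    op_labels, _, rmsep = chem.predict_oplsda(oplsda, val.absorbance, true_labels=val.labels)
    cm_op = confusion_matrix(val.labels, op_labels, oplsda.class_order)
    _, pooled_op = ovr_counts(cm_op)
    op_triple = core_metrics(pooled_op)

    perm = chem.permutation_test(
        cal.absorbance,
        cal.labels,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.master_seed, "permutation"),
        n_orthogonal=oplsda.n_orthogonal,
    )

    return {
        "split": {
            "calibration_counts": cal.class_counts(),
            "validation_counts": val.class_counts(),
            "fraction": config.split_fraction,
        },
        "pca": {"r2x_per_component": pca.r2x_per_component.tolist(), "q2_cumulative": q2},
        "pca_class": {
            "r2x": {c: m.r2x_per_component.sum() for c, m in pca_class.submodels.items()},
            "validation": {
                "accuracy": pc_triple[0],
                "sensitivity": pc_triple[1],
                "specificity": pc_triple[2],
                "confusion": cm_pc.counts.tolist(),
            },
        },
        "oplsda": {
            "n_predictive": oplsda.n_predictive,
            "n_orthogonal": oplsda.n_orthogonal,
            "r2x": oplsda.quality.r2x,
            "r2y": oplsda.quality.r2y,
            "q2y": oplsda.quality.q2y,
            "rmsee": oplsda.quality.rmsee,
            "rmsecv": oplsda.quality.rmsecv,
            "rmsep": rmsep,
            "calibration": {
                "accuracy": oplsda.quality.accuracy,
                "sensitivity": oplsda.quality.sensitivity,
                "specificity": oplsda.quality.specificity,
            },
            "validation": {
                "accuracy": op_triple[0],
                "sensitivity": op_triple[1],
                "specificity": op_triple[2],
                "confusion": cm_op.counts.tolist(),
            },
            "permutation": {
                "n_permutations": perm.n_permutations,
                "r2y_intercept": perm.r2y_intercept,
                "q2y_intercept": perm.q2y_intercept,
            },
        },
    }


def _track_cnn(spectra: SpectraSet, config: ExperimentConfig) -> dict:
    assignment = split_groups(spectra, seed=stage_seed(config.master_seed, "groups"))
    smote = SmoteConfig(
        k_neighbors=config.smote.k_neighbors,
        target_per_class=config.smote.target_per_class,
        seed=stage_seed(config.master_seed, "smote"),
    )
    group_a, group_b = balance_groups(spectra, assignment, smote)
    if config.downsample_cnn > 1:
        group_a = group_a.downsample(config.downsample_cnn)
        group_b = group_b.downsample(config.downsample_cnn)

    arch = config.arch or CnnArchitecture(
        n_classes=len(group_a.classes), input_length=group_a.n_points
    )
    if arch.input_length != group_a.n_points:
        arch = CnnArchitecture(
            conv_blocks=arch.conv_blocks,
            dense_units=arch.dense_units,
            n_classes=arch.n_classes,
            input_length=group_a.n_points,
            activation=arch.activation,
            dropout=arch.dropout,
        )
    train = TrainConfig(
        n_folds=config.train.n_folds,
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
        seed=stage_seed(config.master_seed, "cnn"),
        early_stop_patience=config.train.early_stop_patience,
    )
    fold_results = train_cv(group_a, arch, train)
    summary, matrices = random_segregation_test(
        group_a, group_b, arch, train, n_runs=config.n_runs, fold_results=fold_results
    )
    return {
        "cross_validation": {
            "fold_val_accuracy": [r.val_accuracy for r in fold_results],
            "mean_val_accuracy": float(np.mean([r.val_accuracy for r in fold_results])),
        },
        "table1": {
            "raw_counts": spectra.class_counts(),
            "group_a_raw": spectra.select_ids(assignment.group_a_ids).class_counts(),
            "group_b_raw": spectra.select_ids(assignment.group_b_ids).class_counts(),
            "group_a_oversampled": group_a.class_counts(),
            "group_b_oversampled": group_b.class_counts(),
        },
        "random_segregation": {
            "per_run": [m.as_dict() for m in summary.per_run],
            "mean": summary.mean,
            "sd": summary.sd,
            "cv": summary.cv,
            "confusion_matrices": [cm.counts.tolist() for cm in matrices],
        },
    }


def run_experiment(config: ExperimentConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run both tracks and return (and optionally persist) the JSON report."""
    if config is None:
        config = ExperimentConfig()
    config.validate()
    t0 = time.time()

    if config.input_csv is not None:
        spectra = read_spectra_csv(config.input_csv)
        logger.info("loaded %d spectra from %s", spectra.n_samples, config.input_csv)
    else:
        spectra = generate_dataset(
            default_band_library(),
            WavenumberGrid(),
            baseline_order=config.baseline_order,
            baseline_scale=config.baseline_scale,
            noise_sd=config.noise_sd,
            seed=stage_seed(config.master_seed, "generate"),
        )
        logger.info("generated %d synthetic spectra", spectra.n_samples)

    processed = run_chain(spectra, config.preprocess)
    logger.info("preprocessing chain done (%.1f s)", time.time() - t0)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "master_seed": config.master_seed,
        "n_samples": spectra.n_samples,
        "class_counts": spectra.class_counts(),
        "chemometrics": _track_chemometrics(processed, config),
        "cnn": _track_cnn(processed, config),
        "wall_time_s": None,
    }
    report["wall_time_s"] = round(time.time() - t0, 2)
    logger.info("experiment finished in %.1f s", report["wall_time_s"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
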