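"""Evaluation: hold-one-slide-out cross-validation and metrics.

Each fold holds out every core of one physical slide as the test set,
preventing slide-level batch effects and patient leakage; the remaining
cores are split 75/25 into train and validation.  Bag-level metrics
treat biphasic and sarcomatoid cores as the positive class against
epithelioid.  On synthetic cohorts with planted per-cell classes, the
instance-level recovery AUROC measures how well the per-cell score
separates planted sarcomatoid from epithelioid cells inside biphasic
bags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import Standardizer, compute_core_features
from .graphs import CoreGraph, build_cell_graph
from .model import ModelConfig, ScoreSet, forward
from .synthetic import CohortCore
from .training import TrainConfig, TrainResult, train

__all__ = ["FoldPlan", "split_hold_one_slide_out", "classification_metrics",
           "instance_recovery_metrics", "featurize_cohort",
           "build_cohort_graphs", "run_cross_validation",
           "CrossValidationResult"]


@dataclass(frozen=True)
class FoldPlan:
    """One cross-validation fold keyed by its held-out slide."""

    held_out_slide: str
    train_or_val_core_ids: tuple[str, ...]
    test_core_ids: tuple[str, ...]


def split_hold_one_slide_out(metadata: pd.DataFrame,
                             seed: int = 0) -> list[FoldPlan]:
    """One fold per slide; a patient never straddles train/val and test.

    ``metadata`` needs columns core_id, slide_id, patient_id.  Cores of
    patients who also have cores on the held-out slide are dropped from
    that fold's training pool entirely.
    """
    slides = sorted(metadata["slide_id"].unique())
    if len(slides) < 2:
        raise ValueError("need at least two slides")
    folds = []
    for slide in slides:
        test = metadata[metadata["slide_id"] == slide]
        if len(test) == len(metadata):
            raise ValueError("one slide contains every core")
        test_patients = set(test["patient_id"])
        pool = metadata[(metadata["slide_id"] != slide)
                        & ~metadata["patient_id"].isin(test_patients)]
        folds.append(FoldPlan(
            held_out_slide=slide,
            train_or_val_core_ids=tuple(pool["core_id"]),
            test_core_ids=tuple(test["core_id"]),
        ))
    return folds


def classification_metrics(bag_scores: np.ndarray, subtypes: list[str],
                           threshold: float = 0.0) -> dict[str, float]:
    """AUROC / AP with B+S positive vs E, plus thresholded sens/spec.

    AUROC and average precision are threshold-free on the bag score Z;
    sensitivity and specificity use the decision Z > ``threshold``
    (default 0, the midpoint of the (-1, 1) score range).
    """
    bag_scores = np.asarray(bag_scores, dtype=np.float64)
    y = np.array([0 if s == "E" else 1 for s in subtypes])
    if len(np.unique(y)) < 2:
        raise ValueError("need both positive and negative bags")
    pred = bag_scores > threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return {
        "auroc": float(roc_auc_score(y, bag_scores)),
        "average_precision": float(average_precision_score(y, bag_scores)),
        "sensitivity": tp / max(1, int((y == 1).sum())),
        "specificity": tn / max(1, int((y == 0).sum())),
    }


def instance_recovery_metrics(cell_scores: dict[str, np.ndarray],
                              cohort: list[CohortCore]) -> float:
    """AUROC of per-cell scores against planted classes in biphasic bags."""
    scores, labels = [], []
    for core in cohort:
        if core.subtype != "B" or core.core_id not in cell_scores:
            continue
        planted = (core.detections["planted_class"]
                   == "sarcomatoid").to_numpy()
        scores.append(cell_scores[core.core_id])
        labels.append(planted)
    if not scores:
        raise ValueError("no biphasic bags with planted labels")
    y = np.concatenate(labels)
    s = np.concatenate(scores)
    if len(np.unique(y)) < 2:
        raise ValueError("planted labels are single-class")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# cohort pipeline


def featurize_cohort(cohort: list[CohortCore],
                     include_deep: bool = False) -> dict[str, pd.DataFrame]:
    """Raw (unstandardised) feature tables per core."""
    return {core.core_id: compute_core_features(
        core.detections, core.image, core.mpp, include_deep=include_deep)
        for core in cohort}


def build_cohort_graphs(cohort: list[CohortCore],
                        features: dict[str, pd.DataFrame],
                        standardizer: Standardizer,
                        radius: float = 30.0) -> dict[str, CoreGraph]:
    """Standardise features and assemble one graph per core."""
    graphs = {}
    for core in cohort:
        table = standardizer.transform(features[core.core_id])
        graphs[core.core_id] = build_cell_graph(
            table.to_numpy(),
            core.detections[["cx_um", "cy_um"]].to_numpy(dtype=np.float64),
            radius=radius,
            feature_names=list(table.columns),
            core_id=core.core_id,
            slide_id=core.slide_id,
            patient_id=core.patient_id,
            y_s_task=core.y_s_task,
            y_e_task=core.y_e_task,
        )
    return graphs


@dataclass
class CrossValidationResult:
    fold_metrics: pd.DataFrame
    test_scoresets: dict[str, ScoreSet]
    pooled_metrics: dict[str, float]
    instance_auroc: float | None
    mean_z_by_subtype: dict[str, float]
    train_results: list[TrainResult] = field(default_factory=list)


def run_cross_validation(
    cohort: list[CohortCore],
    features: dict[str, pd.DataFrame] | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    include_deep: bool = False,
) -> CrossValidationResult:
    """Full hold-one-slide-out experiment on a (synthetic) cohort.

    For each fold: fit feature standardisation on the fold's training
    cores, build graphs, train, and score the held-out slide.  Pooled
    test scores across folds yield the headline bag metrics; planted
    instance labels (if present) yield the instance recovery AUROC.
    """
    train_config = train_config or TrainConfig(seed=seed)
    if features is None:
        features = featurize_cohort(cohort, include_deep=include_deep)
    meta = pd.DataFrame({
        "core_id": [c.core_id for c in cohort],
        "slide_id": [c.slide_id for c in cohort],
        "patient_id": [c.patient_id for c in cohort],
        "subtype": [c.subtype for c in cohort],
    })
    by_id = {c.core_id: c for c in cohort}
    n_features = next(iter(features.values())).shape[1]
    model_config = model_config or ModelConfig(input_dim=n_features)

    folds = split_hold_one_slide_out(meta, seed=seed)
    test_scoresets: dict[str, ScoreSet] = {}
    fold_rows = []
    train_results = []
    for fold_idx, fold in enumerate(folds):
        train_cores = [by_id[i] for i in fold.train_or_val_core_ids]
        test_cores = [by_id[i] for i in fold.test_core_ids]
        standardizer = Standardizer().fit(
            [features[c.core_id] for c in train_cores])
        graphs = build_cohort_graphs(train_cores + test_cores, features,
                                     standardizer)
        fold_seed = (seed * 1000 + fold_idx) % (2**31 - 1)
        result = train(
            [graphs[c.core_id] for c in train_cores], model_config,
            TrainConfig(**{**train_config.__dict__, "seed": fold_seed}))
        train_results.append(result)
        fold_scores = []
        for core in test_cores:
            ss = forward(graphs[core.core_id], result.params)
            test_scoresets[core.core_id] = ss
            fold_scores.append(ss.Z)
        subtypes = [c.subtype for c in test_cores]
        row = {"fold": fold_idx, "held_out_slide": fold.held_out_slide,
               "n_test": len(test_cores),
               "best_val_auroc": result.best_val_auroc,
               "best_epoch": result.best_epoch}
        if len(set(s == "E" for s in subtypes)) == 2:
            row.update(classification_metrics(
                np.array(fold_scores), subtypes))
        fold_rows.append(row)

    pooled_z = np.array([test_scoresets[c.core_id].Z for c in cohort])
    pooled_metrics = classification_metrics(
        pooled_z, [c.subtype for c in cohort])
    mean_z = {s: float(np.mean([test_scoresets[c.core_id].Z
                                for c in cohort if c.subtype == s]))
              for s in ("E", "B", "S")
              if any(c.subtype == s for c in cohort)}
    instance_auroc = None
    if any("planted_class" in c.detections.columns for c in cohort):
        cell_scores = {cid: ss.cell_score
                       for cid, ss in test_scoresets.items()}
        try:
            instance_auroc = instance_recovery_metrics(cell_scores, cohort)
        except ValueError:
            instance_auroc = None
    return CrossValidationResult(
        fold_metrics=pd.DataFrame(fold_rows),
        test_scoresets=test_scoresets,
        pooled_metrics=pooled_metrics,
        instance_auroc=instance_auroc,
        mean_z_by_subtype=mean_z,
        train_results=train_results,
    )
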