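"""Stratified K-fold cross-validation and the Sn/Sp/ACC/MCC/AUC metric suite.

Sensitivity Sn = TP/(TP+FN) is the fraction of nucleosome-forming (core DNA)
sequences recovered; specificity Sp = TN/(TN+FP) the fraction of linker
sequences recovered; ACC the overall fraction correct; MCC the Matthews
correlation coefficient in [-1, 1]; AUC the probability that a random
positive outscores a random negative (ties credited 0.5).

Headline metrics are computed on the pooled out-of-fold predictions (every
sample is scored exactly once by a model that never saw it); per-fold
metrics are retained alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.stats import rankdata

from nucleocgr.classifiers import (
    ScoreSet,
    ensemble_average,
    train_cnn,
    train_elm,
    train_mlp,
    train_svm_grid,
    train_xgboost,
)
from nucleocgr.feature_pipeline import (
    FeatureMatrix,
    assemble_features,
    pca_reduce,
    standardize,
)
from nucleocgr.sequence_io import LabeledDataset
from nucleocgr.util import derive_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


@dataclass
class MetricsReport:
    Sn: float
    Sp: float
    ACC: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.ACC, "Sn": self.Sn, "Sp": self.Sp, "MCC": self.MCC, "AUC": self.AUC}


def confusion_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    return ConfusionCounts(
        TP=int(((labels == 1) & (predicted == 1)).sum()),
        TN=int(((labels == 0) & (predicted == 0)).sum()),
        FP=int(((labels == 0) & (predicted == 1)).sum()),
        FN=int(((labels == 1) & (predicted == 0)).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, ACC and MCC from a confusion matrix; 0/0 is reported as 0."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"degenerate denominator in {name}; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    sn = ratio(c.TP, c.TP + c.FN, "Sn")
    sp = ratio(c.TN, c.TN + c.FP, "Sp")
    acc = (c.TP + c.TN) / c.total
    mcc_den = np.sqrt(
        float(c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FN) * (c.TN + c.FP)
    )
    mcc = ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC")
    return MetricsReport(Sn=sn, Sp=sp, ACC=acc, MCC=mcc)


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 0.5."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded per-class shuffle + round-robin fold assignment.

    Fold class counts differ by at most one per class; deterministic given
    the seed.  Returns an integer fold id (0..k-1) per sample.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} members < k={k}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


@dataclass
class CVResult:
    fold_assignments: np.ndarray
    per_fold: list[MetricsReport]
    pooled: MetricsReport
    oof_scores: np.ndarray
    seed: int
    n_folds: int
    config: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n_folds": self.n_folds,
            "pooled": self.pooled.as_dict(),
            "per_fold": [m.as_dict() for m in self.per_fold],
            "config": self.config,
        }


@dataclass
class PipelineConfig:
    """One feature-extraction + preprocessing + classifier configuration.

    ``features`` is a list of feature requests (see feature_pipeline) for the
    vector backends, or a list of K values for the image backends (mlp/cnn).
    ``multik`` controls how image backends handle several K values: train one
    model per K and average probabilities ("average", the default) or feed a
    single multi-channel model ("channels").
    """

    features: list[Mapping[str, Any]] | None = None
    classifier: str = "svm"
    clf_params: dict[str, Any] = field(default_factory=dict)
    scale: bool = True
    pca_rate: float | None = None
    pca_fit: str = "train"  # "train" (leak-free) or "all" (compatibility)
    image_Ks: list[int] | None = None
    multik: str = "average"


_VECTOR_BACKENDS = {"svm": train_svm_grid, "elm": train_elm, "xgboost": train_xgboost}
_IMAGE_BACKENDS = {"mlp": train_mlp, "cnn": train_cnn}


def _train_and_score_vector(
    cfg: PipelineConfig,
    Xtr: FeatureMatrix,
    ytr: np.ndarray,
    Xte: FeatureMatrix,
    seed: int,
) -> np.ndarray:
    if cfg.scale:
        Xtr, Xte, _ = standardize(Xtr, Xte)
    if cfg.pca_rate is not None:
        Xtr, Xte, _ = pca_reduce(Xtr, Xte, cfg.pca_rate)
    trainer = _VECTOR_BACKENDS[cfg.classifier]
    model = trainer(Xtr.values, ytr, seed=seed, **cfg.clf_params)
    return model.predict_scores(Xte.values)


def _train_and_score_images(
    cfg: PipelineConfig,
    img_tr: np.ndarray,
    ytr: np.ndarray,
    img_te: np.ndarray,
    seed: int,
) -> np.ndarray:
    trainer = _IMAGE_BACKENDS[cfg.classifier]
    if cfg.multik == "channels" or img_tr.shape[1] == 1:
        model = trainer(img_tr, ytr, seed=seed, **cfg.clf_params)
        return model.predict_scores(img_te)
    sets = []
    for ch in range(img_tr.shape[1]):
        model = trainer(img_tr[:, ch : ch + 1], ytr, seed=derive_seed(seed, f"k{ch}"), **cfg.clf_params)
        sets.append(ScoreSet(model.predict_scores(img_te[:, ch : ch + 1])))
    return ensemble_average(sets).scores


def cross_validate(
    dataset: LabeledDataset,
    cfg: PipelineConfig,
    k: int = 10,
    seed: int = 0,
    precomputed: FeatureMatrix | None = None,
) -> CVResult:
    """Stratified K-fold CV of a full pipeline; every sample scored once.

    Per fold, scaler/PCA/classifier are fit on the training portion only
    (unless ``cfg.pca_fit == "all"``).  The pooled out-of-fold confusion and
    AUC form the headline report; per-fold metrics are kept alongside.
    """
    labels = np.asarray(dataset.labels, dtype=int)
    folds = stratified_kfold(labels, k, derive_seed(seed, "folds"))
    image_mode = cfg.classifier in _IMAGE_BACKENDS
    if image_mode:
        from nucleocgr.cgr_fcgr import combine_k

        Ks = cfg.image_Ks or [4]
        images = (
            np.stack([combine_k(s, Ks, mode="image_stack") for s in dataset.sequences])
            / 255.0
        )
    else:
        if cfg.classifier not in _VECTOR_BACKENDS:
            raise ValueError(f"unknown classifier {cfg.classifier!r}")
        feats = precomputed if precomputed is not None else assemble_features(
            dataset, cfg.features or [{"kind": "fcgr", "Ks": [4]}]
        )
        if cfg.pca_fit == "all" and cfg.pca_rate is not None:
            scaled, _, _ = standardize(feats) if cfg.scale else (feats, None, None)
            feats, _, _ = pca_reduce(scaled, None, cfg.pca_rate)

    oof = np.full(len(labels), np.nan)
    per_fold: list[MetricsReport] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for f in range(k):
        te = folds == f
        tr = ~te
        fold_seed = derive_seed(seed, f"fold{f}")
        try:
            if image_mode:
                scores = _train_and_score_images(
                    cfg, images[tr], labels[tr], images[te], fold_seed
                )
            elif cfg.pca_fit == "all" and cfg.pca_rate is not None:
                sub_cfg = PipelineConfig(**{**cfg.__dict__, "pca_rate": None, "scale": False})
                scores = _train_and_score_vector(
                    sub_cfg, feats.subset(np.flatnonzero(tr)), labels[tr],
                    feats.subset(np.flatnonzero(te)), fold_seed,
                )
            else:
                scores = _train_and_score_vector(
                    cfg, feats.subset(np.flatnonzero(tr)), labels[tr],
                    feats.subset(np.flatnonzero(te)), fold_seed,
                )
        except Exception as e:
            raise RuntimeError(f"fold {f} failed: {e}") from e
        oof[te] = scores
        c = confusion_from_predictions(labels[te], (scores >= 0.5).astype(int))
        pooled_counts = pooled_counts + c
        rep = metrics_from_confusion(c)
        if len(np.unique(labels[te])) == 2:
            rep.AUC = auc_score(labels[te], scores)
        per_fold.append(rep)

    pooled = metrics_from_confusion(pooled_counts)
    pooled.AUC = auc_score(labels, oof)
    return CVResult(
        fold_assignments=folds,
        per_fold=per_fold,
        pooled=pooled,
        oof_scores=oof,
        seed=seed,
        n_folds=k,
        config={"classifier": cfg.classifier, "pca_rate": cfg.pca_rate, "scale": cfg.scale},
    )
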