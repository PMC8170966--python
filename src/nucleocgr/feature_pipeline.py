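"""Feature assembly, train-fold scaling and PCA reduction.

All fitting (scaler statistics, PCA basis) happens on the training portion
only and is then applied to held-out data, so cross-validation folds never
leak; a compatibility switch (``fit_on="all"`` in the CV layer) reproduces
the variant that fits on the full dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from nucleocgr.cgr_fcgr import combine_k, fcgr_feature_names
from nucleocgr.physchem_features import (
    AutocovParams,
    PseKNCParams,
    autocovariance_feature_names,
    autocovariance_features,
    load_index_table,
    pse_knc_feature_names,
    pse_knc_parallel,
)
from nucleocgr.sequence_io import LabeledDataset

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """n_samples x n_features numeric table with named columns and sample ids."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} ids x {len(self.feature_names)} names"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[rows],
            self.feature_names,
            [self.sample_ids[i] for i in np.atleast_1d(rows)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names, index=self.sample_ids
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(df.to_numpy(float), list(df.columns), [str(i) for i in df.index])


# -- feature requests ---------------------------------------------------------
#
# A feature request is a mapping with a "kind" key:
#   {"kind": "fcgr", "Ks": [1, 2, 4]}
#   {"kind": "dac" | "tac", "lag": 2}           (autocovariance)
#   {"kind": "dacc" | "tacc", "lag": 2}         (with cross-index terms)
#   {"kind": "pcpsednc" | "pcpsetnc", "lam": 8, "w": 0.5}
#   {"kind": "all", "Ks": [...], "lag": 2, "lam": 8, "w": 0.5}
# "all" expands to FCGR ++ DACC ++ TACC ++ PC-PseDNC ++ PC-PseTNC.

_AC_KINDS = {"dac": (2, False), "tac": (3, False), "dacc": (2, True), "tacc": (3, True)}
_PSE_KINDS = {"pcpsednc": 2, "pcpsetnc": 3}


def _expand_requests(spec: Sequence[Mapping[str, Any]]) -> list[dict[str, Any]]:
    out: list[dict[str, Any]] = []
    for req in spec:
        req = dict(req)
        kind = req.pop("kind", None)
        if kind == "all":
            Ks = req.get("Ks", [4])
            lag = req.get("lag", 2)
            lam = req.get("lam", 8)
            w = req.get("w", 0.5)
            out += [
                {"kind": "fcgr", "Ks": Ks},
                {"kind": "dacc", "lag": lag},
                {"kind": "tacc", "lag": lag},
                {"kind": "pcpsednc", "lam": lam, "w": w},
                {"kind": "pcpsetnc", "lam": lam, "w": w},
            ]
        elif kind in ("fcgr", *_AC_KINDS, *_PSE_KINDS):
            out.append({"kind": kind, **req})
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return out


def assemble_features(
    dataset: LabeledDataset, spec: Sequence[Mapping[str, Any]]
) -> FeatureMatrix:
    """Concatenate the requested per-sequence features in spec order."""
    requests = _expand_requests(spec)
    if not requests:
        raise ValueError("empty feature spec")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    tables: dict[int, Any] = {}

    def table_for(order: int):
        if order not in tables:
            builtin = {2: "helical-steps", 3: "bendability"}[order]
            tables[order] = load_index_table(builtin, order)
        return tables[order]

    for req in requests:
        kind = req["kind"]
        try:
            if kind == "fcgr":
                Ks = list(req.get("Ks", [4]))
                block = np.stack(
                    [combine_k(s, Ks, mode="vector") for s in dataset.sequences]
                )
                names += [n for K in Ks for n in fcgr_feature_names(K)]
            elif kind in _AC_KINDS:
                order, cross = _AC_KINDS[kind]
                params = AutocovParams(
                    lag=req.get("lag", 2), order=order, include_cross=cross
                )
                tab = req.get("table") or table_for(order)
                block = np.stack(
                    [autocovariance_features(s, tab, params) for s in dataset.sequences]
                )
                names += autocovariance_feature_names(tab, params)
            elif kind in _PSE_KINDS:
                order = _PSE_KINDS[kind]
                params = PseKNCParams(
                    lam=req.get("lam", 8), w=req.get("w", 0.5), order=order
                )
                tab = req.get("table") or table_for(order)
                block = np.stack(
                    [pse_knc_parallel(s, tab, params) for s in dataset.sequences]
                )
                names += pse_knc_feature_names(params)
        except ValueError as e:
            raise ValueError(f"feature {kind!r} failed: {e}") from e
        blocks.append(block)
    return FeatureMatrix(np.hstack(blocks), names, list(dataset.ids))


# -- scaling ------------------------------------------------------------------


@dataclass
class Scaler:
    """Per-feature (x - mean) / sd transform; sd-0 columns pass through."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of sd-0 columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = X.copy().astype(float)
        nc = ~self.constant
        out[:, nc] = (X[:, nc] - self.mean[nc]) / self.sd[nc]
        return out


def standardize(
    train: FeatureMatrix, apply_to: FeatureMatrix | None = None
) -> tuple[FeatureMatrix, FeatureMatrix | None, Scaler]:
    """Standardize using training statistics only.

    Returns (scaled train, scaled apply_to or None, fitted scaler).
    Constant training columns are left unchanged with a warning.
    """
    if train.n_samples == 0:
        raise ValueError("empty training matrix")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) left unscaled (e.g. %s)",
            int(constant.sum()),
            train.feature_names[int(np.flatnonzero(constant)[0])],
        )
    scaler = Scaler(mean=mean, sd=sd, constant=constant)
    tr = FeatureMatrix(scaler.transform(train.values), train.feature_names, train.sample_ids)
    ap = None
    if apply_to is not None:
        ap = FeatureMatrix(
            scaler.transform(apply_to.values), apply_to.feature_names, apply_to.sample_ids
        )
    return tr, ap, scaler


# -- PCA ----------------------------------------------------------------------


@dataclass
class PCAModel:
    """Centered orthonormal projection retaining a cumulative variance target."""

    mean: np.ndarray
    components: np.ndarray  # (m, n_features), rows orthonormal
    explained_ratio: np.ndarray  # per retained component
    m: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T


def pca_reduce(
    train: FeatureMatrix,
    apply_to: FeatureMatrix | None,
    rate: float,
) -> tuple[FeatureMatrix, FeatureMatrix | None, PCAModel]:
    """Project onto the fewest leading principal components reaching ``rate``.

    The decomposition is fit on ``train`` only (full SVD); ``m`` is the
    smallest count whose cumulative explained-variance ratio is >= ``rate``;
    ``rate=1.0`` keeps every component.  A deterministic sign convention
    (the largest-magnitude loading of each component is positive) makes runs
    reproducible across SVD implementations.
    """
    if not 0.0 < rate <= 1.0:
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    if train.n_samples < 2:
        raise ValueError("PCA needs at least 2 training samples")
    max_m = min(train.n_samples - 1, train.n_features)
    pca = PCA(n_components=max_m, svd_solver="full")
    pca.fit(train.values)
    ratios = pca.explained_variance_ratio_
    if rate >= 1.0:
        m = max_m
    else:
        m = int(np.searchsorted(np.cumsum(ratios), rate) + 1)
        m = min(m, max_m)
    components = pca.components_[:m].copy()
    for i in range(m):  # deterministic sign: largest |loading| positive
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    model = PCAModel(
        mean=pca.mean_, components=components, explained_ratio=ratios[:m], m=m
    )
    names = [f"pc{i+1}" for i in range(m)]
    tr = FeatureMatrix(model.transform(train.values), names, train.sample_ids)
    ap = None
    if apply_to is not None:
        ap = FeatureMatrix(model.transform(apply_to.values), names, apply_to.sample_ids)
    return tr, ap, model
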