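"""Core in-memory containers shared across pipeline stages.

Matrices are genes x samples pandas DataFrames throughout; sample metadata
rides alongside the expression matrix.  Essentiality scores follow the
CERES convention: more negative = stronger dependency, with -0.5 the
conventional "dependent" cutoff.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


def _check_labels(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} labels: {dup[:5]}")


def _check_finite(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise FormatError(
            f"non-finite value in {what} at gene={values.index[bad[0]]!r}, "
            f"sample={values.columns[bad[1]]!r}"
        )


def fingerprint(values: pd.DataFrame) -> str:
    """Short stable hash of a matrix (labels + data), for provenance logs."""
    h = hashlib.sha256()
    h.update("\t".join(map(str, values.index)).encode())
    h.update("\t".join(map(str, values.columns)).encode())
    h.update(np.ascontiguousarray(values.to_numpy(float)).tobytes())
    return h.hexdigest()[:16]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 abundance with per-sample metadata.

    ``metadata`` is indexed by sample and carries ``cohort``, ``lineage`` and
    optionally ``purity`` in [0, 1].
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_labels(self.values.index, "gene")
        _check_labels(self.values.columns, "sample")
        _check_finite(self.values, "expression matrix")
        if self.metadata is not None:
            missing = self.values.columns.difference(self.metadata.index)
            if len(missing):
                raise FormatError(f"samples missing from metadata: {list(missing)[:5]}")
            self.metadata = self.metadata.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.metadata)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.metadata)


@dataclass
class EssentialityMap:
    """Genes x samples essentiality scores; negative = more essential.

    ``provenance`` is one of ``measured``, ``predicted``,
    ``predicted+rescaled``; downstream stages that compare score scales
    across cohorts insist on matching provenance.
    """

    values: pd.DataFrame
    provenance: str = "measured"
    model_fingerprint: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("measured", "predicted", "predicted+rescaled"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        _check_labels(self.values.index, "gene")
        _check_labels(self.values.columns, "sample")
        _check_finite(self.values, "essentiality map")


@dataclass
class GeneModel:
    """Per-gene sparse linear (or logistic) predictor of essentiality.

    Coefficients are stored on the standardized-feature scale together with
    the training means/SDs, so prediction is
    ``intercept + sum(coef * (x - mean) / sd)``.
    """

    gene: str
    mode: str  # expression_only | multi_omics | confounder_null | mutation_classifier
    alpha: float
    lam: float
    intercept: float
    coef: pd.Series           # feature -> coefficient (nonzero only)
    feature_mean: pd.Series
    feature_sd: pd.Series
    cv_r: float               # out-of-fold Pearson R (or CV AUC for classifiers)
    p: float
    q: float = float("nan")
    passed: bool = False
    self_rank: int | None = None
    flag: str = ""

    @property
    def n_features(self) -> int:
        return int((self.coef != 0).sum())

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        """Predict scores for a genes x samples matrix containing all features."""
        feats = self.coef.index
        missing = feats.difference(expr.index)
        if len(missing):
            raise KeyError(f"model {self.gene}: missing features {list(missing)[:5]}")
        x = expr.loc[feats]
        z = x.sub(self.feature_mean.loc[feats], axis=0).div(self.feature_sd.loc[feats], axis=0)
        return z.mul(self.coef, axis=0).sum(axis=0) + self.intercept


@dataclass
class ModelSet:
    """All fitted models from one run, with fitting provenance."""

    models: list[GeneModel] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(m.gene, m.mode) for m in self.models]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene, mode) in ModelSet")

    def passing(self, mode: str | None = None) -> list[GeneModel]:
        return [
            m for m in self.models
            if m.passed and (mode is None or m.mode == mode)
        ]

    def get(self, gene: str, mode: str) -> GeneModel:
        for m in self.models:
            if m.gene == gene and m.mode == mode:
                return m
        raise KeyError((gene, mode))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)
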