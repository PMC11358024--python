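"""Transcriptional alignment between the cell-line cohort and a target cohort.

Tumor biopsies carry stromal/immune admixture that cell lines lack, which
corrupts expression-based essentiality predictions.  The alignment stack is:
quantile normalization to a pooled reference, contrastive PCA (eigenvectors
of C_fg - alpha_c * C_bg, foreground = target cohort) to isolate the
target-specific variance, removal of the top contrastive components from
both cohorts, and a cluster-matched shift correction.  Healthy-tissue
cohorts skip cPCA and instead get a per-gene location-scale adjustment to
the cell cohort (shrunken toward the global adjustment).  The purity
diagnostic quantifies how much predicted essentiality still tracks tumor
purity before and after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.cluster import KMeans

from .config import stage_log
from .containers import EssentialityMap, ExpressionMatrix, fingerprint


def _intersect(*mats: ExpressionMatrix) -> list[ExpressionMatrix]:
    shared = mats[0].genes
    for m in mats[1:]:
        shared = shared.intersection(m.genes)
    shared = [g for g in mats[0].genes if g in set(shared)]  # keep input order
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes after intersection")
    stage_log("alignment.intersect", n_shared=len(shared))
    return [m.subset_genes(shared) for m in mats]


def quantile_normalize(*mats: ExpressionMatrix):
    """Force every sample column onto the pooled mean-of-sorted reference.

    Returns (normalized matrices..., reference quantiles).  Ranks within a
    column are preserved; afterwards all columns share one value multiset.
    """
    mats = _intersect(*mats)
    n_genes = len(mats[0].genes)
    pooled = np.concatenate([m.values.to_numpy() for m in mats], axis=1)
    reference = np.sort(pooled, axis=0).mean(axis=1)

    out = []
    for m in mats:
        arr = m.values.to_numpy()
        ranks = np.apply_along_axis(stats.rankdata, 0, arr)  # average ties
        normed = np.interp(ranks, np.arange(1, n_genes + 1), reference)
        out.append(m.with_values(
            pd.DataFrame(normed, index=m.values.index, columns=m.values.columns)))
    return (*out, reference)


def contrastive_pca(foreground: ExpressionMatrix, background: ExpressionMatrix,
                    alpha_c: float = 1.0, k: int = 4):
    """Top-k eigenvectors of C_fg - alpha_c * C_bg (gene-gene covariances).

    Both matrices are centered per gene internally; eigenvalues are returned
    in decreasing order.  alpha_c = 0 reduces to ordinary PCA of the
    foreground.
    """
    fg, bg = _intersect(foreground, background)
    genes = fg.values.index
    if k > len(genes):
        raise ValueError(f"k={k} exceeds gene count {len(genes)}")
    Cf = np.cov(fg.values.to_numpy())
    Cb = np.cov(bg.values.to_numpy())
    contrast = Cf - alpha_c * Cb
    m = contrast.shape[0]
    evals, evecs = linalg.eigh(contrast, subset_by_index=(m - k, m - 1))
    order = np.argsort(evals)[::-1]
    U = pd.DataFrame(evecs[:, order], index=genes,
                     columns=[f"cPC{i + 1}" for i in range(k)])
    return U, evals[order]


def remove_components(X: ExpressionMatrix, U: pd.DataFrame) -> ExpressionMatrix:
    """Project the per-gene-centered matrix onto the orthocomplement of U.

    X' = center + (I - U U^T)(X - center); idempotent, and columns of the
    centered result are orthogonal to U.
    """
    if U.shape[1] == 0:
        return X
    if not U.index.equals(X.values.index):
        raise ValueError("loading gene set does not match the matrix")
    arr = X.values.to_numpy()
    center = arr.mean(axis=1, keepdims=True)
    Uv = U.to_numpy()
    resid = arr - center
    cleaned = center + resid - Uv @ (Uv.T @ resid)
    return X.with_values(pd.DataFrame(cleaned, index=X.values.index,
                                      columns=X.values.columns))


def cluster_match_correct(cells: ExpressionMatrix, tumors: ExpressionMatrix,
                          n_clusters: int = 4, seed: int = 0):
    """Joint k-means over pooled samples; shift each tumor cluster onto its
    nearest cell-cohort cluster centroid.  Returns (shifted tumors, shifts)."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    cells, tumors = _intersect(cells, tumors)
    pooled = np.concatenate([cells.values.to_numpy().T, tumors.values.to_numpy().T])
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pooled)
    n_cells = cells.values.shape[1]
    lab_cells, lab_tum = km.labels_[:n_cells], km.labels_[n_cells:]

    cell_centroids = {c: pooled[:n_cells][lab_cells == c].mean(axis=0)
                      for c in np.unique(lab_cells)}
    arr = tumors.values.to_numpy().copy()
    shifts = {}
    for c in np.unique(lab_tum):
        members = lab_tum == c
        t_centroid = arr[:, members].mean(axis=1)
        if not cell_centroids:
            stage_log("alignment.cluster_match", cluster=int(c), unmatched=True)
            continue
        nearest = min(cell_centroids,
                      key=lambda cc: np.sum((cell_centroids[cc] - t_centroid) ** 2))
        shift = t_centroid - cell_centroids[nearest]
        arr[:, members] -= shift[:, None]
        shifts[int(c)] = pd.Series(shift, index=tumors.values.index)
    stage_log("alignment.cluster_match", n_clusters=n_clusters,
              n_shifted=len(shifts))
    return tumors.with_values(pd.DataFrame(arr, index=tumors.values.index,
                                           columns=tumors.values.columns)), shifts


def gtex_style_correct(cells: ExpressionMatrix, healthy: ExpressionMatrix,
                       shrink_n0: float = 10.0):
    """Quantile normalization plus shrunken per-gene location-scale adjustment
    of the healthy cohort onto the cell cohort's gene means/SDs.

    The gene-specific adjustment is blended with the global (all-gene)
    adjustment with weight n / (n + shrink_n0), n = healthy sample count, so
    tiny cohorts fall back toward the global shift.  Zero-variance genes get
    the location shift only (logged).
    """
    cells_q, healthy_q, _ = quantile_normalize(cells, healthy)
    c = cells_q.values.to_numpy()
    h = healthy_q.values.to_numpy()
    n = h.shape[1]
    w = n / (n + shrink_n0)

    mu_c, mu_h = c.mean(axis=1), h.mean(axis=1)
    sd_c, sd_h = c.std(axis=1), h.std(axis=1)
    glob_scale = sd_c.mean() / max(sd_h.mean(), 1e-12)
    glob_shift = mu_c.mean() - mu_h.mean()

    zero_var = sd_h <= 1e-12
    if zero_var.any():
        stage_log("alignment.gtex_correct",
                  zero_variance_genes=int(zero_var.sum()))
    gene_scale = np.where(zero_var, 1.0, sd_c / np.where(zero_var, 1.0, sd_h))
    scale = w * gene_scale + (1 - w) * glob_scale
    out = (h - mu_h[:, None]) * scale[:, None]
    target_mu = w * mu_c + (1 - w) * (mu_h + glob_shift)
    out = out + target_mu[:, None]
    return healthy_q.with_values(
        pd.DataFrame(out, index=healthy_q.values.index,
                     columns=healthy_q.values.columns))


@dataclass
class AlignmentTransform:
    """Frozen record of one alignment fit, sufficient for re-application."""

    reference: np.ndarray | None
    loadings: pd.DataFrame | None
    alpha_c: float
    k_removed: int
    shifts: dict = field(default_factory=dict)
    fingerprints: dict = field(default_factory=dict)


def align_cohorts(cells: ExpressionMatrix, target: ExpressionMatrix,
                  k_removed: int = 4, alpha_c: float = 1.0,
                  n_clusters: int | None = None, seed: int = 0,
                  remove_from_cells: bool = True):
    """Full alignment stack for a tumor/PDX target cohort.

    Returns (aligned cells, aligned target, AlignmentTransform).  Foreground
    for cPCA is the target cohort (its stroma is the variance to remove);
    with k_removed = 0 the cPCA step is skipped.
    """
    cells_q, target_q, reference = quantile_normalize(cells, target)
    U = None
    if k_removed > 0:
        U, _ = contrastive_pca(target_q, cells_q, alpha_c=alpha_c, k=k_removed)
        target_q = remove_components(target_q, U)
        if remove_from_cells:
            cells_q = remove_components(cells_q, U)
    k = n_clusters
    if k is None:
        meta = cells.metadata
        k = meta["lineage"].nunique() if meta is not None and "lineage" in meta else 4
    target_q, shifts = cluster_match_correct(cells_q, target_q, n_clusters=k, seed=seed)
    tf = AlignmentTransform(reference, U, alpha_c, k_removed, shifts,
                            fingerprints={"cells": fingerprint(cells_q.values),
                                          "target": fingerprint(target_q.values)})
    return cells_q, target_q, tf


@dataclass
class PurityDiagnostic:
    """Per-model R^2 against tumor purity, pre- and post-alignment."""

    r2_pre: pd.Series
    r2_post: pd.Series
    wilcoxon_p: float

    @property
    def median_pre(self) -> float:
        return float(self.r2_pre.median())

    @property
    def median_post(self) -> float:
        return float(self.r2_post.median())


def purity_r2(predicted: EssentialityMap, purity: pd.Series) -> pd.Series:
    """Per gene model, R^2 of a simple regression of predicted score on purity."""
    pur = purity.loc[predicted.values.columns].to_numpy(float)
    if np.std(pur) == 0:
        raise ValueError("constant purity: R^2 undefined")
    out = {}
    for gene, row in predicted.values.iterrows():
        r = np.corrcoef(row.to_numpy(float), pur)[0, 1]
        out[gene] = float(r * r) if np.isfinite(r) else np.nan
    return pd.Series(out).dropna()


def purity_diagnostic(pred_pre: EssentialityMap, pred_post: EssentialityMap,
                      purity: pd.Series) -> PurityDiagnostic:
    r2_pre = purity_r2(pred_pre, purity)
    r2_post = purity_r2(pred_post, purity)
    stat = stats.ranksums(r2_pre.to_numpy(), r2_post.to_numpy())
    stage_log("alignment.purity", median_pre=round(float(r2_pre.median()), 4),
              median_post=round(float(r2_post.median()), 4),
              wilcoxon_p=float(stat.pvalue))
    return PurityDiagnostic(r2_pre, r2_post, float(stat.pvalue))
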