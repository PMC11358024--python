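"""Model transposition: apply cell-line models to an aligned target cohort.

Passing models are evaluated on the aligned target expression, then each
gene's predictions are rescaled by the linear regression of measured on
predicted scores in the cell cohort, which puts predictions on the measured
CERES-like scale without changing per-gene sample rankings (a monotone
affine map).  Downstream: Ward-linkage lineage clustering of the resulting
map and Wilcoxon gain-of-function association tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .config import stage_log
from .containers import EssentialityMap, ExpressionMatrix, ModelSet


def predict_map(models: ModelSet, target: ExpressionMatrix,
                mode: str = "expression_only") -> EssentialityMap:
    """Predicted essentiality for every passing model whose features are all
    present in the target matrix (models with missing features are skipped
    and logged)."""
    rows = {}
    skipped = 0
    for m in models.passing(mode):
        if len(m.coef.index.difference(target.genes)):
            skipped += 1
            stage_log("transpose.predict", gene=m.gene, skipped="missing features")
            continue
        rows[m.gene] = m.predict(target.values)
    if not rows:
        raise ValueError("no passing model could be applied to the target")
    pred = pd.DataFrame(rows).T.loc[:, target.samples]
    stage_log("transpose.predict", n_models=len(rows), n_skipped=skipped,
              n_samples=pred.shape[1])
    return EssentialityMap(pred, "predicted",
                           model_fingerprint=str(models.provenance.get(
                               "feature_fingerprint")))


@dataclass
class RescaleParams:
    """Per-gene slope/intercept from regressing measured on predicted."""

    table: pd.DataFrame  # index gene, columns slope, intercept, flagged


def rescale(predicted: EssentialityMap, predicted_cells: EssentialityMap,
            measured: EssentialityMap):
    """Affine-map target predictions onto the measured scale.

    Per gene, fit measured ~ a * predicted_cells + b on the cell cohort and
    apply (a, b) to the target predictions.  Degenerate (constant)
    predictions are flagged and passed through unscaled.
    """
    genes = predicted.values.index.intersection(measured.values.index)
    rows, out = [], {}
    for g in genes:
        x = predicted_cells.values.loc[g].to_numpy(float)
        y = measured.values.loc[g].to_numpy(float)
        if np.std(x) == 0:
            rows.append((g, 1.0, 0.0, True))
            out[g] = predicted.values.loc[g]
            continue
        a, b = np.polyfit(x, y, 1)
        rows.append((g, float(a), float(b), False))
        out[g] = a * predicted.values.loc[g] + b
    params = RescaleParams(pd.DataFrame(rows, columns=["gene", "slope",
                                                       "intercept", "flagged"])
                           .set_index("gene"))
    mapped = pd.DataFrame(out).T.loc[genes, predicted.values.columns]
    stage_log("transpose.rescale", n_genes=len(genes),
              n_flagged=int(params.table["flagged"].sum()))
    return EssentialityMap(mapped, "predicted+rescaled",
                           model_fingerprint=predicted.model_fingerprint), params


def lineage_cluster(emap: EssentialityMap, lineages: pd.Series,
                    n_clusters: int | None = None):
    """Ward-linkage hierarchical clustering of samples on Euclidean distance.

    Returns (linkage matrix, cluster labels, adjusted Rand index vs the
    provided lineage labels).
    """
    X = emap.values.T.to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    Z = hierarchy.linkage(X, method="ward")
    lin = lineages.loc[emap.values.columns]
    k = n_clusters or lin.nunique()
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    ari = float(adjusted_rand_score(lin.to_numpy(), labels))
    stage_log("transpose.lineage_cluster", n_samples=X.shape[0], k=k,
              ari=round(ari, 4))
    return Z, pd.Series(labels, index=emap.values.columns), ari


def gof_association(emap: EssentialityMap, gof: pd.DataFrame,
                    min_group: int = 3) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of scores, carriers vs non-carriers, per
    gene with a gain-of-function annotation; BH-FDR across tested genes.

    ``stronger_in_carriers`` flags genes whose carrier median score is more
    negative (the oncogene-addiction direction).
    """
    genes = emap.values.index.intersection(gof.index)
    rows = []
    for g in genes:
        carrier = gof.loc[g, emap.values.columns].to_numpy() > 0
        scores = emap.values.loc[g].to_numpy(float)
        if carrier.sum() < min_group or (~carrier).sum() < min_group:
            stage_log("transpose.gof", gene=g, skipped="group too small")
            continue
        res = stats.ranksums(scores[carrier], scores[~carrier])
        rows.append((g, int(carrier.sum()), float(res.statistic), float(res.pvalue),
                     bool(np.median(scores[carrier]) < np.median(scores[~carrier]))))
    table = pd.DataFrame(rows, columns=["gene", "n_carriers", "statistic", "p",
                                        "stronger_in_carriers"]).set_index("gene")
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = []
    stage_log("transpose.gof", n_tested=len(table),
              n_directional=int((table.get("stronger_in_carriers",
                                           pd.Series(dtype=bool))).sum()))
    return table
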