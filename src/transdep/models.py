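"""Per-gene elastic-net models of essentiality from expression features.

For each gene with enough dependent (< -0.5) and nondependent lines, an
elastic net (mixing 0.5) is fit on standardized features over a 100-point
lambda path spanning four decades below lambda_max, with the penalty chosen
at the minimum mean CV error over ten folds.  Performance is the Pearson R
between pooled out-of-fold predictions and the observed scores, with a
two-sided t-approximation P (n-2 df) and Benjamini-Hochberg FDR across all
attempted genes; a model passes at R > 0.2 and FDR < 1e-3.

Modes: ``expression_only`` (the transposition workhorse), ``multi_omics``
(expression + binary mutation + CNV features), ``confounder_null`` (lineage
one-hot plus nuisance covariates, an empirical floor for what cohort
structure alone predicts) and ``mutation_classifier`` (logistic elastic net
predicting mutation status from expression, for the essentiality-vs-mutation
AUC comparison).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV, enet_path
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, stage_log
from .containers import (EssentialityMap, ExpressionMatrix, GeneModel,
                         ModelSet, fingerprint)


def eligible_genes(ess: EssentialityMap, dep_cutoff: float = -0.5,
                   min_each: int = 5) -> list[str]:
    """Genes with at least ``min_each`` dependent (score < cutoff, strict)
    and ``min_each`` nondependent lines."""
    if ess.provenance != "measured":
        raise ValueError("eligibility is defined on measured essentiality")
    vals = ess.values
    dep = (vals < dep_cutoff).sum(axis=1)
    nondep = (vals >= dep_cutoff).sum(axis=1)
    keep = vals.index[(dep >= min_each) & (nondep >= min_each)]
    return list(keep)


def _lambda_path(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                 n_lambda: int, decades: float) -> np.ndarray:
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * l1_ratio)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def fit_gene_model(y: pd.Series, X: pd.DataFrame, gene: str = "",
                   mode: str = "expression_only", alpha: float = 0.5,
                   folds: int = 10, seed: int = 0, n_lambda: int = 100,
                   lambda_decades: float = 4.0) -> GeneModel:
    """Elastic net of one gene's essentiality on a samples x features matrix.

    Features are standardized within training folds; the final model is refit
    on all samples at the CV-selected lambda and stored on the standardized
    scale together with the full-data means/SDs.
    """
    if not y.index.equals(X.index):
        raise ValueError("y and X sample indices must be aligned")
    yv = y.to_numpy(float)
    Xv = X.to_numpy(float)
    n = len(yv)

    if np.std(yv) == 0:
        empty = pd.Series(dtype=float)
        return GeneModel(gene, mode, alpha, np.nan, float(yv.mean()), empty,
                         empty, empty, np.nan, np.nan, passed=False,
                         flag="constant_response")

    path = _lambda_path(*_standardize(Xv)[:1], yv, alpha, n_lambda, lambda_decades)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros((n, len(path)))
    for tr, va in kf.split(Xv):
        Xtr, mean, sd = _standardize(Xv[tr])
        ytr = yv[tr]
        _, coefs, _ = enet_path(Xtr, ytr - ytr.mean(), l1_ratio=alpha,
                                alphas=path)
        Xva = (Xv[va] - mean) / sd
        oof[va] = Xva @ coefs + ytr.mean()
    mse = ((oof - yv[:, None]) ** 2).mean(axis=0)
    best = int(np.argmin(mse))
    lam = float(path[best])

    pred = oof[:, best]
    if np.std(pred) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, yv)[0, 1])
    # two-sided t approximation for H0: R = 0 at out-of-fold n
    t = r * np.sqrt(max(n - 2, 1)) / np.sqrt(max(1.0 - r * r, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df=max(n - 2, 1)))

    Xs, mean, sd = _standardize(Xv)
    _, coefs, _ = enet_path(Xs, yv - yv.mean(), l1_ratio=alpha, alphas=path)
    beta = coefs[:, best]
    nz = beta != 0
    feat = X.columns[nz]
    coef = pd.Series(beta[nz], index=feat)
    self_rank = None
    if gene in feat:
        order = coef.abs().sort_values(ascending=False).index
        self_rank = int(list(order).index(gene)) + 1
    return GeneModel(gene, mode, alpha, lam, float(yv.mean()), coef,
                     pd.Series(mean[nz], index=feat),
                     pd.Series(sd[nz], index=feat),
                     cv_r=r, p=p, self_rank=self_rank)


def _confounder_features(expr: ExpressionMatrix, seed: int,
                         n_nuisance: int = 6) -> pd.DataFrame:
    """Lineage one-hot plus simulated nuisance covariates (screen-quality,
    age-like continuous noise), the cohort-structure-only null feature set."""
    onehot = pd.get_dummies(expr.metadata["lineage"]).astype(float)
    rng = np.random.default_rng(seed)
    nuis = pd.DataFrame(rng.normal(size=(len(onehot), n_nuisance)),
                        index=onehot.index,
                        columns=[f"nuis{i}" for i in range(n_nuisance)])
    return pd.concat([onehot, nuis], axis=1)


def fit_all(ess: EssentialityMap, expr: ExpressionMatrix,
            mode: str = "expression_only", mut: pd.DataFrame | None = None,
            cnv: pd.DataFrame | None = None, config: RunConfig | None = None,
            genes: list[str] | None = None) -> ModelSet:
    """Fit models for all eligible genes and apply the BH pass rule."""
    cfg = config or RunConfig()
    if not ess.values.columns.equals(expr.samples):
        raise ValueError("essentiality and expression sample sets differ")
    if genes is None:
        genes = eligible_genes(ess, cfg.dep_cutoff, cfg.min_each)

    if mode in ("expression_only",):
        feats = expr.values.T
    elif mode == "multi_omics":
        if mut is None or cnv is None:
            raise ValueError("multi_omics mode needs mutation and CNV matrices")
        feats = pd.concat([expr.values.T.add_suffix("_expr"),
                           mut.T.add_suffix("_mut").astype(float),
                           cnv.T.add_suffix("_cnv").astype(float)], axis=1)
    elif mode == "confounder_null":
        feats = _confounder_features(expr, cfg.seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    models = []
    for g in genes:
        m = fit_gene_model(ess.values.loc[g], feats, gene=g, mode=mode,
                           alpha=cfg.enet_alpha, folds=cfg.enet_folds,
                           seed=cfg.seed, n_lambda=cfg.n_lambda,
                           lambda_decades=cfg.lambda_decades)
        models.append(m)

    ps = np.array([m.p for m in models], dtype=float)
    ok = np.isfinite(ps)
    qs = np.full_like(ps, np.nan)
    if ok.any():
        qs[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for m, q in zip(models, qs):
        m.q = float(q)
        m.passed = bool(np.isfinite(m.cv_r) and np.isfinite(q)
                        and m.cv_r > cfg.r_threshold and q < cfg.q_threshold)
    mset = ModelSet(models, provenance={
        "mode": mode, "alpha": cfg.enet_alpha, "folds": cfg.enet_folds,
        "r_threshold": cfg.r_threshold, "q_threshold": cfg.q_threshold,
        "seed": cfg.seed, "feature_fingerprint": fingerprint(expr.values),
    })
    stage_log("models.fit_all", mode=mode, attempted=len(models),
              passed=len(mset.passing()))
    return mset


def fit_mutation_classifier(mut: pd.Series, X: pd.DataFrame, gene: str = "",
                            min_prev: float = 0.02, folds: int = 5,
                            seed: int = 0) -> GeneModel | None:
    """Logistic elastic net of mutation status on expression; CV AUC stored
    in ``cv_r``.  Returns None (with a log entry) outside the prevalence band."""
    prev = float(mut.mean())
    if not (min_prev < prev < 1 - min_prev):
        stage_log("models.mutation_classifier", gene=gene, prevalence=round(prev, 4),
                  skipped="prevalence out of band")
        return None
    Xs, mean, sd = _standardize(X.to_numpy(float))
    y = mut.to_numpy(int)
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(Cs=10, cv=cv, penalty="elasticnet",
                               l1_ratios=[0.5], solver="saga", max_iter=5000,
                               scoring="roc_auc", random_state=seed, n_jobs=1)
    clf.fit(Xs, y)
    proba = cross_val_predict(clf, Xs, y, cv=cv, method="predict_proba")[:, 1]
    auc = float(roc_auc_score(y, proba))
    beta = clf.coef_.ravel()
    nz = beta != 0
    feat = X.columns[nz]
    return GeneModel(gene, "mutation_classifier", 0.5, float(1.0 / clf.C_[0]),
                     float(clf.intercept_[0]), pd.Series(beta[nz], index=feat),
                     pd.Series(mean[nz], index=feat), pd.Series(sd[nz], index=feat),
                     cv_r=auc, p=np.nan)


def essentiality_auc(scores: pd.Series, y_sensitive: pd.Series | None = None,
                     cutoff: float = -0.5) -> float:
    """AUC of (negated) scores for the sensitive class (score < cutoff)."""
    if y_sensitive is None:
        y_sensitive = (scores < cutoff).astype(int)
    if y_sensitive.nunique() < 2:
        raise ValueError("single-class labels")
    return float(roc_auc_score(y_sensitive.to_numpy(), -scores.to_numpy()))
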