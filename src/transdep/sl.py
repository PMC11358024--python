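"""Synthetic-lethality discovery from a dependency map and LOF events.

Stage 1 (lasso): per essentiality gene, lasso of its scores on the binary
LOF matrix (5-fold CV, minimum-error lambda); coefficients below -0.3 (LOF
carriers more essential; the threshold applies to the original 0/1
predictor scale) go to a Welch t-test of carrier vs non-carrier scores with
BH-FDR across all tested pairs.  Stage 2 (mutual exclusivity): an
UNCOVER-style greedy weighted set cover, run per target gene over its
candidate partners, with a permutation P value.  Stage 3: keep pairs that
are annotated paralogs or closer than 1.5 in phylogenetic distance.  The
funnel report records survivors per stage.

The mutual-exclusivity objective for a gene set S with per-sample weights w
(default: negated essentiality, so the most-dependent samples weigh most) is

    score(S) = sum_s covered(s) * w_s * (2 - k_s)

where k_s is the number of genes in S with an LOF event in sample s: a
sample covered exactly once contributes +w_s and every extra covering gene
subtracts w_s again, penalizing co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, stage_log
from .containers import EssentialityMap


@dataclass
class SLCandidate:
    gene_a: str                  # essentiality gene
    gene_b: str                  # LOF partner
    coefficient: float           # negative = carriers more essential
    t_p: float = float("nan")
    q: float = float("nan")
    me_p: float | None = None
    is_paralog: bool | None = None
    phylo_distance: float | None = None
    prevalence: float = float("nan")
    stages: list[str] = field(default_factory=lambda: ["lasso"])


def _candidates_frame(cands: list[SLCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": c.gene_a, "gene_b": c.gene_b, "coefficient": c.coefficient,
        "t_p": c.t_p, "q": c.q, "me_p": c.me_p, "is_paralog": c.is_paralog,
        "phylo_distance": c.phylo_distance, "prevalence": c.prevalence,
        "stages": "+".join(c.stages),
    } for c in cands])


def prevalence_filter(lof: pd.DataFrame,
                      band: tuple[float, float] = (0.03, 0.70)) -> pd.DataFrame:
    prev = lof.mean(axis=1)
    keep = lof.index[(prev >= band[0]) & (prev <= band[1])]
    stage_log("sl.prevalence", n_in=lof.shape[0], n_kept=len(keep), band=band)
    return lof.loc[keep]


def lasso_sl(emap: EssentialityMap, lof: pd.DataFrame, folds: int = 5,
             coef_threshold: float = 0.3, q_threshold: float = 0.01,
             prevalence_band: tuple[float, float] = (0.03, 0.70),
             seed: int = 0) -> list[SLCandidate]:
    """Lasso + Welch-t confirmation of (essentiality gene, LOF gene) pairs."""
    samples = emap.values.columns.intersection(lof.columns)
    if len(samples) < 50:
        raise ValueError("need at least 50 shared samples")
    lof = prevalence_filter(lof.loc[:, samples], prevalence_band)
    X = lof.T.to_numpy(float)
    cands: list[SLCandidate] = []
    for g, row in emap.values.loc[:, samples].iterrows():
        y = row.to_numpy(float)
        if np.std(y) == 0:
            stage_log("sl.lasso", gene=g, skipped="zero-variance scores")
            continue
        model = LassoCV(cv=folds, random_state=seed, alphas=100).fit(X, y)
        beta = model.coef_
        for j in np.flatnonzero((beta < -coef_threshold) & (lof.index != g)):
            b = lof.index[j]
            carrier = X[:, j] > 0
            t = stats.ttest_ind(y[carrier], y[~carrier], equal_var=False)
            cands.append(SLCandidate(g, b, float(beta[j]), t_p=float(t.pvalue),
                                     prevalence=float(carrier.mean())))
    if cands:
        qs = multipletests([c.t_p for c in cands], method="fdr_bh")[1]
        for c, q in zip(cands, qs):
            c.q = float(q)
        cands = [c for c in cands if c.q < q_threshold]
    stage_log("sl.lasso", n_genes=emap.values.shape[0],
              coef_threshold=coef_threshold, q_threshold=q_threshold,
              n_candidates=len(cands))
    return cands


def _me_objective(cover: np.ndarray, w: np.ndarray) -> float:
    k = cover.sum(axis=0)
    covered = k >= 1
    return float(np.sum(w[covered] * (2.0 - k[covered])))


def _greedy_me(lof_arr: np.ndarray, w: np.ndarray, max_set: int):
    """Multi-start greedy: grow a set from every seed gene, keep the best
    prefix seen anywhere.  Exhaustive for max_set <= 2; a (stronger) greedy
    heuristic beyond that."""
    m = lof_arr.shape[0]
    best_score, best_set = 0.0, []
    for start in range(m):
        cur = [start]
        score = _me_objective(lof_arr[cur], w)
        if score > best_score:
            best_score, best_set = score, list(cur)
        remaining = [j for j in range(m) if j != start]
        while len(cur) < max_set and remaining:
            gains = [_me_objective(lof_arr[cur + [j]], w) for j in remaining]
            j_best = int(np.argmax(gains))
            cur.append(remaining.pop(j_best))
            if gains[j_best] > best_score:
                best_score, best_set = gains[j_best], list(cur)
    return best_set, best_score


def mutual_exclusivity(weights: pd.Series, lof: pd.DataFrame, max_set: int = 10,
                       n_perm: int = 100, seed: int = 0):
    """Greedy mutually-exclusive gene set maximizing weighted exact coverage.

    ``weights`` is per-sample (conventionally negated essentiality).  The
    permutation P shuffles weights across samples and uses the +1 correction,
    so P is never 0.  Returns (gene list, objective, P).
    """
    if not (lof.to_numpy() != 0).any():
        raise ValueError("all-zero LOF matrix")
    samples = weights.index
    arr = lof.loc[:, samples].to_numpy(float)
    w = weights.to_numpy(float)
    chosen, score = _greedy_me(arr, w, max_set)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, s = _greedy_me(arr, rng.permutation(w), max_set)
        if s >= score:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return [lof.index[i] for i in chosen], score, float(p)


def me_filter(cands: list[SLCandidate], emap: EssentialityMap,
              lof: pd.DataFrame, max_set: int = 10, n_perm: int = 100,
              p_threshold: float = 0.01, seed: int = 0) -> list[SLCandidate]:
    """Keep pairs whose partner lands in a significant mutually-exclusive set
    for the target gene (greedy search over that gene's candidate partners)."""
    by_a: dict[str, list[SLCandidate]] = {}
    for c in cands:
        by_a.setdefault(c.gene_a, []).append(c)
    kept = []
    for a, group in by_a.items():
        partners = [c.gene_b for c in group]
        weights = -emap.values.loc[a]
        genes, _, p = mutual_exclusivity(weights, lof.loc[partners],
                                         max_set=max_set, n_perm=n_perm,
                                         seed=seed)
        for c in group:
            if c.gene_b in genes and p < p_threshold:
                c.me_p = p
                c.stages.append("mutual_exclusivity")
                kept.append(c)
    stage_log("sl.mutual_exclusivity", n_in=len(cands), n_kept=len(kept),
              p_threshold=p_threshold, n_perm=n_perm)
    return kept


def paralog_filter(cands: list[SLCandidate], paralog_table: pd.DataFrame,
                   dist_threshold: float = 1.5) -> list[SLCandidate]:
    """Keep annotated paralog pairs OR pairs with phylogenetic distance
    strictly below the threshold; annotate survivors."""
    need = {"gene_a", "gene_b", "is_paralog", "phylo_distance"}
    if not need.issubset(paralog_table.columns):
        raise ValueError(f"paralog table needs columns {sorted(need)}")
    idx = {}
    for _, row in paralog_table.iterrows():
        key = frozenset((row["gene_a"], row["gene_b"]))
        idx[key] = (bool(row["is_paralog"]), row["phylo_distance"])
    kept = []
    for c in cands:
        is_par, dist = idx.get(frozenset((c.gene_a, c.gene_b)), (False, np.nan))
        c.is_paralog = is_par
        c.phylo_distance = None if pd.isna(dist) else float(dist)
        if is_par or (c.phylo_distance is not None
                      and c.phylo_distance < dist_threshold):
            c.stages.append("paralog")
            kept.append(c)
    stage_log("sl.paralog", n_in=len(cands), n_kept=len(kept),
              dist_threshold=dist_threshold)
    return kept


def sl_funnel(emap: EssentialityMap, lof: pd.DataFrame,
              paralog_table: pd.DataFrame, config: RunConfig | None = None):
    """Lasso -> mutual exclusivity -> paralog funnel with per-stage counts."""
    cfg = config or RunConfig()
    s1 = lasso_sl(emap, lof, folds=cfg.sl_folds,
                  coef_threshold=cfg.sl_coef_threshold,
                  q_threshold=cfg.sl_q_threshold,
                  prevalence_band=cfg.prevalence_band, seed=cfg.seed)
    s2 = me_filter(s1, emap, lof, max_set=cfg.me_max_set, n_perm=cfg.me_n_perm,
                   p_threshold=cfg.me_p_threshold, seed=cfg.seed)
    s3 = paralog_filter(s2, paralog_table, cfg.paralog_dist_threshold)
    counts = {"lasso": len(s1), "mutual_exclusivity": len(s2), "paralog": len(s3)}
    stage_log("sl.funnel", **counts)
    return _candidates_frame(s3), counts
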