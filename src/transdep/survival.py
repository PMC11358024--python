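"""Survival and response associations for dependency maps.

The core loop dichotomizes each gene's dependency scores at the maximally
selected rank statistic (the cutpoint maximizing the standardized log-rank
statistic, with a permutation max-statistic P that corrects for the
selection), evaluates the split by log-rank and a Cox proportional-hazards
model (Efron ties, optional lineage strata), and controls BH-FDR across
genes at 0.2.  HR > 1 for the high-dependency (more negative score) group
means a worse expected outcome.

Also here: the predicted-synthetic-lethal carrier survival contrast, drug
response association (Wilcoxon / Pearson / ROC-AUC with the -0.5
sensitivity cutoff), top-variance-dependency subtype classification by LDA
with leave-one-out CV, and one-sided Fisher enrichment of variants in the
most-dependent patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from statsmodels.stats.multitest import multipletests

from .config import RunConfig, stage_log
from .containers import EssentialityMap


# ------------------------------------------------------------- log-rank ---

def _logrank_terms(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    """O-E and variance for the log-rank test of group vs rest.

    Standard hypergeometric accumulation over distinct event times.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(bool), group[order].astype(float)
    n = len(t)
    # row i is the first of its distinct-time block
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, n]))
    at_risk = n - starts                                  # N_j
    rev = np.cumsum(g[::-1])[::-1]
    n1 = rev[starts]                                      # in-group at risk
    d = np.bincount(block, weights=e, minlength=len(starts))
    o1 = np.bincount(block, weights=e * g, minlength=len(starts))
    frac = n1 / at_risk
    o_minus_e = float(np.sum(o1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1 - frac) * (at_risk - d) / np.maximum(at_risk - 1, 1)
    v[at_risk <= 1] = 0.0
    return o_minus_e, float(v.sum())


def logrank(time_a, event_a, time_b, event_b):
    """Two-group log-rank test.

    Returns (O-E for group A, variance, chi-square statistic, P).
    """
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, int), np.asarray(event_b, int)
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("empty group")
    time = np.r_[time_a, time_b]
    event = np.r_[event_a, event_b]
    group = np.r_[np.ones(len(time_a)), np.zeros(len(time_b))]
    o_minus_e, var = _logrank_terms(time, event, group)
    chi2 = o_minus_e ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return o_minus_e, var, float(chi2), p


# ---------------------------------------------------------------- maxstat ---

def _scan_z(time, event, g_cols):
    """Z statistics for each column of g_cols (n, K)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(float)
    g = g_cols[order].astype(float)
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, n]))
    at_risk = (n - starts).astype(float)
    d = np.bincount(block, weights=e, minlength=len(starts))

    rev = np.cumsum(g[::-1], axis=0)[::-1]
    n1 = rev[starts]                                       # (J, K)
    # per-block in-group events: segment sums of e * g
    eg = e[:, None] * g
    cum = np.cumsum(eg, axis=0)
    ends = np.r_[starts[1:], n] - 1
    seg = cum[ends]
    seg[1:] -= cum[ends[:-1]]
    o1 = seg                                               # (J, K)

    frac = n1 / at_risk[:, None]
    u = (o1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (d[:, None] * frac * (1 - frac) *
             ((at_risk - d) / np.maximum(at_risk - 1, 1))[:, None])
    v[at_risk <= 1] = 0.0
    var = v.sum(axis=0)
    z = np.zeros_like(u)
    ok = var > 0
    z[ok] = u[ok] / np.sqrt(var[ok])
    return z


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float        # max |standardized log-rank|
    p: float                # permutation max-statistic P (+1 corrected)
    n_cutpoints: int


def maxstat_cutpoint(score: pd.Series | np.ndarray, surv: pd.DataFrame,
                     qrange: tuple[float, float] = (0.1, 0.9),
                     n_perm: int = 200, seed: int = 0,
                     perm_chunk: int = 64) -> MaxstatResult:
    """Maximally selected rank statistic with a permutation-calibrated P.

    Scans unique score values whose split leaves both groups within
    ``qrange`` proportions; the P value permutes scores against (time,
    event) and compares the permuted *maximum* statistic with the observed
    one, so the selection of the cutpoint is corrected for.
    """
    if isinstance(score, pd.Series):
        score = score.loc[surv.index].to_numpy(float)
    else:
        score = np.asarray(score, float)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    n = len(score)
    if n < 10 or event.sum() == 0:
        raise ValueError("need >= 10 samples and at least one event")

    uniq = np.unique(score)
    frac_low = np.searchsorted(np.sort(score), uniq, side="right") / n
    ok = (frac_low >= qrange[0]) & (frac_low <= qrange[1])
    cuts = uniq[ok]
    if len(cuts) == 0:
        raise ValueError("no admissible cutpoint within qrange")

    g = (score[:, None] > cuts[None, :]).astype(float)     # high-score group
    z = _scan_z(time, event, g)
    best = int(np.argmax(np.abs(z)))
    observed = float(np.abs(z[best]))

    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_perm:
        m = min(perm_chunk, n_perm - done)
        maxes = np.empty(m)
        for i in range(m):
            perm = rng.permutation(n)
            maxes[i] = np.max(np.abs(_scan_z(time, event, g[perm])))
        hits += int(np.sum(maxes >= observed))
        done += m
    p = (hits + 1) / (n_perm + 1)
    return MaxstatResult(float(cuts[best]), observed, float(p), len(cuts))


# -------------------------------------------------------------------- Cox ---

def _score_test(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron-ties Cox score test of beta = 0 for a single covariate; returns P."""
    u, info = _score_parts(x, time, event)
    if info <= 0:
        return 1.0
    return float(stats.chi2.sf(u * u / info, df=1))


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    score_p: float
    converged: bool
    flag: str = ""


def cox_hr(x: pd.Series | np.ndarray, surv: pd.DataFrame,
           strata: pd.Series | None = None) -> CoxResult:
    """Cox proportional-hazards HR for one covariate (Efron ties), with Wald
    and beta=0 score-test P; stratified baseline when ``strata`` is given.

    Monotone-likelihood / non-convergence cases come back flagged, HR = nan.
    """
    if isinstance(x, pd.Series):
        x = x.loc[surv.index].to_numpy(float)
    else:
        x = np.asarray(x, float)
    df = pd.DataFrame({"x": x, "time": surv["time"].to_numpy(float),
                       "event": surv["event"].to_numpy(int)})
    kwargs = {}
    if strata is not None:
        df["stratum"] = strata.loc[surv.index].to_numpy()
        kwargs["strata"] = ["stratum"]
    if strata is None:
        score_p = _score_test(x, df["time"].to_numpy(), df["event"].to_numpy())
    else:
        score_p = _stratified_score_test(df)
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event", **kwargs)
    except (ConvergenceError, Exception) as err:  # lifelines raises various
        return CoxResult(np.nan, np.nan, np.nan, np.nan, score_p, False,
                         flag=f"fit failed: {type(err).__name__}")
    s = cph.summary.loc["x"]
    return CoxResult(float(np.exp(s["coef"])),
                     float(np.exp(s["coef lower 95%"])),
                     float(np.exp(s["coef upper 95%"])),
                     float(s["p"]), score_p, True)


def _stratified_score_test(df: pd.DataFrame) -> float:
    u_tot, i_tot = 0.0, 0.0
    for _, sub in df.groupby("stratum"):
        ui = _score_parts(sub["x"].to_numpy(float), sub["time"].to_numpy(float),
                          sub["event"].to_numpy(int))
        u_tot += ui[0]
        i_tot += ui[1]
    if i_tot <= 0:
        return 1.0
    return float(stats.chi2.sf(u_tot ** 2 / i_tot, df=1))


def _score_parts(x, time, event):
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order].astype(bool), x[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n]
    u, info = 0.0, 0.0
    sx = np.cumsum(xv[::-1])[::-1]
    sx2 = np.cumsum((xv * xv)[::-1])[::-1]
    for s, epos in zip(starts, ends):
        dead = np.flatnonzero(e[s:epos]) + s
        d = len(dead)
        if d == 0:
            continue
        xd = xv[dead]
        s0r, s1r, s2r = float(n - s), float(sx[s]), float(sx2[s])
        s1d, s2d = float(xd.sum()), float((xd * xd).sum())
        u += s1d
        for l in range(d):
            s0 = s0r - l
            s1 = s1r - (l / d) * s1d
            s2 = s2r - (l / d) * s2d
            u -= s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
    return u, info


# --------------------------------------------------------------- pfi scan ---

def pfi_scan(emap: EssentialityMap, surv: pd.DataFrame,
             lineage: pd.Series | None = None,
             config: RunConfig | None = None) -> pd.DataFrame:
    """Per-gene maxstat -> log-rank -> Cox association with outcome, BH-FDR.

    Lineages on the configured exclusion list and strata below the minimum
    size are dropped before testing.  The permutation-corrected maxstat P
    feeds the BH adjustment; HRs (high-dependency group = scores below the
    cutpoint) are fit for genes discovered at the FDR threshold.
    """
    cfg = config or RunConfig()
    samples = emap.values.columns.intersection(surv.index)
    strata = None
    if lineage is not None:
        lin = lineage.loc[samples]
        keep = ~lin.isin(cfg.excluded_lineages)
        sizes = lin[keep].value_counts()
        small = sizes.index[sizes < cfg.min_stratum_n]
        if len(small):
            stage_log("survival.pfi", excluded_small_strata=list(small))
        keep &= ~lin.isin(small)
        samples = samples[keep.to_numpy()]
        strata = lineage.loc[samples]
    sv = surv.loc[samples]

    rows = []
    for i, (g, row) in enumerate(emap.values.loc[:, samples].iterrows()):
        ms = maxstat_cutpoint(row, sv, qrange=cfg.maxstat_qrange,
                              n_perm=cfg.maxstat_n_perm, seed=cfg.seed + i)
        high_dep = row.loc[samples] <= ms.cutpoint       # more negative = dependent
        oe, var, chi2, lr_p = logrank(sv.loc[high_dep.to_numpy(), "time"],
                                      sv.loc[high_dep.to_numpy(), "event"],
                                      sv.loc[~high_dep.to_numpy(), "time"],
                                      sv.loc[~high_dep.to_numpy(), "event"])
        rows.append({"gene": g, "cutpoint": ms.cutpoint, "maxstat": ms.statistic,
                     "perm_p": ms.p, "logrank_chi2": chi2, "logrank_p": lr_p,
                     "o_minus_e": oe})
    tab = pd.DataFrame(rows).set_index("gene")
    tab["q"] = multipletests(tab["perm_p"], method="fdr_bh")[1]
    tab["hr"] = np.nan
    tab["hr_ci_low"] = np.nan
    tab["hr_ci_high"] = np.nan
    for g in tab.index[tab["q"] < cfg.pfi_fdr]:
        row = emap.values.loc[g, samples]
        group = (row <= tab.loc[g, "cutpoint"]).astype(float)
        res = cox_hr(group, sv, strata=strata)
        tab.loc[g, ["hr", "hr_ci_low", "hr_ci_high"]] = (res.hr, res.ci_low,
                                                         res.ci_high)
    n_disc = int((tab["q"] < cfg.pfi_fdr).sum())
    stage_log("survival.pfi", n_genes=len(tab), fdr=cfg.pfi_fdr,
              n_discoveries=n_disc)
    return tab


def sl_survival(emap: EssentialityMap, lof: pd.DataFrame,
                pair: tuple[str, str], surv: pd.DataFrame,
                strata: pd.Series | None = None,
                carrier_quantile: float = 0.25) -> CoxResult:
    """Outcome contrast for predicted-SL carriers of pair (A, B): samples
    with an LOF event in B AND predicted dependency of A below the given
    quantile, vs everyone else (Cox, optional lineage strata)."""
    a, b = pair
    samples = emap.values.columns.intersection(surv.index)
    scores = emap.values.loc[a, samples]
    thr = scores.quantile(carrier_quantile)
    carriers = (lof.loc[b, samples] > 0) & (scores <= thr)
    if carriers.sum() < 10:
        raise ValueError(f"carrier group too small ({int(carriers.sum())})")
    stage_log("survival.sl", pair=f"{a}|{b}",
              rule=f"LOF({b}) & score({a}) <= q{carrier_quantile}",
              n_carriers=int(carriers.sum()))
    return cox_hr(carriers.astype(float), surv.loc[samples],
                  strata=None if strata is None else strata)


# ------------------------------------------------------ response & typing ---

def response_assoc(scores: pd.Series, response: pd.Series,
                   kind: str = "binary", min_n: int = 20,
                   cutoff: float = -0.5) -> dict:
    """Associate per-sample essentiality with treatment response.

    binary: two-sided Wilcoxon rank-sum plus ROC-AUC with sensitive = lower
    score (negative scores mean dependency, so -scores rank the sensitive
    class first).  continuous: Pearson r and P.
    """
    shared = scores.index.intersection(response.index)
    s, r = scores.loc[shared], response.loc[shared]
    if len(shared) < min_n:
        raise ValueError(f"need >= {min_n} samples, got {len(shared)}")
    if kind == "binary":
        if r.nunique() < 2:
            raise ValueError("single-class response")
        pos, neg = s[r == 1], s[r == 0]
        w = stats.ranksums(pos, neg)
        auc = float(roc_auc_score(r.to_numpy(int), -s.to_numpy(float)))
        return {"wilcoxon_p": float(w.pvalue), "auc": auc,
                "n": len(shared), "cutoff": cutoff}
    if kind == "continuous":
        pr = stats.pearsonr(s.to_numpy(float), r.to_numpy(float))
        return {"pearson_r": float(pr.statistic), "p": float(pr.pvalue),
                "n": len(shared)}
    raise ValueError(f"unknown kind {kind!r}")


def dep100_subtype(emap: EssentialityMap, labels: pd.Series, top_k: int = 100,
                   min_class: int = 5) -> tuple[list[str], pd.Series]:
    """Top-variance dependency signature + LDA leave-one-out one-vs-rest AUC.

    Selects the ``top_k`` most variable genes across the cohort, fits a
    linear discriminant per held-out sample and reports a per-class ROC-AUC.
    Classes below ``min_class`` samples are skipped (logged).
    """
    lab = labels.loc[emap.values.columns]
    sizes = lab.value_counts()
    skip = sizes.index[sizes < min_class]
    if len(skip):
        stage_log("survival.dep100", skipped_classes=list(skip))
    keep = ~lab.isin(skip)
    lab = lab[keep]
    vals = emap.values.loc[:, keep.index[keep]]
    k = min(top_k, vals.shape[0])
    if k < top_k:
        stage_log("survival.dep100", warning=f"top_k clamped to {k}")
    genes = list(vals.var(axis=1).sort_values(ascending=False).index[:k])
    X = vals.loc[genes].T.to_numpy(float)
    y = lab.to_numpy()
    proba = cross_val_predict(LinearDiscriminantAnalysis(), X, y,
                              cv=LeaveOneOut(), method="predict_proba")
    classes = np.unique(y)
    aucs = {}
    for i, c in enumerate(classes):
        aucs[c] = float(roc_auc_score((y == c).astype(int), proba[:, i]))
    stage_log("survival.dep100", n_genes=k, n_classes=len(classes),
              aucs={c: round(a, 3) for c, a in aucs.items()})
    return genes, pd.Series(aucs)


def driver_enrichment(emap: EssentialityMap, variants: dict[str, pd.DataFrame],
                      gene: str, top_frac: float = 0.10,
                      prev_min: dict | None = None) -> pd.DataFrame:
    """One-sided Fisher enrichment of variants in the most-dependent patients.

    The dependent group is the lowest ``top_frac`` of samples by the gene's
    score; per variant class, only variants above the class prevalence floor
    are tested (alternative = greater), with BH within class.
    """
    prev_min = prev_min or {"mutation": 0.05, "deletion": 0.10,
                            "amplification": 0.10}
    scores = emap.values.loc[gene]
    n_dep = max(int(round(top_frac * len(scores))), 1)
    dep_samples = scores.nsmallest(n_dep).index
    dep_mask = scores.index.isin(dep_samples)

    rows = []
    for cls, mat in variants.items():
        floor = prev_min.get(cls, 0.0)
        mat = mat.loc[:, scores.index]
        prev = mat.mean(axis=1)
        for v in mat.index[prev > floor]:
            carrier = mat.loc[v].to_numpy() > 0
            a = int(np.sum(carrier & dep_mask))
            b = int(np.sum(~carrier & dep_mask))
            c = int(np.sum(carrier & ~dep_mask))
            d = int(np.sum(~carrier & ~dep_mask))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append({"class": cls, "variant": v, "prevalence": float(prev[v]),
                         "n_dep_carrier": a, "p": float(p)})
    tab = pd.DataFrame(rows)
    if len(tab) == 0:
        stage_log("survival.driver", warning="no qualifying variants")
        return tab
    tab["q"] = np.nan
    for cls in tab["class"].unique():
        m = tab["class"] == cls
        tab.loc[m, "q"] = multipletests(tab.loc[m, "p"], method="fdr_bh")[1]
    stage_log("survival.driver", gene=gene, n_tested=len(tab))
    return tab.set_index(["class", "variant"])
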