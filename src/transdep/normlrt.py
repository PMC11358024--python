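"""Selective-dependency scoring by the normality likelihood ratio test.

A gene that is essential only in a biomarker-defined subset of samples has
a skewed, heavy-tailed essentiality profile; a uniformly (non)essential gene
looks Gaussian.  NormLRT scores each gene by twice the log-likelihood gap
between a skew-t fit and a normal fit of its score vector, clamped at zero.
The skew-t is the Azzalini location-scale family

    f(x) = (2/w) * t_nu(z) * T_{nu+1}(a z sqrt((nu+1)/(nu+z^2))),  z=(x-xi)/w

with location xi, scale w, slant a and df nu in [2.1, 100]; it contains the
t (a=0) and approaches the normal as nu grows, so the LRT is only a ranking
statistic (no closed-form null).  Because the statistic grows roughly
linearly with sample size, scores from cohorts of different sizes are put on
one scale by a bootstrap: resample the measured cohort to the target size,
refit, and regress source scores on mean resampled scores through the
origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import stage_log
from .containers import EssentialityMap

DF_BOUNDS = (2.1, 100.0)


def _skewt_negll(theta: np.ndarray, x: np.ndarray) -> float:
    xi, logw, slant, nu = theta
    w = np.exp(logw)
    z = (x - xi) / w
    arg = slant * z * np.sqrt((nu + 1.0) / (nu + z * z))
    ll = (np.log(2.0) - logw + stats.t.logpdf(z, nu)
          + stats.t.logcdf(arg, nu + 1.0))
    return -float(np.sum(ll))


def _normal_loglik(x: np.ndarray) -> float:
    n = x.size
    s2 = float(np.var(x))
    s2 = max(s2, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


@dataclass
class NormLrtScore:
    gene: str
    loglik_normal: float
    loglik_skewt: float
    lrt: float
    converged: bool
    df: float
    skew: float
    rescaled: float | None = None


def normlrt(x: np.ndarray | pd.Series, gene: str = "",
            df_bounds: tuple[float, float] = DF_BOUNDS) -> NormLrtScore:
    """NormLRT for one gene's score vector (needs >= 30 finite values).

    The skew-t likelihood is maximized from three starts (symmetric t,
    left-skewed, right-skewed); if no start converges the best achieved
    likelihood is still reported, flagged.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError("NormLRT needs at least 30 finite values")
    ll_norm = _normal_loglik(x)

    mu, sd = float(x.mean()), float(x.std())
    sd = max(sd, 1e-6)
    bounds = [(None, None), (np.log(sd) - 6, np.log(sd) + 6), (-50.0, 50.0),
              df_bounds]
    best = None
    converged = False
    for slant0 in (0.0, -5.0, 5.0):
        theta0 = np.array([mu, np.log(sd), slant0, 10.0])
        res = optimize.minimize(_skewt_negll, theta0, args=(x,),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    ll_st = -float(best.fun)
    lrt = 2.0 * (ll_st - ll_norm)
    if lrt < 0:
        stage_log("normlrt.clamp", gene=gene, raw=round(lrt, 4))
        lrt = 0.0
    return NormLrtScore(gene, ll_norm, ll_st, lrt, converged,
                        df=float(best.x[3]), skew=float(best.x[2]))


def normlrt_map(emap: EssentialityMap,
                df_bounds: tuple[float, float] = DF_BOUNDS) -> pd.DataFrame:
    rows = []
    for g, row in emap.values.iterrows():
        s = normlrt(row.to_numpy(), gene=g, df_bounds=df_bounds)
        rows.append((g, s.lrt, s.loglik_normal, s.loglik_skewt, s.df, s.skew,
                     s.converged))
    out = pd.DataFrame(rows, columns=["gene", "lrt", "loglik_normal",
                                      "loglik_skewt", "df", "skew",
                                      "converged"]).set_index("gene")
    stage_log("normlrt.map", n_genes=len(out),
              median_lrt=round(float(out["lrt"].median()), 3))
    return out


@dataclass
class BootstrapScaling:
    source_n: int
    target_n: int
    table: pd.DataFrame  # index gene, columns lrt_source, lrt_target_mean
    slope: float
    n_boot: int


def bootstrap_scaling(measured: EssentialityMap, target_n: int,
                      n_boot: int = 50, seed: int = 0,
                      genes: list[str] | None = None) -> BootstrapScaling:
    """Scaling factor between cohort sizes: resample columns to ``target_n``,
    recompute each gene's NormLRT, average over ``n_boot`` draws, and fit the
    slope of source score on mean resampled score through the origin.

    Source scores rescale a larger cohort's statistics back onto the source
    scale (``rescaled = slope * lrt_target``); a statistic of 0 maps to 0.
    """
    if target_n < 30:
        raise ValueError("target_n must be >= 30")
    rng = np.random.default_rng(seed)
    vals = measured.values if genes is None else measured.values.loc[genes]
    source_n = vals.shape[1]
    src, tgt = [], []
    for g, row in vals.iterrows():
        x = row.to_numpy(float)
        src.append(normlrt(x, gene=g).lrt)
        boots = []
        for _ in range(n_boot):
            xb = x[rng.integers(0, source_n, size=target_n)]
            boots.append(normlrt(xb, gene=g).lrt)
        tgt.append(float(np.mean(boots)))
    src_a, tgt_a = np.asarray(src), np.asarray(tgt)
    denom = float(tgt_a @ tgt_a)
    if denom <= 0:
        raise ValueError("degenerate bootstrap: all resampled scores are 0")
    slope = float(src_a @ tgt_a / denom)
    table = pd.DataFrame({"lrt_source": src_a, "lrt_target_mean": tgt_a},
                         index=vals.index)
    stage_log("normlrt.bootstrap", source_n=source_n, target_n=target_n,
              n_boot=n_boot, slope=round(slope, 5))
    return BootstrapScaling(source_n, target_n, table, slope, n_boot)


def ssd_table(map_a: EssentialityMap, map_b: EssentialityMap,
              lrt_threshold: float = 100.0) -> tuple[pd.DataFrame, float]:
    """Joined per-gene NormLRT ranking for two cohorts plus the cross-cohort
    Pearson r over genes exceeding ``lrt_threshold`` in either cohort."""
    shared = map_a.values.index.intersection(map_b.values.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    ta = normlrt_map(EssentialityMap(map_a.values.loc[shared], map_a.provenance))
    tb = normlrt_map(EssentialityMap(map_b.values.loc[shared], map_b.provenance))
    out = pd.DataFrame({
        "lrt_a": ta["lrt"], "lrt_b": tb["lrt"],
        "rank_a": ta["lrt"].rank(ascending=False),
        "rank_b": tb["lrt"].rank(ascending=False),
    })
    sel = out[(out["lrt_a"] > lrt_threshold) | (out["lrt_b"] > lrt_threshold)]
    if len(sel) >= 3 and sel["lrt_a"].std() > 0 and sel["lrt_b"].std() > 0:
        r = float(np.corrcoef(sel["lrt_a"], sel["lrt_b"])[0, 1])
    else:
        r = float("nan")
    stage_log("normlrt.ssd", n_shared=len(shared), n_selected=len(sel),
              r=round(r, 4) if np.isfinite(r) else "nan")
    return out, r
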