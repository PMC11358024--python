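"""Dual-knockout CRISPR screen analysis: counting, TMM, L2FC, GI scores.

Reads carry a 4-guide array between fixed flanks; only exact array matches
are counted.  Libraries are scale-normalized by the trimmed mean of
M-values (TMM), log2 fold changes compare each day-14 replicate with the
plasmid library on pseudo-counted proportions, and genetic interactions are
scored as observed-minus-expected depletion: construct L2FCs are z-scored
against the NTxNT (non-targeting) null, the expected z of a dual knockout
is the sum of its two single-knockout z values (multiple single-KO
constructs per gene collapse to the median), and the observed-minus-
expected differences are z-scored across all DKOs.  diff_z below -2 calls
synthetic lethality; above +2, buffering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import stage_log
from .simulate import NT, ScreenDesign


def count_guides(reads, design: ScreenDesign, flank5: str, flank3: str,
                 strict: bool = False) -> tuple[pd.Series, int]:
    """Exact-match guide-array counting for one sample.

    ``reads`` yields (read_id, sequence).  The sequence between the flanks is
    matched exactly to the library's concatenated arrays; anything else goes
    to the unmapped tally.  Returns (counts, n_unmapped).
    """
    lookup = {design.array_seq(cid): cid for cid in design.construct_ids}
    counts = pd.Series(0, index=design.construct_ids, dtype=int)
    unmapped = 0
    total = 0
    missing_flank = 0
    for _, seq in reads:
        total += 1
        i = seq.find(flank5)
        if i < 0:
            missing_flank += 1
            unmapped += 1
            continue
        j = seq.find(flank3, i + len(flank5))
        if j < 0:
            missing_flank += 1
            unmapped += 1
            continue
        cid = lookup.get(seq[i + len(flank5):j])
        if cid is None:
            unmapped += 1
        else:
            counts[cid] += 1
    if total == 0:
        stage_log("screen.count", warning="empty FASTQ")
    elif missing_flank > 0.9 * total:
        msg = f"flanks missing in {missing_flank}/{total} reads"
        if strict:
            raise ValueError(msg)
        stage_log("screen.count", warning=msg)
    stage_log("screen.count", n_reads=total, n_unmapped=unmapped)
    return counts, unmapped


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05, ref: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, normalized to geometric mean 1.

    Per sample vs the reference: M and A values over constructs nonzero in
    both, doubly trimmed (``trim_m`` on each M tail, ``trim_a`` on each A
    tail), averaged with inverse asymptotic binomial-variance weights; the
    factor is 2^mean.  The reference defaults to the sample whose
    upper-quartile proportion is closest to the across-sample mean.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    if ref is None:
        uq = counts.apply(lambda c: np.quantile(c[c > 0] / c.sum(), 0.75))
        ref = (uq - uq.mean()).abs().idxmin()
    r = counts[ref].to_numpy(float)
    nr = float(lib[ref])

    logf = {}
    for s in counts.columns:
        if s == ref:
            logf[s] = 0.0
            continue
        x = counts[s].to_numpy(float)
        nx = float(lib[s])
        keep = (x > 0) & (r > 0)
        xs, rs = x[keep], r[keep]
        m = np.log2((xs / nx) / (rs / nr))
        a = 0.5 * np.log2((xs / nx) * (rs / nr))
        w = (nx - xs) / (nx * xs) + (nr - rs) / (nr * rs)
        lo_m, hi_m = np.quantile(m, (trim_m, 1 - trim_m))
        lo_a, hi_a = np.quantile(a, (trim_a, 1 - trim_a))
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            sel = np.ones_like(m, dtype=bool)
        logf[s] = float(np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()})[counts.columns]
    f = f / np.exp(np.log(f).mean())  # geometric mean 1
    stage_log("screen.tmm", ref=ref, factors={s: round(v, 4) for s, v in f.items()})
    return f


def l2fc(counts: pd.DataFrame, factors: pd.Series, plasmid: str = "plasmid",
         pseudo: float = 0.5) -> pd.DataFrame:
    """Per-construct per-replicate log2 fold change vs the plasmid library,
    with replicate mean and one-sample t statistic.

    L2FC = log2((x + pseudo) / (f * N) over (p + pseudo) / (f_p * N_p)) on
    effective (TMM-scaled) library sizes; constructs absent from the plasmid
    are flagged low-confidence.
    """
    lib = counts.sum(axis=0).astype(float) * factors
    reps = [c for c in counts.columns if c != plasmid]
    base = (counts[plasmid].to_numpy(float) + pseudo) / lib[plasmid]
    out = {}
    for s in reps:
        prop = (counts[s].to_numpy(float) + pseudo) / lib[s]
        out[s] = np.log2(prop / base)
    tab = pd.DataFrame(out, index=counts.index)
    tab["mean_l2fc"] = tab[reps].mean(axis=1)
    if len(reps) > 1:
        sd = tab[reps].std(axis=1, ddof=1)
        tab["t"] = tab["mean_l2fc"] / (sd / np.sqrt(len(reps))).replace(0, np.nan)
    else:
        tab["t"] = np.nan
    tab["low_confidence"] = counts[plasmid] == 0
    stage_log("screen.l2fc", n_constructs=len(tab), n_reps=len(reps),
              n_low_conf=int(tab["low_confidence"].sum()))
    return tab


@dataclass
class GIRecord:
    gene_a: str
    gene_b: str
    observed_z: float
    expected_z: float
    difference: float
    diff_z: float = float("nan")
    call: str = "none"


def gi_scores(l2fc_table: pd.DataFrame, design: ScreenDesign,
              call_z: float = 2.0, min_nt: int = 10) -> pd.DataFrame:
    """Expected-vs-observed genetic interaction z-scores for all DKO pairs."""
    tab = design.table
    val = l2fc_table.loc[tab.index, "mean_l2fc"]
    nt_mask = tab["cls"] == "NTxNT"
    if nt_mask.sum() < min_nt:
        raise ValueError(f"only {int(nt_mask.sum())} NTxNT constructs "
                         f"(need >= {min_nt}) for the z-scoring null")
    mu, sd = val[nt_mask].mean(), val[nt_mask].std()
    if sd == 0:
        raise ValueError("degenerate NTxNT distribution")
    z = (val - mu) / sd

    single = {}
    for cid in tab.index[tab["cls"] == "singleKO"]:
        gene = tab.loc[cid, "gene_a"] if tab.loc[cid, "gene_a"] != NT \
            else tab.loc[cid, "gene_b"]
        single.setdefault(gene, []).append(z[cid])
    single_z = {g: float(np.median(v)) for g, v in single.items()}

    recs = []
    for cid in tab.index[tab["cls"] == "DKO"]:
        a, b = sorted((tab.loc[cid, "gene_a"], tab.loc[cid, "gene_b"]))
        if a not in single_z or b not in single_z:
            raise ValueError(f"DKO {cid!r}: missing single-KO construct")
        exp = single_z[a] + single_z[b]
        obs = float(z[cid])
        recs.append(GIRecord(a, b, obs, exp, obs - exp))
    diffs = np.array([r.difference for r in recs])
    dmu, dsd = diffs.mean(), diffs.std()
    for r in recs:
        r.diff_z = float((r.difference - dmu) / dsd) if dsd > 0 else 0.0
        if r.diff_z < -call_z:
            r.call = "synthetic_lethal"
        elif r.diff_z > call_z:
            r.call = "buffering"
    out = pd.DataFrame([vars(r) for r in recs])
    out["pair"] = out["gene_a"] + "|" + out["gene_b"]
    out = out.set_index("pair")
    stage_log("screen.gi", n_dko=len(out),
              n_sl=int((out["call"] == "synthetic_lethal").sum()),
              n_buffering=int((out["call"] == "buffering").sum()))
    return out


def screen_concordance(gi_run1: pd.DataFrame, gi_run2: pd.DataFrame) -> float:
    """Pearson r of diff_z over pairs shared between two screen runs."""
    shared = gi_run1.index.intersection(gi_run2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared pairs")
    r = float(stats.pearsonr(gi_run1.loc[shared, "diff_z"],
                             gi_run2.loc[shared, "diff_z"]).statistic)
    stage_log("screen.concordance", n_shared=len(shared), r=round(r, 4))
    return r
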