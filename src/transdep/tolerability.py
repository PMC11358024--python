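"""Therapeutic-window ranking: tumor vs matched healthy-tissue dependency.

For each tumor-type/healthy-tissue pairing, every gene's predicted scores
are compared by a Welch two-sample t-test with the sign convention t < 0
meaning stronger dependency in tumor (a wider window); BH-FDR is applied
within pairing.  Both maps must be predicted+rescaled from the same model
set so their score scales are comparable — the function refuses otherwise.
Toxicity profiling summarizes annotated target sets per healthy tissue and
contrasts them against the rest of the genome by Wilcoxon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import stage_log
from .containers import EssentialityMap


def _check_comparable(tumor_map: EssentialityMap, healthy_map: EssentialityMap):
    for m, name in ((tumor_map, "tumor"), (healthy_map, "healthy")):
        if m.provenance != "predicted+rescaled":
            raise ValueError(f"{name} map provenance is {m.provenance!r}; "
                             "window analysis needs predicted+rescaled scores")
    if (tumor_map.model_fingerprint is not None
            and healthy_map.model_fingerprint is not None
            and tumor_map.model_fingerprint != healthy_map.model_fingerprint):
        raise ValueError("maps were predicted from different model sets")


def window_scan(tumor_map: EssentialityMap, healthy_map: EssentialityMap,
                tumor_meta: pd.DataFrame, healthy_meta: pd.DataFrame,
                pairing: dict[str, str], min_side: int = 5) -> pd.DataFrame:
    """Welch t-statistics per gene per (tumor type -> healthy tissue) pairing.

    Returns a table sorted with the most-negative t (widest window) first.
    Pairings without a matched healthy tissue or with fewer than ``min_side``
    samples on either side are skipped and logged.
    """
    _check_comparable(tumor_map, healthy_map)
    genes = tumor_map.values.index.intersection(healthy_map.values.index)
    rows = []
    for ttype, tissue in pairing.items():
        t_samples = tumor_meta.index[tumor_meta["lineage"] == ttype]
        h_samples = healthy_meta.index[healthy_meta["lineage"] == tissue]
        t_samples = tumor_map.values.columns.intersection(t_samples)
        h_samples = healthy_map.values.columns.intersection(h_samples)
        if len(t_samples) < min_side or len(h_samples) < min_side:
            stage_log("tolerability.window", pairing=f"{ttype}->{tissue}",
                      skipped="side below minimum size")
            continue
        tv = tumor_map.values.loc[genes, t_samples].to_numpy(float)
        hv = healthy_map.values.loc[genes, h_samples].to_numpy(float)
        t, p = stats.ttest_ind(tv, hv, axis=1, equal_var=False)
        q = multipletests(p, method="fdr_bh")[1]
        for g, ti, pi, qi, mt, mh in zip(genes, t, p, q,
                                         tv.mean(axis=1), hv.mean(axis=1)):
            rows.append({"gene": g, "tumor_type": ttype, "healthy_tissue": tissue,
                         "t": float(ti), "p": float(pi), "q": float(qi),
                         "mean_tumor": float(mt), "mean_healthy": float(mh)})
    cols = ["gene", "tumor_type", "healthy_tissue", "t", "p", "q",
            "mean_tumor", "mean_healthy"]
    out = (pd.DataFrame(rows, columns=cols).sort_values("t")
           .reset_index(drop=True))
    stage_log("tolerability.window", n_pairings=len(pairing),
              n_rows=len(out))
    return out


def toxicity_profile(healthy_map: EssentialityMap, healthy_meta: pd.DataFrame,
                     target_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean essentiality of each annotated target set per healthy tissue,
    with a Wilcoxon comparison against all genes outside the set."""
    rows = []
    all_genes = healthy_map.values.index
    for name, genes in target_sets.items():
        genes = [g for g in genes if g in all_genes]
        if not genes:
            raise ValueError(f"target set {name!r} is empty")
        rest = all_genes.difference(genes)
        if len(rest) == 0:
            raise ValueError(f"target set {name!r} covers all genes; "
                             "comparison is degenerate")
        for tissue, samples in healthy_meta.groupby("lineage").groups.items():
            cols = healthy_map.values.columns.intersection(samples)
            in_set = healthy_map.values.loc[genes, cols].to_numpy().mean()
            per_gene_set = healthy_map.values.loc[genes, cols].mean(axis=1)
            per_gene_rest = healthy_map.values.loc[rest, cols].mean(axis=1)
            w = stats.ranksums(per_gene_set, per_gene_rest)
            rows.append({"set": name, "tissue": tissue,
                         "mean_score": float(in_set),
                         "wilcoxon_p": float(w.pvalue)})
    return pd.DataFrame(rows)
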