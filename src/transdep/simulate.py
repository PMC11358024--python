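"""Synthetic cohorts and screens with planted, exported ground truth.

The generators emulate the statistical structure of the real inputs the
pipeline was designed for: a cell-line cohort with lineage-clustered
expression and sparse linear expression->essentiality relationships; tumor
cohorts whose biopsies mix malignant and stromal signal in linear space
weighted by purity; loss-of-function (LOF) events that shift the
essentiality of a synthetic-lethal partner; healthy-tissue cohorts with a
location-scale batch offset; dual-knockout screens with fitness-dependent
guide depletion; and survival times whose hazard is linear in one gene's
latent essentiality on the log scale.

Effect sizes flow through *expression*: a planted shift of gene A's
essentiality in LOF-of-B carriers is realized by shifting the expression of
A's model features (least-norm direction), so that both the latent score and
any model-predicted score move by the planted amount.

Determinism: every generator derives an independent stream from the global
seed via ``numpy.random.SeedSequence(seed, spawn_key=(k,))``, so cohorts can
be regenerated independently and bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_log
from .containers import EssentialityMap, ExpressionMatrix

_STREAMS = {"cells": 0, "tumor": 1, "screen": 2, "reads": 3, "healthy": 4, "design": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ----------------------------------------------------------------- truth ---

@dataclass
class CohortTruth:
    """Planted ground truth exported next to every generated cohort.

    ``model_support`` maps each modeled gene to its raw-scale intercept and
    (feature, coefficient) list; essentiality = intercept + sum coef*expr.
    """

    model_support: dict = field(default_factory=dict)
    sl_pairs: list = field(default_factory=list)      # (gene_a, lof_gene_b, delta)
    gi_pairs: list = field(default_factory=list)      # (gene_a, gene_b, log2 depletion)
    purity: dict = field(default_factory=dict)
    hazard_gene: str | None = None
    seed: int = 0
    gen_params: dict = field(default_factory=dict)    # base means / lineage shifts etc.

    def to_dict(self) -> dict:
        return {
            "model_support": {
                g: {"intercept": v["intercept"], "features": [list(t) for t in v["features"]]}
                for g, v in self.model_support.items()
            },
            "sl_pairs": [list(t) for t in self.sl_pairs],
            "gi_pairs": [list(t) for t in self.gi_pairs],
            "purity": self.purity,
            "hazard_gene": self.hazard_gene,
            "seed": self.seed,
        }


# ------------------------------------------------------------ cell cohort ---

def _latent_scores(expr: pd.DataFrame, support: dict, noise_sd: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Latent essentiality of the modeled genes given raw-scale support."""
    rows = {}
    for gene, spec in support.items():
        y = np.full(expr.shape[1], spec["intercept"], dtype=float)
        for feat, coef in spec["features"]:
            y += coef * expr.loc[feat].to_numpy()
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.size)
        rows[gene] = y
    return pd.DataFrame(rows, index=expr.columns).T


def make_cell_cohort(
    n_lines: int = 100,
    n_genes: int = 500,
    n_lineages: int = 4,
    n_informative: int = 20,
    n_features: int = 5,
    noise_sd: float = 0.2,
    seed: int = 0,
    lineage_sd: float = 1.0,
    support: dict | None = None,
    self_feature_prob: float = 0.25,
):
    """Cell-line cohort: expression, measured essentiality, mutations, CNV, truth.

    Expression is simulated on the log2 scale as Normal(gene mean + lineage
    shift, 1).  For each of ``n_informative`` modeled genes, essentiality is
    a sparse linear function of ``n_features`` feature genes' expression plus
    Normal(0, noise_sd); the remaining genes are pure noise around the -0.5
    dependency cutoff so that roughly half their lines are "dependent".
    ``support`` overrides the random planted models with an explicit
    {gene: {"intercept": b0, "features": [(feat, coef), ...]}} map.
    """
    if n_lines < 20 or n_genes <= 0 or n_lineages <= 0:
        raise ValueError("need n_lines >= 20 and positive dimensions")
    if n_informative >= n_genes:
        raise ValueError("n_informative must be < n_genes")
    rng = _rng(seed, "cells")

    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"CL{i:04d}" for i in range(n_lines)]
    lineages = [f"L{i}" for i in range(n_lineages)]
    line_lineage = rng.integers(0, n_lineages, size=n_lines)

    base_mean = rng.uniform(4.0, 10.0, size=n_genes)
    lin_shift = rng.normal(0.0, lineage_sd, size=(n_lineages, n_genes))
    expr = (base_mean[None, :] + lin_shift[line_lineage] +
            rng.normal(0.0, 1.0, size=(n_lines, n_genes))).T
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    if support is None:
        modeled = list(rng.choice(genes, size=n_informative, replace=False))
        support = {}
        for g in modeled:
            feats = list(rng.choice([x for x in genes if x != g],
                                    size=n_features, replace=False))
            if n_features > 0 and rng.random() < self_feature_prob:
                feats[0] = g  # self-inclusion, as seen in real cohorts
            # keep modeled scores CERES-like (sd ~0.7 around -0.5)
            coefs = rng.uniform(0.15, 0.30, size=len(feats)) * rng.choice([-1, 1], len(feats))
            center = rng.normal(-0.5, 0.2)
            b0 = center - float(sum(c * base_mean[genes.index(f)]
                                    for f, c in zip(feats, coefs)))
            support[g] = {"intercept": b0,
                          "features": [(f, float(c)) for f, c in zip(feats, coefs)]}
    modeled = list(support)

    ess = pd.DataFrame(
        rng.normal(-0.5, 0.5, size=(n_genes, n_lines)), index=genes, columns=samples
    )
    ess.loc[modeled] = _latent_scores(expr, support, noise_sd, rng).loc[modeled]

    prev_mut = rng.uniform(0.03, 0.30, size=n_genes)
    mut = pd.DataFrame((rng.random((n_genes, n_lines)) < prev_mut[:, None]).astype(int),
                       index=genes, columns=samples)
    prev_cnv = rng.uniform(0.03, 0.30, size=n_genes)
    cnv = pd.DataFrame((rng.random((n_genes, n_lines)) < prev_cnv[:, None]).astype(int),
                       index=genes, columns=samples)

    meta = pd.DataFrame({
        "cohort": "cells",
        "lineage": [lineages[i] for i in line_lineage],
    }, index=pd.Index(samples, name="sample"))

    truth = CohortTruth(
        model_support=support,
        hazard_gene=modeled[0] if modeled else None,
        seed=seed,
        gen_params={
            "base_mean": dict(zip(genes, base_mean.tolist())),
            "lineage_shift": {l: dict(zip(genes, row.tolist()))
                              for l, row in zip(lineages, lin_shift)},
            "lineages": lineages,
            "noise_sd": noise_sd,
            "lineage_sd": lineage_sd,
        },
    )
    stage_log("simulate.cells", n_lines=n_lines, n_genes=n_genes,
              n_modeled=len(modeled), noise_sd=noise_sd, seed=seed)
    return (ExpressionMatrix(expr, meta), EssentialityMap(ess, "measured"),
            mut, cnv, truth)


# ----------------------------------------------------------- tumor cohort ---

def _feature_shift(expr: pd.DataFrame, support_entry: dict, carriers: np.ndarray,
                   delta: float) -> None:
    """Shift carriers' expression of a modeled gene's features so its linear
    score moves by exactly ``delta`` (least-norm direction in feature space)."""
    feats = [f for f, _ in support_entry["features"]]
    coefs = np.array([c for _, c in support_entry["features"]], dtype=float)
    ssq = float(coefs @ coefs)
    if ssq == 0:
        return
    shift = delta * coefs / ssq
    block = expr.loc[feats].to_numpy()
    block[:, carriers] += shift[:, None]
    expr.loc[feats] = block


def make_tumor_cohort(
    cell_truth: CohortTruth,
    n_tumors: int = 200,
    purity_beta: tuple[float, float] = (5.0, 2.0),
    stromal_profile: pd.Series | None = None,
    sl_spec: list[tuple[str, str, float]] | None = None,
    lof_prev: tuple[float, float] = (0.03, 0.30),
    planted_prev: tuple[float, float] = (0.10, 0.30),
    hazard_beta: float = -1.0,
    horizon: float = 24.0,
    seed: int = 0,
):
    """Tumor cohort consistent with a cell-line cohort's generative truth.

    Malignant expression follows the cell cohort's gene/lineage model; the
    observed biopsy mixes malignant and stromal signal in *linear* space,
    ``expr = log2(purity * 2^malignant + (1-purity) * 2^stromal)``, then LOF
    events are drawn per gene and each planted pair (A, B, delta) shifts the
    expression of A's model features in LOF-of-B carriers so A's latent
    essentiality moves by delta.  Survival times are exponential with
    log-hazard linear in the hazard gene's standardized latent essentiality
    (``hazard_beta`` < 0: more essential -> worse outcome), with
    administrative censoring at ``horizon``.

    Returns (expression, lof, survival, purity, latent_essentiality).
    """
    gp = cell_truth.gen_params
    genes = list(gp["base_mean"])
    lineages = gp["lineages"]
    base_mean = np.array([gp["base_mean"][g] for g in genes])
    rng = _rng(seed, "tumor")

    a, b = purity_beta
    if a <= 0 or b <= 0:
        raise ValueError("purity_beta shape parameters must be positive")
    if stromal_profile is None:
        stromal_profile = pd.Series(base_mean + rng.normal(0.0, 2.0, len(genes)),
                                    index=genes)
    if not stromal_profile.index.equals(pd.Index(genes)):
        raise ValueError("stromal profile gene set does not match the cohort")

    samples = [f"TU{i:04d}" for i in range(n_tumors)]
    tum_lineage = rng.integers(0, len(lineages), size=n_tumors)
    lin_shift = np.array([[gp["lineage_shift"][l][g] for g in genes] for l in lineages])
    malignant = (base_mean[None, :] + lin_shift[tum_lineage] +
                 rng.normal(0.0, 1.0, size=(n_tumors, len(genes)))).T
    malignant = pd.DataFrame(malignant, index=genes, columns=samples)

    # LOF events, with planted partners forced into the requested prevalence band
    prev = rng.uniform(*lof_prev, size=len(genes))
    sl_spec = list(sl_spec or [])
    for _, bgene, _ in sl_spec:
        prev[genes.index(bgene)] = rng.uniform(*planted_prev)
    lof = pd.DataFrame((rng.random((len(genes), n_tumors)) < prev[:, None]).astype(int),
                       index=genes, columns=samples)

    for a_gene, b_gene, delta in sl_spec:
        if a_gene not in cell_truth.model_support:
            raise ValueError(f"SL pair target {a_gene!r} has no planted model")
        carriers = lof.loc[b_gene].to_numpy().astype(bool)
        _feature_shift(malignant, cell_truth.model_support[a_gene], carriers, delta)

    purity = pd.Series(rng.beta(a, b, size=n_tumors), index=samples, name="purity")
    linear = (purity.to_numpy()[None, :] * np.exp2(malignant.to_numpy()) +
              (1.0 - purity.to_numpy())[None, :] *
              np.exp2(stromal_profile.to_numpy())[:, None])
    expr = pd.DataFrame(np.log2(linear), index=genes, columns=samples)

    latent = _latent_scores(malignant, cell_truth.model_support,
                            gp.get("noise_sd", 0.2), rng)

    # survival: exponential, log-hazard linear in the hazard gene's latent score
    surv = None
    if cell_truth.hazard_gene is not None:
        z = latent.loc[cell_truth.hazard_gene].to_numpy()
        z = (z - z.mean()) / (z.std() or 1.0)
        rate = (0.5 / horizon) * np.exp(hazard_beta * z)
        t = rng.exponential(1.0 / rate)
        event = (t <= horizon).astype(int)
        surv = pd.DataFrame({"time": np.minimum(t, horizon), "event": event},
                            index=pd.Index(samples, name="sample"))

    meta = pd.DataFrame({
        "cohort": "tumor",
        "lineage": [lineages[i] for i in tum_lineage],
        "purity": purity,
    }, index=pd.Index(samples, name="sample"))
    stage_log("simulate.tumor", n_tumors=n_tumors, n_sl_pairs=len(sl_spec),
              mean_purity=round(float(purity.mean()), 3), seed=seed)
    return (ExpressionMatrix(expr, meta), lof, surv, purity,
            EssentialityMap(latent, "measured"))


# --------------------------------------------------------- healthy cohort ---

def make_healthy_cohort(
    cell_truth: CohortTruth,
    n_samples: int = 120,
    batch_scale: tuple[float, float] = (0.8, 1.25),
    batch_shift_sd: float = 1.0,
    window_spec: list[tuple[str, float]] | None = None,
    toxic_spec: list[tuple[str, str, float]] | None = None,
    seed: int = 0,
):
    """Healthy-tissue cohort: cell-like expression under a per-gene
    location-scale batch distortion, with optional planted contrasts.

    ``window_spec`` entries (gene, delta) shift the gene's model features in
    *all* healthy samples (delta > 0 -> less essential in healthy tissue,
    i.e. a therapeutic window).  ``toxic_spec`` entries (gene, tissue, delta)
    shift only one tissue's samples (delta < 0 -> tissue-specific toxicity).

    Returns (expression, latent_essentiality).
    """
    gp = cell_truth.gen_params
    genes = list(gp["base_mean"])
    lineages = gp["lineages"]  # reused as healthy tissue labels
    base_mean = np.array([gp["base_mean"][g] for g in genes])
    rng = _rng(seed, "healthy")

    samples = [f"HT{i:04d}" for i in range(n_samples)]
    tissue = rng.integers(0, len(lineages), size=n_samples)
    lin_shift = np.array([[gp["lineage_shift"][l][g] for g in genes] for l in lineages])
    clean = (base_mean[None, :] + lin_shift[tissue] +
             rng.normal(0.0, 1.0, size=(n_samples, len(genes)))).T
    clean = pd.DataFrame(clean, index=genes, columns=samples)

    for gene, delta in window_spec or []:
        _feature_shift(clean, cell_truth.model_support[gene],
                       np.ones(n_samples, dtype=bool), delta)
    for gene, tiss, delta in toxic_spec or []:
        mask = np.array([lineages[t] == tiss for t in tissue])
        _feature_shift(clean, cell_truth.model_support[gene], mask, delta)

    latent = _latent_scores(clean, cell_truth.model_support,
                            gp.get("noise_sd", 0.2), rng)

    scale = rng.uniform(*batch_scale, size=len(genes))
    shift = rng.normal(0.0, batch_shift_sd, size=len(genes))
    expr = clean.mul(scale, axis=0).add(shift, axis=0)

    meta = pd.DataFrame({
        "cohort": "healthy",
        "lineage": [lineages[t] for t in tissue],
    }, index=pd.Index(samples, name="sample"))
    stage_log("simulate.healthy", n_samples=n_samples, seed=seed)
    return ExpressionMatrix(expr, meta), EssentialityMap(latent, "measured")


def stromal_direction(cell_truth: CohortTruth, stromal_profile: pd.Series,
                      purity_beta: tuple[float, float] = (5.0, 2.0),
                      n_mc: int = 4000, seed: int = 0) -> np.ndarray:
    """Planted admixture direction: top eigenvector of the model-implied
    excess covariance (mixed-expression covariance minus pure-malignant
    covariance), estimated by Monte Carlo from generator parameters only.

    This is the gene-space direction the contrastive step is supposed to
    find and remove; it never looks at a generated cohort.
    """
    gp = cell_truth.gen_params
    genes = list(gp["base_mean"])
    lineages = gp["lineages"]
    base = np.array([gp["base_mean"][g] for g in genes])
    lin_shift = np.array([[gp["lineage_shift"][l][g] for g in genes]
                          for l in lineages])
    rng = np.random.default_rng(seed)
    lin = rng.integers(0, len(lineages), n_mc)
    M = base[None, :] + lin_shift[lin] + rng.normal(0, 1, (n_mc, len(genes)))
    p = rng.beta(*purity_beta, n_mc)[:, None]
    s = np.exp2(stromal_profile.to_numpy())[None, :]
    mixed = np.log2(p * np.exp2(M) + (1 - p) * s)
    w, v = np.linalg.eigh(np.cov(mixed.T) - np.cov(M.T))
    return v[:, -1]


# ----------------------------------------------------------------- screens ---

NT = "NT"
_BASES = np.array(list("ACGT"))


@dataclass
class ScreenDesign:
    """Guide-array library: one row per construct, 4 guides per construct."""

    table: pd.DataFrame  # construct_id (index), gene_a, gene_b, guide1..guide4, cls

    def __post_init__(self) -> None:
        guides = self.table[["guide1", "guide2", "guide3", "guide4"]].to_numpy().ravel()
        if len(set(guides)) != len(guides):
            raise ValueError("guide sequences must be unique across the library")
        for cls, row in zip(self.table["cls"],
                            self.table[["gene_a", "gene_b"]].to_numpy()):
            n_target = sum(g != NT for g in row)
            want = {"NTxNT": 0, "singleKO": 1, "DKO": 2}[cls]
            if n_target != want:
                raise ValueError(f"class {cls} with {n_target} targeted genes")

    def array_seq(self, construct_id: str) -> str:
        row = self.table.loc[construct_id]
        return "".join(row[f"guide{i}"] for i in range(1, 5))

    @property
    def construct_ids(self) -> pd.Index:
        return self.table.index


def _unique_guides(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        g = "".join(rng.choice(_BASES, size=length))
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def make_screen_design(pairs: list[tuple[str, str]], n_nt: int = 50,
                       guide_len: int = 21, seed: int = 0) -> ScreenDesign:
    """Library with one DKO per pair, one single-KO per involved gene and
    ``n_nt`` NTxNT negative-control constructs (4 guides each, all unique)."""
    rng = _rng(seed, "design")
    genes = sorted({g for p in pairs for g in p})
    n_constructs = len(genes) + len(pairs) + n_nt
    pool = _unique_guides(rng, 4 * n_constructs, guide_len)
    it = iter(pool)
    rows = []
    for g in genes:
        rows.append((f"S_{g}", g, NT, next(it), next(it), next(it), next(it),
                     "singleKO"))
    for a, bgene in pairs:
        rows.append((f"D_{a}_{bgene}", a, bgene,
                     next(it), next(it), next(it), next(it), "DKO"))
    for i in range(n_nt):
        rows.append((f"NT_{i:03d}", NT, NT, next(it), next(it), next(it),
                     next(it), "NTxNT"))
    df = pd.DataFrame(rows, columns=["construct_id", "gene_a", "gene_b",
                                     "guide1", "guide2", "guide3", "guide4",
                                     "cls"]).set_index("construct_id")
    return ScreenDesign(df)


def make_screen_counts(
    design: ScreenDesign,
    gi_truth: dict[tuple[str, str], float] | None = None,
    single_effects: dict[str, float] | None = None,
    depth: float = 500.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    seed: int = 0,
):
    """Plasmid and day-14 replicate counts with fitness-dependent depletion.

    The day-14 expectation for a construct is its plasmid proportion times
    ``2^(sum of single-gene log2 effects + interaction term)``, renormalized
    to the library; counts are negative-binomial with the given dispersion
    (Poisson at dispersion 0).  NTxNT constructs carry zero planted effect.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    gi_truth = {tuple(sorted(k)): v for k, v in (gi_truth or {}).items()}
    single_effects = single_effects or {}
    rng = _rng(seed, "screen")
    tab = design.table
    n = len(tab)

    def draw(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    plasmid = pd.Series(draw(np.full(n, float(depth))), index=tab.index, name="plasmid")
    effect = np.zeros(n)
    for i, (a, bgene, cls) in enumerate(zip(tab["gene_a"], tab["gene_b"], tab["cls"])):
        if cls == "NTxNT":
            continue
        e = single_effects.get(a, 0.0) + single_effects.get(bgene, 0.0)
        if cls == "DKO":
            e += gi_truth.get(tuple(sorted((a, bgene))), 0.0)
        effect[i] = e
    prop = plasmid.to_numpy() / max(plasmid.sum(), 1)
    weight = prop * np.exp2(effect)
    weight = weight / weight.sum()
    day14 = {}
    for r in range(n_reps):
        day14[f"day14_rep{r + 1}"] = draw(weight * depth * n)
    day14 = pd.DataFrame(day14, index=tab.index)
    stage_log("simulate.screen", n_constructs=n, depth=depth, n_reps=n_reps, seed=seed)
    return plasmid, day14


def make_reads(design: ScreenDesign, counts: pd.Series, flank5: str, flank3: str,
               error_rate: float = 0.0, seed: int = 0):
    """Emit FASTQ-ready (id, sequence) reads for per-construct counts.

    Each read is flank5 + the construct's concatenated 4-guide array +
    flank3; optional uniform substitution errors at ``error_rate``.
    """
    for col in ("guide1", "guide2", "guide3", "guide4"):
        bad = ~design.table[col].str.fullmatch("[ACGT]+")
        if bad.any():
            raise ValueError(f"non-ACGT guide in {design.table.index[bad][0]!r}")
    rng = _rng(seed, "reads")
    i = 0
    for cid in counts.index:
        seq = flank5 + design.array_seq(cid) + flank3
        for _ in range(int(counts[cid])):
            read = seq
            if error_rate > 0:
                arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
                hit = rng.random(arr.size) < error_rate
                if hit.any():
                    arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
                    read = "".join(arr)
            yield f"read{i:07d}_{cid}", read
            i += 1
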