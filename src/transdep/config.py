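"""Run configuration and structured stage logging.

Every tunable threshold in the pipeline lives here with its default, so a
run is fully described by one :class:`RunConfig`.  Defaults follow the
published procedure: elastic-net mixing 0.5 with tenfold CV at the
minimum-error lambda, a pass rule of cross-validated R > 0.2 at FDR < 1e-3,
a dependency cutoff of -0.5 on CERES-like scores, removal of the top 4
contrastive components for tumor cohorts (3 for PDX, 0 for healthy tissue),
SL lasso with 5-fold CV and a 0.3 coefficient threshold at FDR < 0.01,
greedy mutual exclusivity over at most 10 genes with 100 permutations at
P < 0.01, a paralog phylogenetic-distance threshold of 1.5 (strict <), and
survival associations at FDR < 0.2.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("transdep")


def stage_log(stage: str, **kv: object) -> None:
    """One structured line per pipeline stage: shapes, thresholds, funnel counts."""
    payload = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("[%s] %s", stage, payload)


@dataclass
class RunConfig:
    seed: int = 0

    # essentiality models
    dep_cutoff: float = -0.5          # CERES-like score below which a line is "dependent"
    min_each: int = 5                 # min dependent AND nondependent lines per modeled gene
    enet_alpha: float = 0.5           # L1/L2 mixing
    enet_folds: int = 10
    n_lambda: int = 100               # log-spaced path, 4 decades below lambda_max
    lambda_decades: float = 4.0
    r_threshold: float = 0.2          # pass rule: CV Pearson R
    q_threshold: float = 1e-3         # pass rule: BH FDR
    min_mut_prev: float = 0.02        # mutation classifiers need prevalence in (p, 1-p)

    # alignment
    cpca_alpha: float = 1.0           # contrast weight
    k_removed_tumor: int = 4
    k_removed_pdx: int = 3
    k_removed_healthy: int = 0
    n_clusters: int | None = None     # cluster-matched correction; None -> n lineages
    shrink_n0: float = 10.0           # location-scale shrinkage prior weight

    # selectivity
    normlrt_df_bounds: tuple[float, float] = (2.1, 100.0)
    normlrt_boot: int = 50
    ssd_lrt_threshold: float = 100.0

    # synthetic lethality
    sl_folds: int = 5
    sl_coef_threshold: float = 0.3
    sl_q_threshold: float = 0.01
    prevalence_band: tuple[float, float] = (0.03, 0.70)
    me_max_set: int = 10
    me_n_perm: int = 100
    me_p_threshold: float = 0.01
    paralog_dist_threshold: float = 1.5

    # screens
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    l2fc_pseudo: float = 0.5
    gi_call_z: float = 2.0
    min_nt_constructs: int = 10

    # clinical outcomes
    maxstat_qrange: tuple[float, float] = (0.1, 0.9)
    maxstat_n_perm: int = 200
    pfi_fdr: float = 0.2
    excluded_lineages: tuple[str, ...] = ()
    min_stratum_n: int = 30
    sl_carrier_quantile: float = 0.25
    response_min_n: int = 20
    dep_top_k: int = 100
    lda_min_class: int = 5
    driver_top_frac: float = 0.10
    driver_prev_min: dict = field(
        default_factory=lambda: {"mutation": 0.05, "deletion": 0.10, "amplification": 0.10}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(d)
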