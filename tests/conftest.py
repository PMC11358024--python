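import logging

import numpy as np
import pandas as pd
import pytest

import transdep as td

logging.getLogger("transdep").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def cell_cohort():
    """Small cell-line cohort with 10 modeled genes (session-cached)."""
    return td.make_cell_cohort(n_lines=100, n_genes=200, n_informative=10,
                               seed=11)


@pytest.fixture(scope="session")
def tumor_cohort(cell_cohort):
    """Tumor cohort derived from the cell cohort, 5 planted SL pairs."""
    _, _, _, _, truth = cell_cohort
    modeled = list(truth.model_support)
    free = [g for g in truth.gen_params["base_mean"] if g not in modeled][:5]
    sl_spec = [(modeled[i], free[i], -0.6) for i in range(5)]
    out = td.make_tumor_cohort(truth, n_tumors=300, sl_spec=sl_spec, seed=11)
    return (*out, sl_spec)


@pytest.fixture(scope="session")
def small_models(cell_cohort):
    """Expression-only models for the modeled genes plus a few noise genes."""
    expr, ess, _, _, truth = cell_cohort
    modeled = list(truth.model_support)
    noise = [g for g in expr.genes if g not in modeled][:10]
    return td.fit_all(ess, expr, genes=modeled + noise,
                      config=td.RunConfig(seed=11))


@pytest.fixture(scope="session")
def screen():
    """Small dual-KO screen: 30 pairs, 5 with a planted interaction of -2."""
    pairs = [(f"p{i}A", f"p{i}B") for i in range(30)]
    design = td.make_screen_design(pairs, n_nt=30, seed=7)
    gi_truth = {pairs[i]: -2.0 for i in range(5)}
    singles = {g: -0.5 for p in pairs for g in p}
    plasmid, day14 = td.make_screen_counts(design, gi_truth, singles,
                                           depth=500, seed=7)
    counts = pd.concat([plasmid, day14], axis=1)
    return design, counts, gi_truth, singles


def random_expression(n_genes=30, n_samples=20, seed=0, prefix="s"):
    rng = np.random.default_rng(seed)
    return td.ExpressionMatrix(pd.DataFrame(
        rng.normal(7, 1.5, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{prefix}{i}" for i in range(n_samples)]))
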