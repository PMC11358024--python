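import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transdep as td
from conftest import random_expression


def _em(arr, cols=None, prefix="s"):
    arr = np.asarray(arr, float)
    cols = cols or [f"{prefix}{i}" for i in range(arr.shape[1])]
    return td.ExpressionMatrix(pd.DataFrame(
        arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols))


class TestQuantileNormalize:
    def test_two_column_mean_reference(self):
        m = _em(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out, ref = td.quantile_normalize(m)
        np.testing.assert_allclose(ref, [2.5, 3.5, 4.5])
        for col in out.values:
            np.testing.assert_allclose(np.sort(out.values[col]), ref)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_all_columns_share_one_value_multiset(self, seed):
        m = random_expression(n_genes=15, n_samples=6, seed=seed)
        out, _ = td.quantile_normalize(m)
        ref = np.sort(out.values.iloc[:, 0].to_numpy())
        for c in out.values.columns[1:]:
            np.testing.assert_allclose(np.sort(out.values[c].to_numpy()), ref)

    def test_ranks_preserved_within_column(self):
        m = random_expression(n_genes=30, n_samples=4, seed=1)
        out, _ = td.quantile_normalize(m)
        mv = m.values.loc[out.values.index]
        for c in m.values.columns:
            assert (mv[c].rank() == out.values[c].rank()).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            td.quantile_normalize(_em([[1.0, 2.0]]))


class TestContrastivePCA:
    def test_alpha_zero_reduces_to_foreground_pca(self):
        fg = random_expression(n_genes=12, n_samples=40, seed=2)
        bg = random_expression(n_genes=12, n_samples=40, seed=3, prefix="b")
        U, evals = td.contrastive_pca(fg, bg, alpha_c=0.0, k=3)
        cov = np.cov(fg.values.to_numpy())
        w, v = np.linalg.eigh(cov)
        for i in range(3):
            cos = abs(U.iloc[:, i] @ v[:, -1 - i])
            assert cos > 1 - 1e-8
        np.testing.assert_allclose(evals, w[::-1][:3], rtol=1e-8)

    def test_identical_covariance_cancels(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(10, 500))
        fg = _em(base, prefix="f")
        bg = _em(base, prefix="b")
        _, evals = td.contrastive_pca(fg, bg, alpha_c=1.0, k=3)
        assert np.all(np.abs(evals) < 1e-6)

    def test_planted_direction_recovered_vs_dense_oracle(self):
        rng = np.random.default_rng(5)
        g = 50
        v = rng.normal(size=g)
        v /= np.linalg.norm(v)
        bg_arr = rng.normal(size=(g, 300))
        fg_arr = rng.normal(size=(g, 300)) + 4.0 * np.outer(
            v, rng.normal(size=300))
        fg, bg = _em(fg_arr, prefix="f"), _em(bg_arr, prefix="b")
        U, _ = td.contrastive_pca(fg, bg, alpha_c=1.0, k=1)
        assert abs(U.iloc[:, 0] @ v) > 0.95
        # independent oracle: dense eigendecomposition of the contrast matrix
        C = np.cov(fg_arr) - np.cov(bg_arr)
        w, vec = np.linalg.eigh(C)
        assert abs(U.iloc[:, 0] @ vec[:, -1]) > 0.999

    def test_k_exceeding_rank_rejected(self):
        fg = random_expression(n_genes=5, n_samples=10, seed=6)
        bg = random_expression(n_genes=5, n_samples=10, seed=7, prefix="b")
        with pytest.raises(ValueError):
            td.contrastive_pca(fg, bg, k=6)


class TestRemoveComponents:
    def test_k_zero_is_identity(self):
        m = random_expression(seed=8)
        out = td.remove_components(m, pd.DataFrame(index=m.genes))
        pd.testing.assert_frame_equal(out.values, m.values)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_projection_idempotent_and_orthogonal(self, seed):
        m = random_expression(n_genes=20, n_samples=15, seed=seed)
        bg = random_expression(n_genes=20, n_samples=15, seed=seed + 1,
                               prefix="b")
        U, _ = td.contrastive_pca(m, bg, k=3)
        once = td.remove_components(m, U)
        twice = td.remove_components(once, U)
        assert np.abs(once.values - twice.values).to_numpy().max() < 1e-10
        centered = once.values.sub(once.values.mean(axis=1), axis=0)
        assert np.abs(U.to_numpy().T @ centered.to_numpy()).max() < 1e-8


class TestClusterMatch:
    def test_constant_offset_removed_exactly(self):
        cells = random_expression(n_genes=25, n_samples=30, seed=9)
        shift = np.random.default_rng(10).normal(size=25)
        tumors = td.ExpressionMatrix(
            cells.values.add(shift, axis=0).rename(
                columns=lambda c: c.replace("s", "t")))
        out, shifts = td.cluster_match_correct(cells, tumors, n_clusters=1)
        assert np.abs(out.values.to_numpy()
                      - cells.values.to_numpy()).max() < 1e-8

    def test_already_aligned_cohorts_barely_move(self):
        cells = random_expression(n_genes=25, n_samples=40, seed=11)
        tumors = random_expression(n_genes=25, n_samples=40, seed=12,
                                   prefix="t")
        out, shifts = td.cluster_match_correct(cells, tumors, n_clusters=2)
        for s in shifts.values():
            assert np.linalg.norm(s) < 2.0  # small relative to gene scale ~7

    def test_invalid_cluster_count(self):
        m = random_expression(seed=13)
        with pytest.raises(ValueError):
            td.cluster_match_correct(m, m, n_clusters=0)


class TestGtexCorrect:
    def test_identity_when_cohorts_match(self):
        cells = random_expression(n_genes=40, n_samples=50, seed=14)
        healthy = td.ExpressionMatrix(
            cells.values.rename(columns=lambda c: c.replace("s", "h")))
        out = td.gtex_style_correct(cells, healthy)
        ref, _ = td.quantile_normalize(cells)
        assert np.abs(out.values.to_numpy()
                      - ref.values.to_numpy()).max() < 1e-8

    def test_affine_batch_effect_undone(self):
        cells = random_expression(n_genes=60, n_samples=50, seed=15)
        healthy = td.ExpressionMatrix(
            (2.0 * cells.values + 3.0).rename(columns=lambda c: "h" + c))
        out = td.gtex_style_correct(cells, healthy)
        cq, _, _ = td.quantile_normalize(cells, healthy)
        resid = out.values.mean(axis=1) - cq.values.mean(axis=1)
        assert np.abs(resid).max() < 0.05

    def test_tiny_cohort_shrinks_toward_global(self):
        cells = random_expression(n_genes=30, n_samples=40, seed=16)
        healthy = td.ExpressionMatrix(
            cells.values.iloc[:, :2].rename(columns=lambda c: "h" + c))
        out = td.gtex_style_correct(cells, healthy, shrink_n0=10.0)
        # with n=2, weight is 2/12: per-gene means must NOT match cells'
        cq, hq, _ = td.quantile_normalize(cells, healthy)
        gene_resid = (out.values.mean(axis=1) - cq.values.mean(axis=1)).abs()
        assert gene_resid.mean() > 0.05


class TestPurityDiagnostic:
    def test_linear_in_purity_gives_r2_one(self):
        purity = pd.Series(np.linspace(0.2, 1.0, 30),
                           index=[f"t{i}" for i in range(30)])
        emap = td.EssentialityMap(pd.DataFrame(
            [2 * purity + 1], index=["g"]).astype(float), "predicted")
        r2 = td.purity_r2(emap, purity)
        assert r2["g"] == pytest.approx(1.0)

    def test_independent_prediction_has_small_r2(self):
        rng = np.random.default_rng(17)
        purity = pd.Series(rng.uniform(0.3, 1, 200),
                           index=[f"t{i}" for i in range(200)])
        hits = 0
        for rep in range(20):
            emap = td.EssentialityMap(pd.DataFrame(
                [rng.normal(size=200)], index=["g"],
                columns=purity.index), "predicted")
            if td.purity_r2(emap, purity)["g"] < 0.05:
                hits += 1
        assert hits >= 18

    def test_constant_purity_rejected(self):
        purity = pd.Series(0.5, index=["a", "b", "c"])
        emap = td.EssentialityMap(pd.DataFrame(
            [[0.0, 1.0, 2.0]], index=["g"], columns=["a", "b", "c"]),
            "predicted")
        with pytest.raises(ValueError):
            td.purity_r2(emap, purity)
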