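import numpy as np
import pandas as pd
import pytest

import transdep as td
from transdep.containers import GeneModel


def _toy_model():
    return GeneModel(
        gene="gT", mode="expression_only", alpha=0.5, lam=0.1, intercept=-0.3,
        coef=pd.Series({"g1": 0.5, "g2": -0.2}),
        feature_mean=pd.Series({"g1": 0.0, "g2": 0.0}),
        feature_sd=pd.Series({"g1": 1.0, "g2": 1.0}),
        cv_r=0.9, p=1e-6, q=1e-6, passed=True)


class TestPredictMap:
    def test_arithmetic_on_a_toy_model(self):
        mset = td.ModelSet([_toy_model()])
        target = td.ExpressionMatrix(pd.DataFrame({"s1": [2.0, 1.0]},
                                                  index=["g1", "g2"]))
        out = td.predict_map(mset, target)
        assert out.values.loc["gT", "s1"] == pytest.approx(0.5)
        assert out.provenance == "predicted"

    def test_in_sample_predictions_match_fitted_values(self, cell_cohort,
                                                       small_models):
        expr, ess, *_ = cell_cohort
        out = td.predict_map(small_models, expr)
        m = small_models.passing()[0]
        manual = m.predict(expr.values)
        np.testing.assert_allclose(out.values.loc[m.gene], manual)

    def test_predictions_track_latent_truth(self, cell_cohort, small_models):
        expr, ess, _, _, truth = cell_cohort
        out = td.predict_map(small_models, expr)
        rs = []
        for g in out.values.index:
            if g in truth.model_support:
                rs.append(np.corrcoef(out.values.loc[g], ess.values.loc[g])[0, 1])
        assert np.median(rs) > 0.6

    def test_missing_feature_skips_model(self):
        m = _toy_model()
        mset = td.ModelSet([m])
        target = td.ExpressionMatrix(pd.DataFrame({"s1": [2.0]}, index=["g1"]))
        with pytest.raises(ValueError, match="no passing model"):
            td.predict_map(mset, target)


class TestRescale:
    def _maps(self, seed=0, slope=1.0, offset=0.0):
        rng = np.random.default_rng(seed)
        cells = pd.DataFrame(rng.normal(-0.5, 0.8, (4, 50)),
                             index=[f"g{i}" for i in range(4)],
                             columns=[f"c{i}" for i in range(50)])
        target = pd.DataFrame(rng.normal(-0.5, 0.8, (4, 30)),
                              index=cells.index,
                              columns=[f"t{i}" for i in range(30)])
        measured = slope * cells + offset
        return (td.EssentialityMap(target, "predicted"),
                td.EssentialityMap(cells, "predicted"),
                td.EssentialityMap(measured, "measured"))

    def test_identity_when_predicted_equals_measured(self):
        pred_t, pred_c, meas = self._maps(slope=1.0, offset=0.0)
        out, params = td.rescale(pred_t, pred_c, meas)
        np.testing.assert_allclose(params.table["slope"], 1.0, atol=1e-10)
        np.testing.assert_allclose(params.table["intercept"], 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values, pred_t.values)
        assert out.provenance == "predicted+rescaled"

    def test_affine_truth_recovered_and_ranks_preserved(self):
        pred_t, pred_c, meas = self._maps(seed=1, slope=0.6, offset=-0.2)
        out, params = td.rescale(pred_t, pred_c, meas)
        np.testing.assert_allclose(params.table["slope"], 0.6, atol=1e-10)
        for g in out.values.index:
            a = pred_t.values.loc[g].rank()
            b = out.values.loc[g].rank()
            pd.testing.assert_series_equal(a, b)

    def test_correlations_unchanged(self):
        pred_t, pred_c, meas = self._maps(seed=2, slope=2.0, offset=1.0)
        out, _ = td.rescale(pred_t, pred_c, meas)
        g = out.values.index[0]
        r_pre = np.corrcoef(pred_t.values.loc[g], pred_t.values.iloc[1])[0, 1]
        r_post = np.corrcoef(out.values.loc[g], out.values.iloc[1])[0, 1]
        assert abs(r_pre - r_post) < 1e-12

    def test_least_squares_mean_property(self):
        pred_t, pred_c, meas = self._maps(seed=3, slope=0.8, offset=0.3)
        out, params = td.rescale(pred_c, pred_c, meas)
        # rescaled cell predictions must hit the measured per-gene mean
        diff = out.values.mean(axis=1) - meas.values.mean(axis=1)
        assert np.abs(diff).max() < 1e-10


class TestLineageCluster:
    def test_separated_lineages_recovered(self):
        rng = np.random.default_rng(4)
        blocks = [rng.normal(m, 0.3, (20, 25)) for m in (-2.0, 0.0, 2.0)]
        vals = pd.DataFrame(np.hstack(blocks),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(75)])
        lineages = pd.Series(["A"] * 25 + ["B"] * 25 + ["C"] * 25,
                             index=vals.columns)
        _, labels, ari = td.lineage_cluster(td.EssentialityMap(vals), lineages)
        assert ari > 0.9

    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(rng.normal(size=(10, 5)),
                            index=[f"g{i}" for i in range(10)],
                            columns=list("abcde"))
        vals["e"] = vals["a"]  # exact duplicate pair
        Z, _, _ = td.lineage_cluster(td.EssentialityMap(vals),
                                     pd.Series("x", index=vals.columns))
        assert Z[0, 2] == 0.0  # first merge at distance zero

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(size=(15, 30)),
                            index=[f"g{i}" for i in range(15)],
                            columns=[f"s{i}" for i in range(30)])
        lin = pd.Series(rng.choice(["A", "B"], 30), index=vals.columns)
        _, lab1, _ = td.lineage_cluster(td.EssentialityMap(vals), lin, 2)
        perm = rng.permutation(vals.columns)
        _, lab2, _ = td.lineage_cluster(
            td.EssentialityMap(vals[perm]), lin, 2)
        # identical partitions up to label names
        joint = pd.crosstab(lab1.loc[perm].to_numpy(), lab2.to_numpy())
        assert (joint.astype(bool).sum(axis=1) == 1).all()

    def test_too_few_samples(self):
        vals = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            td.lineage_cluster(td.EssentialityMap(vals),
                               pd.Series("x", index=["a", "b"]))


class TestGofAssociation:
    def test_planted_oncogene_flagged_with_direction(self):
        rng = np.random.default_rng(7)
        n = 200
        carrier = rng.random(n) < 0.3
        scores = rng.normal(-0.5, 0.3, n) - 0.8 * carrier
        emap = td.EssentialityMap(pd.DataFrame([scores], index=["onc"],
                                               columns=[f"s{i}" for i in
                                                        range(n)]))
        gof = pd.DataFrame([carrier.astype(int)], index=["onc"],
                           columns=emap.values.columns)
        tab = td.gof_association(emap, gof)
        assert tab.loc["onc", "q"] < 0.01
        assert bool(tab.loc["onc", "stronger_in_carriers"])

    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(8)
        hits = 0
        for rep in range(20):
            scores = rng.normal(-0.5, 0.3, 100)
            carrier = np.r_[np.ones(50), np.zeros(50)].astype(int)
            emap = td.EssentialityMap(pd.DataFrame(
                [scores], index=["g"], columns=[f"s{i}" for i in range(100)]))
            gof = pd.DataFrame([carrier], index=["g"],
                               columns=emap.values.columns)
            if td.gof_association(emap, gof).loc["g", "p"] > 0.05:
                hits += 1
        assert hits >= 17

    def test_small_group_skipped(self):
        emap = td.EssentialityMap(pd.DataFrame(
            [np.arange(10.0)], index=["g"],
            columns=[f"s{i}" for i in range(10)]))
        gof = pd.DataFrame([[1] + [0] * 9], index=["g"],
                           columns=emap.values.columns)
        assert len(td.gof_association(emap, gof)) == 0
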