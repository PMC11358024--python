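import numpy as np
import pandas as pd
import pytest

import transdep as td


def _surv(time, event):
    return pd.DataFrame({"time": time, "event": event},
                        index=[f"s{i}" for i in range(len(time))])


def _sim_cohort(rng, n, rate_fn, horizon=3.0):
    score = rng.normal(0, 1, n)
    t = rng.exponential(1.0 / rate_fn(score))
    surv = _surv(np.minimum(t, horizon), (t <= horizon).astype(int))
    return pd.Series(score, index=surv.index), surv


class TestLogrank:
    def test_hand_computed_hypergeometric_toy(self):
        # events at 1,3 (A) vs 2,4 (B): E_A = 1/2 + 1/3 + 1/2 -> O-E = 2/3
        oe, var, chi2, p = td.logrank([1, 3], [1, 1], [2, 4], [1, 1])
        assert oe == pytest.approx(2 / 3, abs=1e-10)

    def test_identical_groups_score_zero(self):
        oe, var, chi2, p = td.logrank([1, 2, 3], [1, 1, 0],
                                      [1, 2, 3], [1, 1, 0])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 25)
        ea, eb = np.ones(20, int), np.ones(25, int)
        oe1, _, _, p1 = td.logrank(ta, ea, tb, eb)
        oe2, _, _, p2 = td.logrank(tb, eb, ta, ea)
        assert oe1 == pytest.approx(-oe2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            td.logrank([], [], [1.0], [1])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(1, 30), rng.exponential(1.8, 30)
        ca = (ta < 2).astype(int)
        cb = (tb < 2).astype(int)
        _, _, chi2, p = td.logrank(np.minimum(ta, 2), ca, np.minimum(tb, 2), cb)
        res = logrank_test(np.minimum(ta, 2), np.minimum(tb, 2), ca, cb)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-6)


class TestCox:
    def test_binary_hazard_ratio_recovery(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 2, 500).astype(float)
            t = rng.exponential(1 / np.where(g == 1, 2.0, 1.0))
            surv = _surv(np.minimum(t, 3.0), (t <= 3.0).astype(int))
            res = td.cox_hr(pd.Series(g, index=surv.index), surv)
            hits += 1.7 <= res.hr <= 2.3
        assert hits >= 9

    def test_score_test_equals_logrank_for_binary_tie_free(self):
        rng = np.random.default_rng(2)
        n = 80
        g = rng.integers(0, 2, n).astype(float)
        t = rng.permutation(np.arange(1, n + 1)).astype(float)
        surv = _surv(t, np.ones(n, int))
        res = td.cox_hr(pd.Series(g, index=surv.index), surv)
        _, _, _, p = td.logrank(t[g == 1], np.ones(int(g.sum())),
                                t[g == 0], np.ones(int((1 - g).sum())))
        assert res.score_p == pytest.approx(p, abs=1e-6)

    def test_partial_likelihood_matches_grid_oracle(self):
        # 6 samples, no ties: brute-force the partial likelihood over beta
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        surv = _surv(time, event)

        def neg_pl(beta):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = time >= time[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-3, 3, 60001)
        beta_star = grid[np.argmin([neg_pl(b) for b in grid])]
        res = td.cox_hr(pd.Series(x, index=surv.index), surv)
        assert np.log(res.hr) == pytest.approx(beta_star, abs=1e-4)

    def test_null_ci_coverage(self):
        covered = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            score, surv = _sim_cohort(rng, 120, lambda s: np.ones_like(s))
            res = td.cox_hr(score, surv)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 33  # ~95% nominal, loose binomial bound


class TestMaxstat:
    def test_changepoint_at_median_recovered(self):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            score = rng.normal(0, 1, 300)
            rate = np.where(score > np.median(score), 2.0, 1.0)
            t = rng.exponential(1 / rate)
            surv = _surv(np.minimum(t, 3.0), (t <= 3.0).astype(int))
            ms = td.maxstat_cutpoint(pd.Series(score, index=surv.index), surv,
                                     n_perm=50, seed=seed)
            pct = (score <= ms.cutpoint).mean()
            ok += 0.40 <= pct <= 0.60
        assert ok >= 4

    def test_qrange_excludes_extreme_cutpoints(self):
        rng = np.random.default_rng(6)
        score, surv = _sim_cohort(rng, 100, lambda s: np.ones_like(s))
        ms = td.maxstat_cutpoint(score, surv, qrange=(0.25, 0.75), n_perm=10,
                                 seed=0)
        frac_low = (score <= ms.cutpoint).mean()
        assert 0.25 <= frac_low <= 0.75

    def test_minimum_cohort_rejected(self):
        surv = _surv([1.0] * 5, [1] * 5)
        with pytest.raises(ValueError):
            td.maxstat_cutpoint(pd.Series(np.arange(5.0), index=surv.index),
                                surv)


class TestPfiScan:
    def test_hazard_gene_detected_with_direction(self, cell_cohort,
                                                 tumor_cohort):
        truth = cell_cohort[4]
        _, _, surv, _, latent, _ = tumor_cohort
        cfg = td.RunConfig(seed=11, maxstat_n_perm=99)
        tab = td.pfi_scan(latent, surv, config=cfg)
        g = truth.hazard_gene
        assert tab.loc[g, "q"] < 0.2
        # planted hazard_beta < 0: low scores (high dependency) do worse
        assert tab.loc[g, "hr"] > 1

    def test_small_strata_excluded(self, tumor_cohort):
        texpr, _, surv, _, latent, _ = tumor_cohort
        lineage = texpr.metadata["lineage"].copy()
        lineage.iloc[:5] = "rare"
        cfg = td.RunConfig(seed=11, maxstat_n_perm=20, min_stratum_n=30)
        tab = td.pfi_scan(
            td.EssentialityMap(latent.values.iloc[:1]), surv,
            lineage=lineage, config=cfg)
        assert len(tab) == 1  # runs after dropping the rare stratum


class TestSlSurvival:
    def test_carrier_group_definition_and_guard(self, tumor_cohort):
        _, lof, surv, _, latent, sl_spec = tumor_cohort
        a, b, _ = sl_spec[0]
        res = td.sl_survival(latent, lof, (a, b), surv, carrier_quantile=0.6)
        assert res.hr > 0
        with pytest.raises(ValueError, match="carrier"):
            td.sl_survival(latent, lof, (a, b), surv, carrier_quantile=0.01)


class TestResponse:
    def test_perfect_separation_auc_one(self):
        scores = pd.Series([-2.0, -1.8, -1.5, -0.2, -0.1, 0.0],
                           index=[f"s{i}" for i in range(6)])
        resp = pd.Series([1, 1, 1, 0, 0, 0], index=scores.index)
        out = td.response_assoc(scores, resp, min_n=6)
        assert out["auc"] == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(7)
        aucs = []
        for rep in range(50):
            scores = pd.Series(rng.normal(-0.5, 0.5, 40),
                               index=[f"s{i}" for i in range(40)])
            resp = pd.Series(rng.permutation([1] * 20 + [0] * 20),
                             index=scores.index)
            aucs.append(td.response_assoc(scores, resp, min_n=20)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_continuous_correlation_recovered(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(-0.5, 0.5, 100),
                           index=[f"s{i}" for i in range(100)])
        burden = 0.8 * scores + rng.normal(0, 0.35, 100)
        out = td.response_assoc(scores, burden, kind="continuous")
        assert out["pearson_r"] > 0.6

    def test_single_class_rejected(self):
        scores = pd.Series(np.arange(25.0), index=[f"s{i}" for i in range(25)])
        resp = pd.Series(1, index=scores.index)
        with pytest.raises(ValueError, match="single-class"):
            td.response_assoc(scores, resp)


class TestDep100:
    def test_separated_subtypes_classified(self):
        rng = np.random.default_rng(9)
        blocks = [rng.normal(m, 0.5, (120, 30)) for m in (-1.0, 0.0, 1.0)]
        vals = pd.DataFrame(np.hstack(blocks),
                            index=[f"g{i}" for i in range(120)],
                            columns=[f"s{i}" for i in range(90)])
        labels = pd.Series(["lumA"] * 30 + ["lumB"] * 30 + ["basal"] * 30,
                           index=vals.columns)
        genes, aucs = td.dep100_subtype(td.EssentialityMap(vals), labels)
        assert len(genes) == 100
        assert (aucs > 0.9).all()

    def test_small_class_skipped_and_k_clamped(self):
        rng = np.random.default_rng(10)
        vals = pd.DataFrame(rng.normal(size=(30, 43)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(43)])
        labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 3,
                           index=vals.columns)
        genes, aucs = td.dep100_subtype(td.EssentialityMap(vals), labels,
                                        top_k=100)
        assert len(genes) == 30        # clamped to available genes
        assert "C" not in aucs.index   # 3-sample class skipped


class TestDriverEnrichment:
    def _map(self):
        return td.EssentialityMap(pd.DataFrame(
            [np.arange(10.0)], index=["gX"],
            columns=[f"p{i}" for i in range(10)]), "predicted+rescaled")

    def test_fisher_toy_matches_hypergeometric_tail(self):
        # 2x2 table [[3,1],[1,5]] -> P = (C(4,3)C(6,1)+C(4,4)C(6,0))/C(10,4)
        var = pd.DataFrame([[1, 1, 1, 0, 0, 1, 0, 0, 0, 0]], index=["v"],
                           columns=[f"p{i}" for i in range(10)])
        tab = td.driver_enrichment(self._map(), {"mutation": var}, "gX",
                                   top_frac=0.4, prev_min={"mutation": 0.0})
        assert tab["p"].iloc[0] == pytest.approx(25 / 210, abs=1e-12)

    def test_perfect_cooccurrence_is_minimal_p(self):
        var = pd.DataFrame([[1, 1, 1, 1, 0, 0, 0, 0, 0, 0]], index=["v"],
                           columns=[f"p{i}" for i in range(10)])
        tab = td.driver_enrichment(self._map(), {"mutation": var}, "gX",
                                   top_frac=0.4, prev_min={"mutation": 0.0})
        from math import comb
        assert tab["p"].iloc[0] == pytest.approx(1 / comb(10, 4), abs=1e-12)

    def test_prevalence_floor_is_strict(self):
        cols = [f"p{i}" for i in range(100)]
        emap = td.EssentialityMap(pd.DataFrame(
            [np.arange(100.0)], index=["gX"], columns=cols),
            "predicted+rescaled")
        var = pd.DataFrame([[1] * 4 + [0] * 96, [1] * 6 + [0] * 94],
                           index=["rare", "common"], columns=cols)
        tab = td.driver_enrichment(emap, {"mutation": var}, "gX",
                                   prev_min={"mutation": 0.05})
        tested = tab.index.get_level_values("variant")
        assert "common" in tested and "rare" not in tested
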