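import numpy as np
import pandas as pd
import pytest
from _reference import bh_reference, cox_grid_search, km_reference

from coexsurv import moduledetect, survassoc, synthdata

# 6-subject worked example (no ties): time, event, covariate
TOY_T = np.array([2.0, 5.0, 7.0, 11.0, 14.0, 20.0])
TOY_E = np.array([1, 1, 0, 1, 1, 0])
TOY_X = np.array([1.2, -0.4, 0.7, 0.1, -1.0, 0.3])


def _sim_cohort(rng, n, beta=0.0, censor_scale=40.0):
    x = rng.normal(size=n)
    t_event = rng.exponential(30.0 * np.exp(-beta * x))
    c = rng.uniform(0, censor_scale, size=n)
    t = np.minimum(t_event, c)
    e = (t_event <= c).astype(int)
    return x, t, e


class TestScaleEigengene:
    def test_quantile_anchors(self, rng):
        # n=41: the 2.5/50/97.5% quantiles are exactly data points
        # (0.025*40=1, 0.5*40=20, 0.975*40=39)
        x = np.sort(rng.normal(size=41))
        s = survassoc.scale_eigengene(x)
        assert s[1] == pytest.approx(-1.0, abs=1e-12)
        assert s[20] == pytest.approx(0.0, abs=1e-12)
        assert s[39] == pytest.approx(1.0, abs=1e-12)

    def test_standard_normal_value_at_196(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10000)
        s = survassoc.scale_eigengene(np.append(x, 1.96))
        assert s[-1] == pytest.approx(1.0, abs=0.08)

    def test_monotone(self, rng):
        x = rng.normal(size=500)
        s = survassoc.scale_eigengene(x)
        order = np.argsort(x)
        assert (np.diff(s[order]) >= 0).all()

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            survassoc.scale_eigengene(np.ones(100))

    def test_series_index_preserved(self, rng):
        me = pd.Series(rng.normal(size=50),
                       index=[f"s{j}" for j in range(50)])
        s = survassoc.scale_eigengene(me)
        assert list(s.index) == list(me.index)


class TestCoxFit:
    def test_translation_invariance(self):
        a = survassoc.cox_fit(TOY_X, TOY_T, TOY_E)
        b = survassoc.cox_fit(TOY_X + 17.3, TOY_T, TOY_E)
        assert a.hr == pytest.approx(b.hr, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_toy_matches_grid_search(self):
        rec = survassoc.cox_fit(TOY_X, TOY_T, TOY_E)
        beta_ref = cox_grid_search(TOY_X, TOY_T, TOY_E)
        assert rec.coef == pytest.approx(beta_ref, abs=1e-4)

    def test_tied_data_matches_grid_search(self, rng):
        x, t, e = _sim_cohort(rng, 80, beta=0.4)
        t = np.ceil(t)  # monthly resolution: heavy ties
        e = np.where(t > 0, e, 0)
        rec = survassoc.cox_fit(x, t, e)
        assert rec.coef == pytest.approx(cox_grid_search(x, t, e), abs=1e-4)

    def test_negation_inverts_hr(self, rng):
        x, t, e = _sim_cohort(rng, 100, beta=0.5)
        a = survassoc.cox_fit(x, t, e)
        b = survassoc.cox_fit(-x, t, e)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        x, t, e = _sim_cohort(rng, 250, beta=-0.5)
        t = np.ceil(t)
        rec = survassoc.cox_fit(x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e")
        assert rec.coef == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert rec.se == pytest.approx(cph.standard_errors_.iloc[0],
                                       abs=1e-6)

    def test_breslow_differs_from_efron_under_ties(self, rng):
        x, t, e = _sim_cohort(rng, 120, beta=0.6)
        t = np.ceil(t / 5)
        efron = survassoc.cox_fit(x, t, e, ties="efron")
        breslow = survassoc.cox_fit(x, t, e, ties="breslow")
        assert efron.coef != breslow.coef

    def test_hr_recovery_simulation(self):
        # protective covariate, true HR 0.6: estimates centre on the truth
        hrs = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            x, t, e = _sim_cohort(rng, 500, beta=np.log(0.6))
            hrs.append(survassoc.cox_fit(x, t, e).hr)
        assert np.mean(hrs) == pytest.approx(0.6, abs=0.05)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            survassoc.cox_fit(np.ones(6), TOY_T, TOY_E)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            survassoc.cox_fit(TOY_X, TOY_T, np.zeros(6, dtype=int))

    def test_monotone_separation_raises(self):
        # events perfectly ordered along the covariate: beta diverges
        x = np.arange(20, dtype=float)
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20, dtype=int)
        with pytest.raises(survassoc.ConvergenceError):
            survassoc.cox_fit(x, t, e)

    def test_record_invariants(self, rng):
        x, t, e = _sim_cohort(rng, 150, beta=0.3)
        rec = survassoc.cox_fit(x, t, e)
        assert rec.ci_low <= rec.hr <= rec.ci_high
        assert rec.hr > 0 and rec.gs >= 0


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert survassoc.benjamini_hochberg([0.123])[0] == \
            pytest.approx(0.123)

    def test_hand_step_up(self):
        out = survassoc.benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_reference_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=25)
        out = survassoc.benjamini_hochberg(p)
        assert np.allclose(out, bh_reference(p), atol=1e-12)
        assert (out >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            survassoc.benjamini_hochberg([0.5, 1.2])


class TestModuleTraitCorrelation:
    def test_perfect_correlation(self):
        stage = np.array([2.0, 3.0, 2.0, 3.0, 3.0])
        r, p = survassoc.module_trait_correlation(stage, stage)
        assert r == pytest.approx(1.0)

    def test_formula_oracle(self, rng):
        me = rng.normal(size=10)
        stage = rng.choice([2.0, 3.0], size=10)
        r, _ = survassoc.module_trait_correlation(me, stage)
        mc, sc = me - me.mean(), stage - stage.mean()
        expected = (mc * sc).sum() / np.sqrt((mc**2).sum() * (sc**2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_null_correlation_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            me = rng.normal(size=461)
            stage = rng.choice([2.0, 3.0], size=461)
            r, _ = survassoc.module_trait_correlation(me, stage)
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_constant_stage_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            survassoc.module_trait_correlation(rng.normal(size=5),
                                               np.full(5, 2.0))


class TestSubtypes:
    @pytest.mark.parametrize("markers,expected", [
        (("high", "positive", "mutant", "wildtype"), "type1"),
        (("low", "positive", "mutant", "wildtype"), "type2"),
        (("low", "negative", "wildtype", "mutant"), "type3"),
        (("low", "negative", "wildtype", "wildtype"), "type4"),
        (("high", "negative", "wildtype", "wildtype"), "type5"),
        (("missing", "negative", "wildtype", "mutant"), "unclassified"),
        (("high", "positive", "mutant", "mutant"), "unclassified"),
        ((None, "negative", "wildtype", "mutant"), "unclassified"),
    ])
    def test_rule_table(self, markers, expected):
        assert survassoc.assign_subtype(*markers) == expected

    def test_partition_of_marker_complete_cohort(self):
        # every complete marker combination maps to exactly one label
        labels = set()
        for msi in ("high", "low"):
            for cimp in ("positive", "negative"):
                for braf in ("mutant", "wildtype"):
                    for kras in ("mutant", "wildtype"):
                        labels.add(survassoc.assign_subtype(
                            msi, cimp, braf, kras))
        assert {"type1", "type2", "type3", "type4", "type5"} < labels


class TestHubGenes:
    def _inputs(self, rng, n=30):
        genes = [f"g{i:02d}" for i in range(n)]
        part = pd.Series("green", index=genes)
        conn = pd.DataFrame({"k_in": rng.uniform(0, 20, n)}, index=genes)
        assoc = pd.DataFrame({"target": genes,
                              "gs": rng.uniform(0, 4, n)})
        return part, conn, assoc

    def test_rank7_high_gs_is_hub(self):
        genes = [f"g{i:02d}" for i in range(15)]
        part = pd.Series("green", index=genes)
        conn = pd.DataFrame({"k_in": np.arange(15, 0, -1.0)}, index=genes)
        gs = np.full(15, 1.0)
        gs[6] = -np.log10(4.40e-4)    # ~3.36, k_in rank 7
        assoc = pd.DataFrame({"target": genes, "gs": gs})
        rep = survassoc.select_hub_genes(part, conn, assoc, "green")
        row = rep[rep["gene_id"] == "g06"].iloc[0]
        assert row["k_in_rank"] == 7 and row["is_hub"]

    def test_rank1_low_gs_not_hub(self):
        genes = ["a", "b", "c"]
        part = pd.Series("green", index=genes)
        conn = pd.DataFrame({"k_in": [9.0, 5.0, 1.0]}, index=genes)
        assoc = pd.DataFrame({"target": genes, "gs": [1.9, 2.5, 0.1]})
        rep = survassoc.select_hub_genes(part, conn, assoc, "green")
        assert not rep.loc[rep["gene_id"] == "a", "is_hub"].iloc[0]
        assert rep.loc[rep["gene_id"] == "b", "is_hub"].iloc[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_brute_force_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        part, conn, assoc = self._inputs(rng)
        rep = survassoc.select_hub_genes(part, conn, assoc, "green")
        ranks = {g: r for r, g in enumerate(
            sorted(part.index,
                   key=lambda g: (-conn.loc[g, "k_in"], g)), start=1)}
        gs = assoc.set_index("target")["gs"]
        for _, row in rep.iterrows():
            expected = ranks[row["gene_id"]] <= 10 and \
                gs[row["gene_id"]] > 2
            assert bool(row["is_hub"]) == expected


class TestKMCurves:
    def test_no_events_flat_curve(self):
        curves, _ = survassoc.km_curves(
            np.arange(9.0), np.full(9, 12.0), np.zeros(9, dtype=int))
        for c in curves:
            assert np.allclose(c.survival, 1.0)

    def test_two_subject_hand_product_limit(self):
        curves, _ = survassoc.km_curves(
            np.array([1.0, 2.0]), np.array([1.0, 2.0]),
            np.array([1, 1]), n_groups=1, labels=("all",))
        assert np.allclose(curves[0].survival, [1.0, 0.5, 0.0])

    def test_matches_reference_estimator(self, rng):
        t = np.ceil(rng.exponential(20, size=60))
        e = rng.integers(0, 2, size=60)
        if e.sum() == 0:
            e[0] = 1
        curves, _ = survassoc.km_curves(np.zeros(60), t, e, n_groups=1,
                                        labels=("all",))
        ref_t, ref_s = km_reference(t, e)
        got = {float(tt): ss for tt, ss in
               zip(curves[0].times, curves[0].survival)}
        for tt, ss in zip(ref_t, ref_s):
            assert got[tt] == pytest.approx(ss, abs=1e-10)

    def test_flat_after_last_event(self):
        t = np.array([1.0, 2.0, 8.0, 9.0, 10.0])
        e = np.array([1, 1, 0, 0, 0])
        curves, _ = survassoc.km_curves(np.zeros(5), t, e, n_groups=1,
                                        labels=("all",))
        surv = curves[0].survival
        assert surv[-1] == surv[np.searchsorted(curves[0].times, 2.0)]

    def test_survival_monotone_from_one(self, small_study):
        _, clin, truth = small_study
        me = truth.factors.loc["m1"]
        curves, logrank_p = survassoc.km_curves(
            me.to_numpy(), clin["rfs_months"].to_numpy(),
            clin["event"].to_numpy())
        assert len(curves) == 3
        for c in curves:
            assert c.survival[0] == 1.0
            assert (np.diff(c.survival) <= 1e-12).all()
        assert 0.0 <= logrank_p <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            survassoc.km_curves(np.ones(6), np.arange(1.0, 7.0),
                                np.ones(6, dtype=int))


class TestAssociateModules:
    def test_planted_protective_module_found(self, small_study):
        expr, clin, truth = small_study
        eig = moduledetect.module_eigengene(expr, truth.grey_partition())
        cov = eig.eigengenes.apply(survassoc.scale_eigengene, axis=1)
        tab = survassoc.associate_modules(cov, clin)
        best = tab.sort_values("p").iloc[0]
        assert best["target"] == "m1"
        assert best["hr"] < 1.0
        assert (tab["fdr"] >= tab["p"] - 1e-12).all()

    def test_stratum_subsetting(self, small_study):
        expr, clin, truth = small_study
        eig = moduledetect.module_eigengene(expr, truth.grey_partition())
        cov = eig.eigengenes.apply(survassoc.scale_eigengene, axis=1)
        subtypes = truth.subtypes
        tab = survassoc.associate_modules(cov, clin, stratum="type4",
                                          subtypes=subtypes)
        n_type4 = int((subtypes == "type4").sum())
        assert (tab["n"] == n_type4).all()

    def test_few_events_warns(self, small_study):
        expr, clin, truth = small_study
        eig = moduledetect.module_eigengene(expr, truth.grey_partition())
        cov = eig.eigengenes.apply(survassoc.scale_eigengene, axis=1)
        tiny = clin.head(14).copy()
        with pytest.warns(UserWarning, match="events"):
            survassoc.associate_modules(cov[tiny["sample_id"]], tiny)


class TestAssociateGenes:
    def test_protective_gene_detected(self):
        rng = np.random.default_rng(5)
        n = 400
        factor = rng.standard_normal(n)
        t_event = rng.exponential(30 * np.exp(0.5 * factor))
        c = rng.uniform(0, 60, n)
        t = np.minimum(t_event, c)
        e = (t_event <= c).astype(int)
        clin = pd.DataFrame({"sample_id": [f"s{j}" for j in range(n)],
                             "rfs_months": t, "event": e})
        expr = pd.DataFrame(
            {f"s{j}": [factor[j], rng.normal()] for j in range(n)},
            index=["protective", "noise"])
        tab = survassoc.associate_genes(expr, clin).set_index("target")
        assert tab.loc["protective", "hr"] < 1
        assert tab.loc["protective", "p"] < 0.01
        assert tab.loc["noise", "gs"] < 2
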