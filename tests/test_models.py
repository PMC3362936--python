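"""Model builders and the analysis pipeline on simulated data."""

import numpy as np
import pytest

from tolgen import models as M
from tolgen import reml as R
from tolgen import simulate as S


class TestSpecShapes:
    def test_model1_terms(self):
        spec = M.model1_spec("bw2")
        assert len(spec.fixed_factors) == 3  # gender, batch x stable, age
        assert len(spec.random) == 2
        assert spec.random[0].structure == "pedigree"
        assert spec.random[1].structure == "iid"

    def test_model1_bw7_uses_bw7_age(self):
        assert ("age_bw7",) in [tuple(f) for f in M.model1_spec("bw7").fixed_factors]

    def test_model1_rejects_non_weight(self):
        with pytest.raises(R.DesignError):
            M.model1_spec("ratio")

    def test_model2_adds_person(self):
        spec = M.model2_spec()
        assert len(spec.fixed_factors) == 4
        assert ("person",) in [tuple(f) for f in spec.fixed_factors]

    def test_model3_variance_parameter_count(self, tiny_population):
        ped, tab, _ = tiny_population
        tab2 = M.prepare_tolerance_table(tab)
        asm = R.build_design(M.model3_spec(), tab2, ped)
        model = R.REMLModel(asm)
        # 3 animal + 3 dam (unstructured 2x2 blocks) + 5 residual classes
        assert model.npar == 11

    def test_model3_covariate_adds_one_fixed_column(self, tiny_population):
        ped, tab, _ = tiny_population
        tab2 = M.prepare_tolerance_table(tab).dropna(subset=["bw2"])
        a0 = R.build_design(M.model3_spec(False), tab2, ped)
        a1 = R.build_design(M.model3_spec(True), tab2, ped)
        assert a1.p == a0.p + 1
        assert R.REMLModel(a0).npar == R.REMLModel(a1).npar

    def test_model3_slope_covariate_is_coded_severity(self, tiny_population):
        ped, tab, _ = tiny_population
        tab2 = M.prepare_tolerance_table(tab)
        asm = R.build_design(M.model3_spec(), tab2, ped)
        animal = asm.terms[0]
        # per-record slope covariate equals the plateau-coded heart ratio
        row = animal.Z[5].toarray().ravel()
        lev = np.flatnonzero(row)[0] // 2
        assert row[2 * lev + 1] == pytest.approx(
            tab2.dropna(subset=["bw7", "ratio"]).iloc[5].ratioplat
        )


class TestToleranceFit:
    def test_fit_and_population_slope(self, small_population):
        ped, tab, truth = small_population
        rep = M.fit_tolerance_model(tab, ped, compute_se=False)
        assert rep.converged
        slope = M.population_mean_slope(rep, tab)
        # single replicate at 1200 birds: the population slope is estimated
        # with an SE of a few g/%, so only a loose bracket is meaningful
        assert -25.0 < slope < -5.0
        g, m = M.genetic_blocks(rep)
        assert g.is_psd() and m.is_psd()
        ve = M.residual_class_variances(rep)
        assert len(ve) == 5 and (ve > 0).all()

    def test_with_and_without_bw2_covariate_agree_roughly(self, small_population):
        ped, tab, _ = small_population
        rep0 = M.fit_tolerance_model(tab, ped, compute_se=False)
        rep1 = M.fit_tolerance_model(
            tab, ped, include_bw2_covariate=True, compute_se=False
        )
        # BW2 is (nearly) independent of severity in the generator, so the
        # slope variance should not shift by more than sampling noise scale
        v0, v1 = rep0["animal:var(slope)"], rep1["animal:var(slope)"]
        assert v1 == pytest.approx(v0, abs=0.8 * max(v0, 20.0))

    def test_healthy_only_intercept_identity(self, small_population):
        """Fitting the plain BW7 mean model on healthy birds only must agree
        with the reaction-norm intercept variance (the trajectory at zero
        severity), up to sampling noise."""
        ped, tab, _ = small_population
        rep3 = M.fit_tolerance_model(tab, ped, compute_se=False)
        healthy = tab[tab.ratio <= 29.0]
        rep1 = M.fit_mean_model(healthy, ped, "bw7", compute_se=False)
        vg_int = rep3["animal:var(intercept)"]
        vg_mean = rep1["animal:var(mean)"]
        assert vg_mean == pytest.approx(vg_int, rel=0.8)

    def test_slope_variance_and_ebv_spread_shrink_without_tolerance_variation(self):
        """Paired generator comparison: removing the genetic/maternal slope
        variation must shrink both the fitted slope variance and the spread
        of slope EBVs. The slope-variance estimator is strongly skewed at
        this scale (it is censored at zero), so means over paired seeds are
        compared rather than single fits."""
        out = {}
        for label, gv, mv in (("free", 1e-6, 1e-6), ("with", 57.8, 23.0)):
            svs, esd = [], []
            for seed in (9, 10, 11):
                cfg = S.SimConfig.reduced(
                    20, 6, 8,
                    genetic_vars=(309.0, 15.1, 10640.0, gv),
                    maternal_vars=(59.3, 1.17, 2771.0, mv),
                )
                ped, tab, _ = S.simulate_population(cfg, seed=seed)
                rep = M.fit_tolerance_model(tab, ped, compute_se=False)
                svs.append(rep["animal:var(slope)"])
                sols = rep.solutions["animal"]
                off = [a for a in tab.animal_id if a in sols.index]
                esd.append(float(sols.loc[off, "slope"].std()))
            out[label] = (np.mean(svs), np.mean(esd))
        assert out["with"][0] > out["free"][0]
        assert out["with"][1] > out["free"][1]


class TestMeanModels:
    def test_base_population_ebvs_average_near_zero(self, small_population):
        ped, tab, _ = small_population
        rep = M.fit_mean_model(tab, ped, "bw2", compute_se=False)
        founders = ped.ids[ped.founder_mask]
        ebv = rep.solutions["animal"].loc[founders, "mean"]
        # BLUPs of the base population centre on zero under the fitted model
        assert abs(ebv.mean()) < 0.15 * ebv.std()

    def test_omitting_cutter_effect_inflates_ratio_residual(self, small_population):
        ped, tab, _ = small_population
        with_person = M.fit_mean_model(tab, ped, "ratio", compute_se=False)
        no_person = R.reml_fit(
            R.build_design(M.model1_spec("bw2").__class__(
                response="ratio",
                fixed_factors=[("gender",), ("batch", "stable"), ("age_ratio",)],
                random=M.model1_spec("bw2").random,
            ), tab, ped),
            compute_se=False,
        )
        assert (
            no_person["residual:var(residual)"]
            > with_person["residual:var(residual)"]
        )


class TestExtendedFit:
    def test_extended_fit_reports_trait_blocks(self, small_population):
        ped, tab, _ = small_population
        rep = M.extended_fit(tab, ped, "bw2", compute_se=False)
        # 6 + 6 block components + 6 residual classes + 1 residual covariance
        assert rep.n_parameters == 19
        for c1, c2 in (("bw2.mean", "bw7.intercept"), ("bw2.mean", "bw7.slope")):
            est, _ = M.correlation_from_bivariate(rep, "animal", c1, c2)
            assert np.isfinite(est) and abs(est) <= 1.0 + 1e-9


class TestBivariate:
    def test_null_genetic_correlation_recovered(self):
        cfg = S.SimConfig.reduced(
            25, 6, 8,
            genetic_corr=np.eye(4),
            maternal_corr=np.eye(4),
        )
        ped, tab, _ = S.simulate_population(cfg, seed=17)
        rep = M.bivariate_fit(tab, ped, "bw2", "ratio", compute_se=False)
        est, _ = M.correlation_from_bivariate(rep, "animal", "bw2.mean", "ratio.mean")
        assert abs(est) < 0.35  # null within sampling noise at this scale

    def test_phenotypic_correlation_matches_raw_product_moment(self):
        cfg = S.SimConfig.reduced(40, 8, 10)
        ped, tab, _ = S.simulate_population(cfg, seed=23)
        rep = M.bivariate_fit(tab, ped, "bw2", "bw7", compute_se=False)
        est, _ = M.phenotypic_correlation(rep, "bw2", "bw7")
        both = tab.dropna(subset=["bw2", "bw7"])
        raw = np.corrcoef(both.bw2, both.bw7)[0, 1]
        assert est == pytest.approx(raw, abs=0.08)


class TestFullAnalysis:
    def test_bundle_smoke(self, tiny_population):
        ped, tab, _ = tiny_population
        bundle = M.run_full_analysis(
            tab, ped, with_correlations=False, compute_se=False
        )
        assert bundle.complete
        assert set(bundle.mean_models) == {"bw2", "bw7", "ratio"}
        assert bundle.trajectories is not None
        assert bundle.trajectories.r_with_healthy.iloc[0] == pytest.approx(1.0)
        assert np.allclose(
            bundle.trajectories.v_p,
            bundle.trajectories[["v_g", "v_m", "v_e"]].sum(axis=1),
        )
        assert set(bundle.ebv) == {"offspring", "sires", "dams"}
        # EBV ranges bracket the per-group solutions
        off = bundle.ebv["offspring"]
        assert off["min"] <= off["mean"] <= off["max"]

    def test_empty_table_rejected(self, tiny_population):
        ped, tab, _ = tiny_population
        with pytest.raises(R.DesignError):
            M.run_full_analysis(tab.iloc[0:0], ped)
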