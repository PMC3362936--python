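"""REML engine: likelihood, derivatives, oracle equivalences, SEs."""

import numpy as np
import pandas as pd
import pytest

from tolgen import pedigree as P
from tolgen import reml as R


def _tiny_model(seed=3, n=30):
    """Random-regression design on a 3-sire, 6-dam mini population."""
    rng = np.random.default_rng(seed)
    trips = [(f"s{i}", None, None) for i in range(3)] + [
        (f"d{i}", None, None) for i in range(6)
    ]
    recs = []
    for k in range(n):
        s, d = rng.integers(0, 3), rng.integers(0, 6)
        trips.append((f"o{k}", f"s{s}", f"d{d}"))
        recs.append(
            dict(animal_id=f"o{k}", dam_id=f"d{d}", gender=str(rng.integers(0, 2)),
                 t=float(rng.uniform(0, 10)), y=float(rng.normal(100, 10)))
        )
    ped = P.make_pedigree(trips)
    tab = pd.DataFrame(recs)
    tab["rclass"] = (tab.t > 5).astype(int)
    spec = R.ModelSpec(
        response="y",
        fixed_factors=[("gender",)],
        slope_col="t",
        random=[
            R.RandomTermSpec("animal", "animal_id", "pedigree", ("1", "t"),
                             ("intercept", "slope")),
            R.RandomTermSpec("dam", "dam_id", "iid", ("1", "t"),
                             ("intercept", "slope")),
        ],
        residual_classes="rclass",
    )
    asm = R.build_design(spec, tab, ped)
    return ped, asm


def dense_reml_loglik(ped, asm, theta):
    """Marginal-covariance REML log-likelihood (independent oracle route)."""
    sigmas, rvar, _ = R._unpack(theta, asm)
    n = asm.n
    A = P.tabular_a(ped)
    V = np.diag(rvar[asm.residual.classes]).astype(float)
    for t, S in zip(asm.terms, sigmas):
        K = A if t.kinv is not None else np.eye(t.m)
        Z = t.Z.toarray()
        V += Z @ np.kron(K, S) @ Z.T
    X = asm.X.toarray()
    y = asm.y
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    Pm = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    p = X.shape[1]
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + y @ Pm @ y
    )


class TestLikelihoodAndDerivatives:
    def test_mme_loglik_equals_dense_oracle(self):
        ped, asm = _tiny_model()
        model = R.REMLModel(asm)
        rng = np.random.default_rng(1)
        for _ in range(3):
            theta = model.default_start() * rng.uniform(0.6, 1.5, model.npar)
            for k, info in enumerate(model.infos):
                if info.kind == "g" and not info.is_variance:
                    theta[k] = rng.uniform(-0.05, 0.05)
            l_mme = model.loglik(theta)
            l_dense = dense_reml_loglik(ped, asm, theta)
            assert l_mme == pytest.approx(l_dense, rel=1e-9)

    def test_analytic_scores_match_numeric_gradient(self):
        _, asm = _tiny_model(seed=5)
        model = R.REMLModel(asm)
        theta = model.default_start()
        cache = model._evaluate(theta)
        s_mats, w_inv = model._iteration_quantities(cache)
        g = model.scores(cache, s_mats, w_inv)
        gn = np.zeros_like(g)
        for k in range(model.npar):
            h = max(abs(theta[k]), 1.0) * 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            gn[k] = (model.loglik(tp) - model.loglik(tm)) / (2 * h)
        assert np.allclose(g, gn, rtol=1e-4, atol=1e-5)


class TestOracleEquivalences:
    def test_balanced_half_sib_reml_equals_anova(self):
        rng = np.random.default_rng(7)
        ns, k = 50, 20
        sire_eff = rng.normal(0, np.sqrt(40), ns)
        tab = pd.DataFrame(
            [
                {"sire": f"s{s}", "y": 100 + sire_eff[s] + rng.normal(0, np.sqrt(160))}
                for s in range(ns)
                for _ in range(k)
            ]
        )
        asm = R.build_design(
            R.ModelSpec(response="y",
                        random=[R.RandomTermSpec("sire", "sire", "iid")]),
            tab,
        )
        rep = R.reml_fit(asm)
        ybar_s = tab.groupby("sire")["y"].mean()
        ms_b = k * ((ybar_s - tab.y.mean()) ** 2).sum() / (ns - 1)
        ms_w = ((tab.y - tab.sire.map(ybar_s)) ** 2).sum() / (ns * (k - 1))
        anova_sire = (ms_b - ms_w) / k
        assert rep["sire:var(1)"] == pytest.approx(anova_sire, rel=1e-6)
        assert rep["residual:var(residual)"] == pytest.approx(ms_w, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(11)
        groups = np.repeat(np.arange(40), 8)
        u = rng.normal(0, 2.0, 40)
        tab = pd.DataFrame(
            {"g": groups.astype(str), "x": rng.normal(size=len(groups))}
        )
        tab["y"] = 5 + 0.7 * tab.x + u[groups] + rng.normal(0, 1.5, len(groups))
        asm = R.build_design(
            R.ModelSpec(response="y", fixed_covariates=["x"],
                        random=[R.RandomTermSpec("grp", "g", "iid")]),
            tab,
        )
        rep = R.reml_fit(asm)
        sm_fit = MixedLM.from_formula("y ~ x", groups="g", data=tab).fit(reml=True)
        assert rep["grp:var(1)"] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                                  rel=1e-4)
        assert rep["residual:var(residual)"] == pytest.approx(sm_fit.scale, rel=1e-4)
        assert rep.logl == pytest.approx(sm_fit.llf, abs=1e-5)

    def test_zero_variance_truth_hits_boundary(self):
        rng = np.random.default_rng(13)
        tab = pd.DataFrame(
            {"g": np.repeat([f"s{i}" for i in range(30)], 10),
             "y": rng.normal(0, 1.0, 300)}
        )
        asm = R.build_design(
            R.ModelSpec(response="y", random=[R.RandomTermSpec("grp", "g", "iid")]),
            tab,
        )
        rep = R.reml_fit(asm)
        vy = float(np.var(tab.y))
        assert rep["grp:var(1)"] < 0.05 * vy  # at or near the zero boundary
        assert rep["residual:var(residual)"] == pytest.approx(vy, rel=0.05)


class TestStandardErrors:
    def test_delta_se_identity_function(self):
        _, asm = _tiny_model(seed=9)
        rep = R.reml_fit(asm, max_iter=60)
        name = "residual:var(class1)"
        se = R.delta_se(rep, lambda p: p[name])
        assert se == pytest.approx(rep.se_of(name), rel=1e-4)

    def test_h2_delta_se_matches_parametric_bootstrap(self):
        """Balanced half-sib design: the delta-method SE of the sire-variance
        ratio must agree with a parametric bootstrap that exploits the exact
        REML = ANOVA equivalence on balanced data (closed form per draw)."""
        rng = np.random.default_rng(21)
        ns, k = 40, 10
        s2s, s2e = 30.0, 120.0
        tab = pd.DataFrame(
            [
                {"sire": f"s{s}", "y": 50 + es + rng.normal(0, np.sqrt(s2e))}
                for s, es in enumerate(rng.normal(0, np.sqrt(s2s), ns))
                for _ in range(k)
            ]
        )
        asm = R.build_design(
            R.ModelSpec(response="y", random=[R.RandomTermSpec("sire", "sire", "iid")]),
            tab,
        )
        rep = R.reml_fit(asm)
        vs, ve = rep["sire:var(1)"], rep["residual:var(residual)"]

        def ratio(p):
            return p["sire:var(1)"] / (p["sire:var(1)"] + p["residual:var(residual)"])

        se_delta = R.delta_se(rep, ratio)
        # bootstrap: closed-form ANOVA estimator on balanced re-simulated data
        boots = []
        for _ in range(500):
            sir = rng.normal(0, np.sqrt(vs), ns)
            yb = (np.repeat(sir, k) + rng.normal(0, np.sqrt(ve), ns * k)).reshape(ns, k)
            msb = k * ((yb.mean(1) - yb.mean()) ** 2).sum() / (ns - 1)
            msw = ((yb - yb.mean(1, keepdims=True)) ** 2).sum() / (ns * (k - 1))
            vsb = max((msb - msw) / k, 0.0)
            boots.append(vsb / (vsb + msw))
        se_boot = np.std(boots, ddof=1)
        assert se_delta == pytest.approx(se_boot, rel=0.2)

    def test_aic_bic_from_report(self):
        _, asm = _tiny_model(seed=15)
        rep = R.reml_fit(asm, max_iter=50, compute_se=False)
        aic, bic = R.information_criteria(rep)
        assert aic == pytest.approx(-2 * rep.logl + 2 * rep.n_parameters)
        assert bic == pytest.approx(
            -2 * rep.logl + rep.n_parameters * np.log(rep.n_records)
        )


class TestDesignConstruction:
    def test_rank_deficiency_reported_with_names(self):
        tab = pd.DataFrame(
            {"animal_id": ["a", "b", "c", "d"], "dam_id": ["d1"] * 4,
             "f1": ["x", "x", "y", "y"], "f2": ["u", "u", "v", "v"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        spec = R.ModelSpec(response="y", fixed_factors=[("f1",), ("f2",)])
        with pytest.raises(R.DesignError, match="confounded|rank"):
            R.build_design(spec, tab)

    def test_single_level_factor_rejected(self):
        tab = pd.DataFrame(
            {"animal_id": list("abcd"), "f1": ["x"] * 4, "y": [1.0, 2, 3, 4]}
        )
        spec = R.ModelSpec(response="y", fixed_factors=[("f1",)])
        with pytest.raises(R.DesignError, match="single level"):
            R.build_design(spec, tab)

    def test_missing_response_rows_dropped(self, tiny_population):
        ped, tab, _ = tiny_population
        from tolgen.models import model1_spec

        asm = R.build_design(model1_spec("bw7"), tab, ped)
        assert asm.n == int(tab.bw7.notna().sum())
        # all pedigree animals keep equations even without records
        assert asm.terms[0].m == len(ped)
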