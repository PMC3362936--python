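"""Reproducibility studies: worked examples and parameter-recovery runs.

These drivers re-derive the analysis's checkable quantities from scratch:

* worked examples evaluate the covariance-function arithmetic on the
  published component values (which are also the simulator defaults);
* recovery studies simulate populations at reduced scale with those same
  generating values, refit them with the matching animal models, and
  summarise the estimates with Monte-Carlo standard errors.

Each study takes an explicit base seed; replicate seeds are derived
deterministically from it.
"""

from __future__ import annotations

import numpy as np

from . import covfun, models, plateau
from .simulate import SimConfig, simulate_population


def _rep_seed(base_seed: int, rep: int) -> int:
    return int(np.random.SeedSequence((base_seed, rep)).generate_state(1)[0] % (2**31 - 1))


def worked_examples(cfg: SimConfig | None = None) -> dict:
    """Covariance-function arithmetic on the reference component values.

    Returns h^2/m^2 of the two body weights from their components, and the
    healthy-vs-affected genetic correlation of the tolerance reaction norm
    at the healthy point and at heart ratio 46.5%.
    """
    cfg = cfg or SimConfig()
    g_int, g_slope = cfg.genetic_vars[2], cfg.genetic_vars[3]
    r_int_slope = float(cfg.genetic_corr[2, 3])
    g = covfun.GenCov2.from_correlation(g_int, g_slope, r_int_slope)
    # BW2: V_G, V_M and V_P -> ratios; BW7 likewise
    h2_bw2, m2_bw2 = covfun.variance_ratios(
        cfg.genetic_vars[0], cfg.maternal_vars[0], cfg.residual_bw2
    )
    v_g7, v_m7, v_p7 = 12952.0, 2913.0, 73479.0
    h2_bw7, m2_bw7 = covfun.variance_ratios(v_g7, v_m7, v_p7 - v_g7 - v_m7)
    t_severe = 46.5 - cfg.threshold
    return {
        "h2_bw2": h2_bw2,
        "m2_bw2": m2_bw2,
        "h2_bw7": h2_bw7,
        "m2_bw7": m2_bw7,
        "r_healthy_at_0": covfun.correlation_with_healthy(g, 0.0),
        "r_healthy_at_46_5": covfun.correlation_with_healthy(g, t_severe),
        "vg_at_0": covfun.trajectory_variance(g, 0.0),
    }


def recover_h2_bw2(
    n_sires: int = 40,
    dams_per_sire: int = 8,
    offspring_per_dam: int = 10,
    n_reps: int = 100,
    base_seed: int = 1,
) -> dict:
    """Mean-model recovery of the 2-week body-weight heritability.

    Simulates `n_reps` reduced-scale populations with the reference BW2
    components and refits each with the trait-mean animal model.
    """
    h2s, vgs, vms, ves = [], [], [], []
    cfg = SimConfig.reduced(n_sires, dams_per_sire, offspring_per_dam)
    for rep in range(n_reps):
        ped, tab, _ = simulate_population(cfg, seed=_rep_seed(base_seed, rep))
        fit = models.fit_mean_model(tab, ped, "bw2", compute_se=False)
        vg = fit["animal:var(mean)"]
        vm = fit["dam:var(mean)"]
        ve = fit["residual:var(residual)"]
        h2s.append(vg / (vg + vm + ve))
        vgs.append(vg)
        vms.append(vm)
        ves.append(ve)

    def summ(x):
        x = np.asarray(x)
        return {"mean": float(x.mean()),
                "mc_se": float(x.std(ddof=1) / np.sqrt(len(x))), "n": len(x)}

    truth_h2 = cfg.genetic_vars[0] / (
        cfg.genetic_vars[0] + cfg.maternal_vars[0] + cfg.residual_bw2
    )
    return {
        "h2": summ(h2s),
        "v_g": summ(vgs),
        "v_m": summ(vms),
        "v_e": summ(ves),
        "truth": {"h2": truth_h2, "v_g": cfg.genetic_vars[0],
                  "v_m": cfg.maternal_vars[0], "v_e": cfg.residual_bw2},
        "n_records_per_rep": cfg.n_offspring,
    }


def recover_tolerance_components(
    n_sires: int = 30,
    dams_per_sire: int = 10,
    offspring_per_dam: int = 10,
    n_reps: int = 20,
    base_seed: int = 1,
) -> dict:
    """Random-regression recovery of the tolerance components.

    Refits the reaction-norm model on `n_reps` simulated populations and
    summarises every generating component (intercept/slope blocks, dam
    blocks, residual classes) plus the fixed population slope.
    """
    cfg = SimConfig.reduced(n_sires, dams_per_sire, offspring_per_dam)
    names = None
    all_est = []
    slopes = []
    conv = 0
    for rep in range(n_reps):
        ped, tab, _ = simulate_population(cfg, seed=_rep_seed(base_seed, rep))
        fit = models.fit_tolerance_model(tab, ped, compute_se=False)
        conv += bool(fit.converged)
        names = fit.names
        all_est.append(fit.estimates.copy())
        slopes.append(models.population_mean_slope(fit, tab))
    E = np.asarray(all_est)
    out = {"n_reps": n_reps, "n_converged": conv,
           "n_records_per_rep": cfg.n_offspring, "components": {}}
    gcov = cfg.genetic_cov()
    mcov = cfg.maternal_cov()
    truth = {
        "animal:var(intercept)": gcov[2, 2],
        "animal:cov(slope,intercept)": gcov[2, 3],
        "animal:var(slope)": gcov[3, 3],
        "dam:var(intercept)": mcov[2, 2],
        "dam:cov(slope,intercept)": mcov[2, 3],
        "dam:var(slope)": mcov[3, 3],
    }
    for c, ve in enumerate(cfg.bw7_class_variances()):
        truth[f"residual:var(class{c+1})"] = float(ve)
    for j, nm in enumerate(names):
        x = E[:, j]
        out["components"][nm] = {
            "mean": float(x.mean()),
            "mc_se": float(x.std(ddof=1) / np.sqrt(len(x))),
            "truth": truth.get(nm),
        }
    s = np.asarray(slopes)
    out["population_slope"] = {
        "mean": float(s.mean()),
        "mc_se": float(s.std(ddof=1) / np.sqrt(len(s))),
        "truth": cfg.population_slope,
    }
    return out


def recover_population_slope(
    n_sires: int = 42,
    dams_per_sire: int = 10,
    offspring_per_dam: int = 12,
    n_reps: int = 10,
    base_seed: int = 1,
) -> dict:
    """Fixed population tolerance slope from larger single-replicate fits."""
    cfg = SimConfig.reduced(n_sires, dams_per_sire, offspring_per_dam)
    slopes = []
    for rep in range(n_reps):
        ped, tab, _ = simulate_population(cfg, seed=_rep_seed(base_seed, rep))
        fit = models.fit_tolerance_model(tab, ped, compute_se=False)
        slopes.append(models.population_mean_slope(fit, tab))
    s = np.asarray(slopes)
    return {
        "mean": float(s.mean()),
        "mc_se": float(s.std(ddof=1) / np.sqrt(len(s))),
        "truth": cfg.population_slope,
        "n_reps": n_reps,
        "n_records_per_rep": cfg.n_offspring,
    }


def expected_conditional_slope(cfg: SimConfig | None = None) -> float:
    """Closed-form mean tolerance slope among affected birds.

    Severity is a function of the RATIO phenotype, which is genetically and
    maternally correlated with the slope; conditioning on being affected
    (RATIO above the threshold) therefore shifts the mean slope by

        (cov_G + cov_M) / V_P(RATIO) * E[RATIO - mu | RATIO > threshold],

    with the truncated-normal mean sigma * phi(z) / (1 - Phi(z)). This is
    the estimand the reaction-norm fixed slope targets on generated data.
    """
    from scipy import stats

    cfg = cfg or SimConfig()
    gcov = cfg.genetic_cov()
    mcov = cfg.maternal_cov()
    v_ratio = gcov[1, 1] + mcov[1, 1] + cfg.residual_ratio
    sd = np.sqrt(v_ratio)
    z = (cfg.threshold - cfg.mean_ratio) / sd
    excess = sd * stats.norm.pdf(z) / (1.0 - stats.norm.cdf(z))
    shift = (gcov[1, 3] + mcov[1, 3]) / v_ratio * excess
    return float(cfg.population_slope + shift)


def threshold_selection_study(
    n_seeds: int = 10,
    n_sires: int = 25,
    dams_per_sire: int = 6,
    offspring_per_dam: int = 8,
    candidates=(27.0, 28.0, 29.0, 30.0),
    include_linear: bool = True,
    base_seed: int = 1,
) -> dict:
    """Threshold-scan behaviour on data generated with a 29% plateau.

    Returns the per-seed selected thresholds and, when `include_linear`,
    the per-seed AIC margin of the plateau model over the linear model.
    """
    cfg = SimConfig.reduced(n_sires, dams_per_sire, offspring_per_dam)
    selected, margins = [], []
    for rep in range(n_seeds):
        ped, tab, _ = simulate_population(cfg, seed=_rep_seed(base_seed, rep))
        df, sel = plateau.threshold_scan(
            tab, ped, candidates, include_linear=include_linear, compute_se=False
        )
        selected.append(sel)
        if include_linear:
            pl = df[(df.model == "plateau") & (df.threshold == cfg.threshold)]
            li = df[df.model == "linear"]
            if len(pl) and len(li):
                margins.append(float(li.aic.iloc[0] - pl.aic.iloc[0]))
    sel = np.asarray(selected)
    return {
        "selected": sel.tolist(),
        "n_correct": int(np.sum(sel == cfg.threshold)),
        "n_seeds": n_seeds,
        "true_threshold": cfg.threshold,
        "plateau_aic_margins": margins,
        "n_records_per_rep": cfg.n_offspring,
    }
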