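"""Synthetic broiler population with ascites resistance and tolerance.

Generates pedigrees and phenotype tables with the statistical structure the
random-regression tolerance analysis assumes, so that every pipeline stage
can be exercised and validated without the original (undeposited) data:

* a sire-dam hierarchy (default 83 sires, ~788 dams, ~7722 offspring,
  reared in 5 batches x 2 stables, hearts cut by 11 people);
* four correlated additive-genetic traits per animal — 2-week body weight
  (BW2, g), heart ratio (RATIO, % right ventricle of total heart weight),
  the 7-week body weight of a healthy bird (INTERCEPT, g) and the
  tolerance slope of 7-week weight on ascites severity (SLOPE, g/%) —
  with matching dam (maternal, environmental) effects;
* phenotypes built forward from the reaction-norm model: RATIO is a normal
  trait, severity is RATIOPlat = max(0, RATIO - threshold), and
  BW7 = intercept-part + slope-part * RATIOPlat + a class-heterogeneous
  residual; about 9% of birds die before week 7 and lose BW7/RATIO.

Default parameter values are the study conditions: variance components and
trait means from the mean-model and random-regression fits, genetic and
maternal correlation structure over the four traits, a plateau threshold
of 29% and population slope of -14.6 g/%. The five BW7 residual-class
variances are not printed anywhere, so they are calibrated such that the
class-wise phenotypic coefficients of variation reproduce the reported
sequence 11.5, 11.7, 13.8, 15.2, 19.1% given the default genetic and
maternal components (see :func:`calibrate_residual_classes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, make_pedigree
from .plateau import code_ratioplat, residual_class

TRAITS = ("bw2", "ratio", "intercept", "slope")

#: genetic correlations among (BW2, RATIO, INTERCEPT, SLOPE)
GENETIC_CORR = np.array(
    [
        [1.00, 0.09, 0.71, -0.27],
        [0.09, 1.00, 0.15, -0.36],
        [0.71, 0.15, 1.00, -0.30],
        [-0.27, -0.36, -0.30, 1.00],
    ]
)

#: maternal-effect correlations among the same four traits
MATERNAL_CORR = np.array(
    [
        [1.00, -0.31, 0.76, -0.005],
        [-0.31, 1.00, 0.003, -0.80],
        [0.76, 0.003, 1.00, -0.26],
        [-0.005, -0.80, -0.26, 1.00],
    ]
)

#: reported class-wise phenotypic CVs (%) used to calibrate residual classes
TARGET_CLASS_CV = np.array([11.5, 11.7, 13.8, 15.2, 19.1])


@dataclass
class SimConfig:
    """Parameters of the synthetic population (defaults = study conditions)."""

    n_sires: int = 83
    dams_per_sire: float = 15.7  # mean; actual counts drawn around this
    sires_per_dam: float = 1.65  # controls dam-sharing across sires
    n_offspring: int = 7722
    n_batches: int = 5
    n_stables: int = 2
    n_cutters: int = 11
    balanced: bool = False  # exact dams_per_sire and equal family sizes

    # trait means
    mean_bw2: float = 248.0
    mean_ratio: float = 28.2
    mean_intercept: float = 2080.0
    population_slope: float = -14.6

    # additive genetic variances of (bw2, ratio, intercept, slope)
    genetic_vars: tuple = (309.0, 15.1, 10640.0, 57.8)
    maternal_vars: tuple = (59.3, 1.17, 2771.0, 23.0)
    genetic_corr: np.ndarray = field(default_factory=lambda: GENETIC_CORR.copy())
    maternal_corr: np.ndarray = field(default_factory=lambda: MATERNAL_CORR.copy())

    # residual variances: bw2 and ratio from V_P - V_G - V_M; the 5 BW7
    # classes are calibrated from the class CVs when left to None
    residual_bw2: float = 946.0 - 309.0 - 59.3
    residual_ratio: float = 46.72 - 15.1 - 1.17
    residual_bw7_classes: tuple | None = None

    threshold: float = 29.0
    class_edges: tuple = (0.0, 5.0, 10.0, 15.0)
    mortality: float = 0.09
    bw2_missing: float = 7722.0 / 7722 - 7710.0 / 7722  # a handful of lost BW2 records
    ratio_extra_missing: float = (7039.0 - 6991.0) / 7039  # unusable hearts

    # fixed-effect magnitudes (not reported; modest relative to trait SDs)
    gender_effect_bw2: float = 8.0
    gender_effect_bw7: float = 60.0
    gender_effect_ratio: float = 0.6
    batch_stable_sd_bw2: float = 6.0
    batch_stable_sd_bw7: float = 25.0
    batch_stable_sd_ratio: float = 0.5
    age_effect_per_day_bw2: float = 12.0
    age_effect_per_day_bw7: float = 30.0
    cutter_sd_ratio: float = 0.5
    batch_stable_slope_sd: float = 1.0
    cutter_slope_sd: float = 1.0

    def genetic_cov(self) -> np.ndarray:
        s = np.sqrt(np.asarray(self.genetic_vars))
        return nearest_psd(self.genetic_corr) * np.outer(s, s)

    def maternal_cov(self) -> np.ndarray:
        s = np.sqrt(np.asarray(self.maternal_vars))
        return nearest_psd(self.maternal_corr) * np.outer(s, s)

    def bw7_class_variances(self) -> np.ndarray:
        if self.residual_bw7_classes is not None:
            return np.asarray(self.residual_bw7_classes, dtype=float)
        return calibrate_residual_classes(self)

    @classmethod
    def reduced(cls, n_sires=40, dams_per_sire=8, offspring_per_dam=10, n_cutters=4,
                **overrides) -> "SimConfig":
        """Balanced reduced-scale preset (hierarchical dams within sires)."""
        cfg = cls(
            n_sires=n_sires,
            dams_per_sire=float(dams_per_sire),
            sires_per_dam=1.0,
            n_offspring=int(n_sires * dams_per_sire * offspring_per_dam),
            n_cutters=n_cutters,
            balanced=True,
        )
        return replace(cfg, **overrides)


def nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a (possibly slightly indefinite, rounded) correlation matrix
    onto the PSD cone: clip negative eigenvalues, restore the unit diagonal."""
    C = 0.5 * (corr + corr.T)
    w, V = np.linalg.eigh(C)
    if w.min() >= eps:
        return C
    w = np.clip(w, eps, None)
    C = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def class_midpoints(cfg: SimConfig, n_classes: int = 5) -> np.ndarray:
    """Expected RATIOPlat within each residual class under the RATIO normal
    distribution (class 1 is exactly 0)."""
    sd = np.sqrt(
        float(np.asarray(cfg.genetic_vars)[1] + np.asarray(cfg.maternal_vars)[1]
              + cfg.residual_ratio)
    )
    dist = stats.norm(cfg.mean_ratio - cfg.threshold, sd)
    edges = list(cfg.class_edges[1:]) + [np.inf]
    lo = list(cfg.class_edges)
    mids = [0.0]
    for a, b in zip(lo, edges):
        # E[t | a < t <= b] for the plateau-coded severity
        num, _ = _truncated_mean(dist, a, b)
        mids.append(num)
    return np.asarray(mids[: n_classes])


def _truncated_mean(dist, a, b):
    pa, pb = dist.cdf(a), dist.cdf(b)
    mass = pb - pa
    if mass <= 0:
        return (a if np.isfinite(a) else 0.0), 0.0
    # numeric integration is robust for the one-sided tail
    xs = np.linspace(a, b if np.isfinite(b) else dist.ppf(1 - 1e-9), 2001)
    pdf = dist.pdf(xs)
    m = np.trapezoid(xs * pdf, xs) / max(np.trapezoid(pdf, xs), 1e-300)
    return m, mass


def calibrate_residual_classes(cfg: SimConfig) -> np.ndarray:
    """BW7 residual variances per severity class from the reported CV curve.

    V_E(class) = (CV * mean_BW7(class) / 100)^2 - V_G(t) - V_M(t) evaluated
    at the class-representative severity t, where V_G/V_M follow the
    reaction-norm covariance function.
    """
    G = cfg.genetic_cov()[2:, 2:]
    M = cfg.maternal_cov()[2:, 2:]
    mids = class_midpoints(cfg)
    out = []
    for cv, t in zip(TARGET_CLASS_CV, mids):
        x = np.array([1.0, t])
        vg = float(x @ G @ x)
        vm = float(x @ M @ x)
        mean_bw7 = cfg.mean_intercept + cfg.population_slope * t
        vp = (cv * mean_bw7 / 100.0) ** 2
        out.append(max(vp - vg - vm, 0.1 * vp))
    return np.asarray(out)


@dataclass
class SimTruth:
    """Generating values retained for parameter-recovery tests."""

    config: SimConfig
    breeding_values: pd.DataFrame  # per animal, columns TRAITS
    maternal_effects: pd.DataFrame  # per dam, columns TRAITS
    residual_bw7_classes: np.ndarray
    fixed_effects: dict


def simulate_pedigree(cfg: SimConfig, seed: int):
    """Founder sires and dams plus the offspring generation.

    Returns (pedigree, mating table with per-offspring sire/dam indices).
    Dams can be shared between sires (`sires_per_dam` > 1) as in the study.
    """
    if cfg.n_sires < 1 or cfg.n_offspring < 1:
        raise ValueError("need at least one sire and one offspring")
    rng = np.random.default_rng(seed)
    n_dams_total = max(int(round(cfg.n_sires * cfg.dams_per_sire / cfg.sires_per_dam)), 1)
    sire_ids = [f"S{i+1:03d}" for i in range(cfg.n_sires)]
    dam_ids = [f"D{i+1:04d}" for i in range(n_dams_total)]
    # each sire mates a number of dams around the configured mean
    if cfg.balanced:
        k = int(round(cfg.dams_per_sire))
        matings = [(s, s * k + j) for s in range(cfg.n_sires) for j in range(k)]
        if n_dams_total < cfg.n_sires * k:
            dam_ids = [f"D{i+1:04d}" for i in range(cfg.n_sires * k)]
    else:
        matings = []
        for s in range(cfg.n_sires):
            nd = max(2, int(round(rng.normal(cfg.dams_per_sire, cfg.dams_per_sire / 4))))
            dams = rng.choice(n_dams_total, size=min(nd, n_dams_total), replace=False)
            matings += [(s, int(d)) for d in dams]
    matings = np.asarray(matings)
    # offspring allocated (near-)evenly over matings
    alloc = np.full(len(matings), cfg.n_offspring // len(matings))
    extra = rng.choice(len(matings), size=cfg.n_offspring - alloc.sum(), replace=False)
    alloc[extra] += 1
    off_sire = np.repeat(matings[:, 0], alloc)
    off_dam = np.repeat(matings[:, 1], alloc)
    order = rng.permutation(len(off_sire))
    off_sire, off_dam = off_sire[order], off_dam[order]
    off_ids = [f"O{i+1:05d}" for i in range(len(off_sire))]
    trips = [(s, None, None) for s in sire_ids]
    trips += [(d, None, None) for d in dam_ids]
    trips += [
        (o, sire_ids[s], dam_ids[d]) for o, s, d in zip(off_ids, off_sire, off_dam)
    ]
    ped = make_pedigree(trips)
    mating = pd.DataFrame(
        {
            "animal_id": off_ids,
            "sire_id": [sire_ids[s] for s in off_sire],
            "dam_id": [dam_ids[d] for d in off_dam],
        }
    )
    return ped, mating


def simulate_genetic_values(ped: Pedigree, cfg: SimConfig, seed: int):
    """Additive 4-vectors per animal and maternal 4-vectors per dam.

    Founders are drawn from N(0, G4); each non-founder is the parent
    average plus a Mendelian-sampling deviation with covariance
    0.5 (1 - (F_s + F_d)/2) G4. Maternal effects are independent N(0, M4)
    draws per dam (an environmental, not a transmitted, effect).
    """
    rng = np.random.default_rng(seed)
    G4 = cfg.genetic_cov()
    M4 = cfg.maternal_cov()
    n = len(ped)
    cholG = np.linalg.cholesky(G4 + 1e-12 * np.eye(4)) if np.any(G4) else np.zeros((4, 4))
    bv = np.zeros((n, 4))
    F = ped.inbreeding
    z = rng.standard_normal((n, 4))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            bv[i] = cholG @ z[i]
            continue
        pa = 0.0
        fs = fd = 0.0
        cnt = 0
        if s >= 0:
            pa = pa + bv[s]
            fs = F[s]
            cnt += 1
        if d >= 0:
            pa = pa + bv[d]
            fd = F[d]
            cnt += 1
        if cnt == 2:
            mean = 0.5 * pa
            msv = 0.5 * (1 - 0.5 * (fs + fd))
        else:
            mean = 0.5 * pa
            msv = 0.75 - 0.25 * (fs + fd)
        bv[i] = mean + np.sqrt(msv) * (cholG @ z[i])
    bvdf = pd.DataFrame(bv, columns=list(TRAITS), index=ped.ids)
    # dams = any animal appearing as a dam
    dam_pos = np.unique(ped.dam[ped.dam >= 0])
    dam_ids = ped.ids[dam_pos]
    cholM = np.linalg.cholesky(M4 + 1e-12 * np.eye(4)) if np.any(M4) else np.zeros((4, 4))
    mat = (cholM @ rng.standard_normal((4, len(dam_ids)))).T
    matdf = pd.DataFrame(mat, columns=list(TRAITS), index=dam_ids)
    return bvdf, matdf


def _fixed_effect_levels(cfg: SimConfig, rng) -> dict:
    bs = cfg.n_batches * cfg.n_stables

    def centered(sd, k):
        # sum-to-zero level effects keep the population means identifiable
        # as the configured trait means / population slope
        e = rng.normal(0, sd, k)
        return e - e.mean()

    return {
        "gender": {
            "bw2": np.array([-0.5, 0.5]) * cfg.gender_effect_bw2,
            "bw7": np.array([-0.5, 0.5]) * cfg.gender_effect_bw7,
            "ratio": np.array([-0.5, 0.5]) * cfg.gender_effect_ratio,
        },
        "batch_stable": {
            "bw2": centered(cfg.batch_stable_sd_bw2, bs),
            "bw7": centered(cfg.batch_stable_sd_bw7, bs),
            "ratio": centered(cfg.batch_stable_sd_ratio, bs),
            "slope": centered(cfg.batch_stable_slope_sd, bs),
        },
        "cutter": {
            "ratio": centered(cfg.cutter_sd_ratio, cfg.n_cutters),
            "slope": centered(cfg.cutter_slope_sd, cfg.n_cutters),
        },
    }


def simulate_phenotypes(ped: Pedigree, mating: pd.DataFrame, bv: pd.DataFrame,
                        mat: pd.DataFrame, cfg: SimConfig, seed: int):
    """Phenotype table for the offspring generation plus the truth sidecar.

    BW2 and RATIO are ordinary normal traits; BW7 follows the plateau-linear
    reaction norm with per-animal intercept/slope deviations and a residual
    variance specific to the severity class. Mortality removes BW7 and
    RATIO of ~9% of birds.
    """
    rng = np.random.default_rng(seed)
    n = len(mating)
    fx = _fixed_effect_levels(cfg, rng)
    gender = rng.integers(0, 2, n)
    batch = rng.integers(0, cfg.n_batches, n)
    stable = rng.integers(0, cfg.n_stables, n)
    bs = batch * cfg.n_stables + stable
    cutter = rng.integers(0, cfg.n_cutters, n)
    age_bw2 = rng.integers(12, 14, n)
    age_bw7 = rng.integers(45, 47, n)
    age_ratio = np.clip(age_bw7 + rng.integers(0, 3, n) - 1, 45, 48)

    a = bv.loc[mating.animal_id].to_numpy()
    m = mat.loc[mating.dam_id].to_numpy()

    e_bw2 = rng.normal(0, np.sqrt(cfg.residual_bw2), n)
    e_ratio = rng.normal(0, np.sqrt(cfg.residual_ratio), n)
    bw2 = (
        cfg.mean_bw2
        + fx["gender"]["bw2"][gender]
        + fx["batch_stable"]["bw2"][bs]
        + cfg.age_effect_per_day_bw2 * (age_bw2 - age_bw2.mean())
        + a[:, 0]
        + m[:, 0]
        + e_bw2
    )
    ratio = (
        cfg.mean_ratio
        + fx["gender"]["ratio"][gender]
        + fx["batch_stable"]["ratio"][bs]
        + fx["cutter"]["ratio"][cutter]
        + a[:, 1]
        + m[:, 1]
        + e_ratio
    )
    ratio = np.clip(ratio, 0.5, 99.5)
    t = code_ratioplat(ratio, cfg.threshold)
    cls = residual_class(t, cfg.class_edges)  # 1..5
    vclass = cfg.bw7_class_variances()
    e_bw7 = rng.normal(0, 1.0, n) * np.sqrt(vclass[cls - 1])
    intercept_part = (
        cfg.mean_intercept
        + fx["gender"]["bw7"][gender]
        + fx["batch_stable"]["bw7"][bs]
        + cfg.age_effect_per_day_bw7 * (age_bw7 - age_bw7.mean())
        + a[:, 2]
        + m[:, 2]
    )
    slope_part = (
        cfg.population_slope
        + fx["batch_stable"]["slope"][bs]
        + fx["cutter"]["slope"][cutter]
        + a[:, 3]
        + m[:, 3]
    )
    bw7 = intercept_part + slope_part * t + e_bw7

    dead = rng.random(n) < cfg.mortality
    miss_bw2 = rng.random(n) < cfg.bw2_missing
    miss_ratio = ~dead & (rng.random(n) < cfg.ratio_extra_missing)

    tab = pd.DataFrame(
        {
            "animal_id": mating.animal_id,
            "sire_id": mating.sire_id,
            "dam_id": mating.dam_id,
            "gender": np.where(gender == 0, "female", "male"),
            "batch": batch + 1,
            "stable": stable + 1,
            "person": [f"P{c+1:02d}" for c in cutter],
            "age_bw2": age_bw2,
            "age_bw7": age_bw7,
            "age_ratio": age_ratio,
            "bw2": np.where(miss_bw2, np.nan, np.round(bw2, 1)),
            "bw7": np.where(dead, np.nan, np.round(bw7, 1)),
            "ratio": np.where(dead | miss_ratio, np.nan, np.round(ratio, 2)),
        }
    )
    truth = SimTruth(
        config=cfg,
        breeding_values=bv,
        maternal_effects=mat,
        residual_bw7_classes=vclass,
        fixed_effects=fx,
    )
    return tab, truth


def simulate_population(cfg: SimConfig | None = None, seed: int = 1):
    """One-call generator: returns (pedigree, phenotype table, truth)."""
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_ped, s_gen, s_phe = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3)]
    ped, mating = simulate_pedigree(cfg, s_ped)
    bv, mat = simulate_genetic_values(ped, cfg, s_gen)
    tab, truth = simulate_phenotypes(ped, mating, bv, mat, cfg, s_phe)
    return ped, tab, truth
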