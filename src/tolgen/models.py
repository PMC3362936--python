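"""The analysis models: trait means, tolerance reaction norm, correlations.

Three animal models drive the whole analysis:

* model 1 — trait mean for body weights:
  y = mu + animal + dam + GENDER + BATCHxSTABLE + AGE + e
* model 2 — trait mean for heart ratio: model 1 + PERSON (heart cutter)
* model 3 — random-regression tolerance model for 7-week weight:
  per-animal and per-dam random intercept and slope on RATIOPlat
  (unstructured 2x2 blocks; animal block carries the pedigree), fixed
  population slope plus slope-by-batch-stable and slope-by-cutter
  interactions, and residual variance per severity class.

Bivariate and extended (trait x intercept/slope) fits provide the genetic,
maternal and phenotypic correlation tables; covariance functions turn the
model-3 blocks into trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covfun, plateau
from .reml import (
    DesignError,
    ModelSpec,
    RandomTermSpec,
    REMLModel,
    VarianceReport,
    build_design,
    delta_se,
    reml_fit,
    stack_bivariate,
)

AGE_COLUMN = {"bw2": "age_bw2", "bw7": "age_bw7", "ratio": "age_ratio"}


def model1_spec(trait: str) -> ModelSpec:
    """Trait-mean animal model for a body weight (BW2 or BW7)."""
    if trait not in ("bw2", "bw7"):
        raise DesignError(f"model 1 is for body weights, not {trait!r}")
    return ModelSpec(
        response=trait,
        fixed_factors=[("gender",), ("batch", "stable"), (AGE_COLUMN[trait],)],
        random=[
            RandomTermSpec("animal", "animal_id", "pedigree", ("1",), ("mean",)),
            RandomTermSpec("dam", "dam_id", "iid", ("1",), ("mean",)),
        ],
        name=f"model1[{trait}]",
    )


def model2_spec() -> ModelSpec:
    """Trait-mean animal model for heart ratio (adds the cutter effect)."""
    spec = model1_spec("bw2")
    return ModelSpec(
        response="ratio",
        fixed_factors=[("gender",), ("batch", "stable"), ("age_ratio",), ("person",)],
        random=spec.random,
        name="model2[ratio]",
    )


def model3_spec(include_bw2_covariate: bool = False) -> ModelSpec:
    """Random-regression tolerance model for BW7 on RATIOPlat.

    Expects the table to carry `ratioplat` and `rclass` columns (added by
    :func:`prepare_tolerance_table`).
    """
    fixed_cov = ["bw2"] if include_bw2_covariate else []
    return ModelSpec(
        response="bw7",
        fixed_factors=[("gender",), ("batch", "stable"), ("age_bw7",), ("person",)],
        fixed_covariates=fixed_cov,
        slope_col="ratioplat",
        slope_by=[("batch", "stable"), ("person",)],
        random=[
            RandomTermSpec(
                "animal", "animal_id", "pedigree", ("1", "ratioplat"),
                ("intercept", "slope"),
            ),
            RandomTermSpec(
                "dam", "dam_id", "iid", ("1", "ratioplat"), ("intercept", "slope")
            ),
        ],
        residual_classes="rclass",
        name="model3" + ("+bw2" if include_bw2_covariate else ""),
    )


def prepare_tolerance_table(
    table: pd.DataFrame,
    threshold: float | None = plateau.DEFAULT_THRESHOLD,
    class_edges=plateau.DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Add severity (`ratioplat`) and residual class (`rclass`, 0-based)
    columns. `threshold=None` gives the fully linear comparison model
    (severity = RATIO - 29 without plateau capping; classes still follow
    the plateau coding so both models estimate the same parameter count).
    """
    tab = table.copy()
    base = plateau.DEFAULT_THRESHOLD if threshold is None else threshold
    plat = plateau.code_ratioplat(tab["ratio"].to_numpy(dtype=float), base)
    with np.errstate(invalid="ignore"):
        tab["ratioplat"] = (
            plat if threshold is not None
            else tab["ratio"].to_numpy(dtype=float) - base
        )
        cls = np.where(np.isnan(plat), 0, plateau.residual_class(np.nan_to_num(plat), class_edges))
    tab["rclass"] = cls - np.where(cls > 0, 1, 0)  # 0-based classes
    return tab


def tolerance_start_values(model: REMLModel, table: pd.DataFrame) -> np.ndarray:
    """Heuristic starting components for the tolerance model: most of the
    healthy-class variance split 30/10/60 into animal/dam/residual, slope
    variances scaled by the mean squared severity of affected birds."""
    asm = model.asm
    vy = float(np.var(asm.y))
    theta = model.default_start()
    for k, info in enumerate(model.infos):
        if info.kind == "g":
            term = asm.terms[info.term]
            share = 0.30 if term.kinv is not None else 0.08
            if info.a == info.b:
                # mean squared covariate of this effect column
                sc = float(np.asarray(term.Z.power(2).sum(axis=0)).ravel()
                           [info.a :: term.q].sum()) / asm.n
                theta[k] = share * vy / max(sc, 1e-8)
            else:
                theta[k] = 0.0
        elif info.kind == "rvar":
            theta[k] = 0.55 * vy
        else:
            theta[k] = 0.0
    return theta


def fit_mean_model(table: pd.DataFrame, ped, trait: str, **options) -> VarianceReport:
    """Fit model 1 (body weights) or model 2 (heart ratio) by REML."""
    spec = model2_spec() if trait == "ratio" else model1_spec(trait)
    asm = build_design(spec, table, ped)
    return reml_fit(asm, **options)


def fit_tolerance_model(
    table: pd.DataFrame,
    ped,
    threshold: float | None = plateau.DEFAULT_THRESHOLD,
    include_bw2_covariate: bool = False,
    class_edges=plateau.DEFAULT_CLASS_EDGES,
    **options,
) -> VarianceReport:
    """Fit the model-3 reaction norm; `threshold=None` fits the linear
    comparison model."""
    tab = prepare_tolerance_table(table, threshold, class_edges)
    spec = model3_spec(include_bw2_covariate)
    asm = build_design(spec, tab, ped)
    model = REMLModel(asm)
    start = options.pop("start", None)
    if start is None:
        start = tolerance_start_values(model, tab)
    return model.fit(start=start, **options)


def bivariate_fit(table: pd.DataFrame, ped, trait1: str, trait2: str,
                  **options) -> VarianceReport:
    """Joint two-trait animal model giving genetic, maternal and residual
    covariances (residual covariance inside same-animal record pairs)."""
    specs = {}
    for tr in (trait1, trait2):
        specs[tr] = model2_spec() if tr == "ratio" else model1_spec(tr)
    asm1 = build_design(specs[trait1], table, ped)
    asm2 = build_design(specs[trait2], table, ped)
    asm = stack_bivariate(asm1, asm2, residual_cov=True)
    return reml_fit(asm, **options)


def extended_fit(
    table: pd.DataFrame,
    ped,
    trait: str,
    threshold: float = plateau.DEFAULT_THRESHOLD,
    **options,
) -> VarianceReport:
    """Joint fit of a trait-mean model (BW2 or RATIO) with the tolerance
    reaction norm: 3x3 genetic and maternal blocks over (trait, intercept,
    slope)."""
    tab = prepare_tolerance_table(table, threshold)
    spec1 = model2_spec() if trait == "ratio" else model1_spec(trait)
    asm1 = build_design(spec1, tab, ped)
    asm3 = build_design(model3_spec(), tab, ped)
    asm = stack_bivariate(asm1, asm3, residual_cov=True)
    return reml_fit(asm, **options)


# ---------------------------------------------------------------------------
# correlations and summaries from fitted reports
# ---------------------------------------------------------------------------


def correlation_from_bivariate(rep: VarianceReport, term: str, c1: str, c2: str):
    """(estimate, SE) of the correlation of two effect columns of a term."""
    v1n, v2n = f"{term}:var({c1})", f"{term}:var({c2})"
    cn = (
        f"{term}:cov({c1},{c2})"
        if f"{term}:cov({c1},{c2})" in rep.names
        else f"{term}:cov({c2},{c1})"
    )

    def f(p):
        return p[cn] / np.sqrt(p[v1n] * p[v2n])

    est = f(dict(zip(rep.names, rep.estimates)))
    return est, delta_se(rep, f)


def phenotypic_correlation(rep: VarianceReport, t1: str, t2: str):
    """Phenotypic correlation from summed (co)variance components of a
    bivariate trait-mean fit."""
    names = rep.names

    def f(p):
        def vp(tr):
            tot = 0.0
            for nm in names:
                if nm.endswith(f"var({tr}.mean)") or (
                    nm.startswith("residual:var(") and f"({tr}." in nm
                ):
                    tot += p[nm]
            return tot

        cov = 0.0
        for nm in names:
            if ":cov(" in nm and t1 in nm and t2 in nm:
                cov += p[nm]
        return cov / np.sqrt(vp(t1) * vp(t2))

    est = f(dict(zip(rep.names, rep.estimates)))
    return est, delta_se(rep, f)


def population_mean_slope(rep: VarianceReport, table: pd.DataFrame) -> float:
    """Record-frequency-weighted population tolerance slope.

    The fixed `ratioplat` coefficient is the slope of the reference
    batch-stable cell and cutter; averaging the slope-by-group interaction
    coefficients over the records (reference levels contribute zero) gives
    the population mean slope that the trait table realises.
    """
    fixed = rep.solutions["fixed"]
    base = float(fixed["ratioplat"])
    tab = table.loc[table.index.isin(rep.meta.get("record_labels", table.index))] \
        if "record_labels" in rep.meta else table
    n = len(tab)
    adj = 0.0
    groups: dict = {}
    for name, val in fixed.items():
        if not name.startswith("ratioplat."):
            continue
        body = name[len("ratioplat."):]
        fac, lev = body.split("[", 1)
        lev = lev.rstrip("]")
        groups.setdefault(fac, []).append((lev, float(val)))
    for fac, levels in groups.items():
        cols = fac.split("x")
        lab = tab[cols[0]].astype(str)
        for c in cols[1:]:
            lab = lab + ":" + tab[c].astype(str)
        freq = lab.value_counts(normalize=True)
        adj += sum(freq.get(lev, 0.0) * val for lev, val in levels)
    return base + adj


def genetic_blocks(rep: VarianceReport):
    """(genetic GenCov2, maternal GenCov2) from a model-3 report."""
    g = rep.covariance_block("animal", ["intercept", "slope"])
    m = rep.covariance_block("dam", ["intercept", "slope"])
    return (
        covfun.GenCov2(g[0, 0], g[1, 1], g[0, 1]),
        covfun.GenCov2(m[0, 0], m[1, 1], m[0, 1]),
    )


def residual_class_variances(rep: VarianceReport) -> np.ndarray:
    out = []
    for c in range(5):
        nm = f"residual:var(class{c+1})"
        if nm in rep.names:
            out.append(rep[nm])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisBundle:
    """Everything the full analysis produces on one data set."""

    mean_models: dict = field(default_factory=dict)  # trait -> VarianceReport
    tolerance: VarianceReport | None = None
    tolerance_bw2cov: VarianceReport | None = None
    correlations: pd.DataFrame | None = None  # bivariate trait-mean cells
    extended: dict = field(default_factory=dict)  # trait -> VarianceReport
    trajectories: pd.DataFrame | None = None
    ebv: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return (
            all(r.converged for r in self.mean_models.values())
            and self.tolerance is not None
            and self.tolerance.converged
        )


def run_full_analysis(
    table: pd.DataFrame,
    ped,
    threshold: float = plateau.DEFAULT_THRESHOLD,
    with_bw2_covariate: bool = True,
    with_correlations: bool = True,
    with_extended: bool = False,
    mean_intercept_for_cv: float | None = None,
    **options,
) -> AnalysisBundle:
    """Run the analysis sequence: mean models for the three traits, the
    tolerance reaction norm (with and without the BW2 covariate),
    bivariate correlations, covariance-function trajectories and EBV
    summaries. Stages that fail to converge are noted and skipped
    downstream."""
    from .report import ebv_summary

    if len(table) == 0:
        raise DesignError("empty phenotype table")
    bundle = AnalysisBundle()
    for trait in ("bw2", "bw7", "ratio"):
        try:
            bundle.mean_models[trait] = fit_mean_model(table, ped, trait, **options)
        except DesignError as e:
            bundle.notes.append(f"mean model {trait}: {e}")
    try:
        bundle.tolerance = fit_tolerance_model(table, ped, threshold, **options)
    except DesignError as e:
        bundle.notes.append(f"tolerance model: {e}")
    if with_bw2_covariate:
        try:
            bundle.tolerance_bw2cov = fit_tolerance_model(
                table, ped, threshold, include_bw2_covariate=True, **options
            )
        except DesignError as e:
            bundle.notes.append(f"tolerance model with BW2 covariate: {e}")
    if with_correlations:
        cells = []
        for t1, t2 in (("bw2", "bw7"), ("bw2", "ratio"), ("bw7", "ratio")):
            try:
                rep = bivariate_fit(table, ped, t1, t2, **options)
                for term in ("animal", "dam"):
                    est, se = correlation_from_bivariate(
                        rep, term, f"{t1}.mean", f"{t2}.mean"
                    )
                    cells.append(
                        {"pair": f"{t1}-{t2}", "kind": term, "estimate": est, "se": se}
                    )
                est, se = phenotypic_correlation(rep, t1, t2)
                cells.append(
                    {"pair": f"{t1}-{t2}", "kind": "phenotypic", "estimate": est,
                     "se": se}
                )
            except DesignError as e:
                bundle.notes.append(f"bivariate {t1}-{t2}: {e}")
        bundle.correlations = pd.DataFrame(cells)
    if with_extended:
        for trait in ("bw2", "ratio"):
            try:
                bundle.extended[trait] = extended_fit(
                    table, ped, trait, threshold, **options
                )
            except DesignError as e:
                bundle.notes.append(f"extended fit {trait}: {e}")
    if bundle.tolerance is not None and bundle.tolerance.converged:
        g, m = genetic_blocks(bundle.tolerance)
        ve = residual_class_variances(bundle.tolerance)
        slope_name = "ratioplat"
        pop_slope = bundle.tolerance.solutions["fixed"].get(slope_name, np.nan)
        bundle.trajectories = covfun.trajectory_ratios(
            g,
            m,
            ve,
            threshold=threshold,
            mean_intercept=mean_intercept_for_cv,
            population_slope=pop_slope if mean_intercept_for_cv else None,
        )
        bundle.ebv = {
            grp: ebv_summary(bundle.tolerance.solutions, table, grp)
            for grp in ("offspring", "sires", "dams")
        }
    return bundle
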