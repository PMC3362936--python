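"""Average-information REML for pedigree animal models.

The estimation machinery behind every fit in this package: a linear mixed
model

    y = X b + sum_t Z_t u_t + e,
    u_t ~ N(0, Sigma_t (x) K_t),      e ~ N(0, R),

where each random term t carries q_t correlated effect columns per level
(e.g. an intercept and a tolerance slope per animal), K_t is either the
pedigree numerator-relationship matrix A (animal terms) or the identity
(dam terms), and R is diagonal with class-specific variances — optionally
with a cross-trait residual covariance inside same-animal record pairs in
multivariate fits.

Estimation maximises the restricted likelihood with Newton steps that use
the average-information (AI) matrix, exact first derivatives obtained from
a Takahashi selected inverse of the sparse mixed-model equations, and
expectation-maximisation fallback steps whenever an AI proposal leaves the
parameter space or fails to improve the likelihood. Standard errors come
from the inverse AI matrix at the optimum; standard errors of derived
ratios (h^2, m^2, correlations) use the delta method.

The restricted log-likelihood is evaluated through the mixed-model
equations C s = W' R^-1 y with C = W' R^-1 W + diag(0, G^-1):

    -2 logL = (n - p) log 2pi + log|R| + log|G| + log|C| + y' P y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .sparse_ldl import LDLSolver, subset_positions

__all__ = [
    "RandomTerm",
    "ResidualSpec",
    "Assembled",
    "ModelSpec",
    "VarianceReport",
    "build_design",
    "reml_fit",
    "information_criteria",
    "delta_se",
    "DesignError",
]


class DesignError(ValueError):
    """Invalid model/data combination (rank deficiency, empty factor, ...)."""


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


@dataclass
class RandomTermSpec:
    """Declarative random term: `level_col` groups records, `structure` is
    'pedigree' (covariance sigma^2 A) or 'iid', and `covariate_cols` name the
    per-record regressors of the effect columns ("1" = intercept)."""

    name: str
    level_col: str
    structure: str  # "pedigree" | "iid"
    covariate_cols: tuple = ("1",)
    col_names: tuple | None = None


@dataclass
class ModelSpec:
    """Declarative single-trait model description.

    fixed_factors: list of factor-name tuples; a tuple of length > 1 is the
        interaction of its factors (e.g. ("batch", "stable")).
    fixed_covariates: list of column names entering linearly.
    slope_by: factor tuples whose (reference-coded) dummies multiply
        `slope_col` — the fixed slope-by-group interactions of a reaction
        norm model.
    residual_classes: column with an integer class per record, or None for
        a homogeneous residual.
    """

    response: str
    fixed_factors: list = field(default_factory=list)
    fixed_covariates: list = field(default_factory=list)
    slope_col: str | None = None
    slope_by: list = field(default_factory=list)
    random: list = field(default_factory=list)
    residual_classes: str | None = None
    name: str = ""


# ---------------------------------------------------------------------------
# assembled design
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    name: str
    Z: sparse.csr_matrix  # n x (m*q), level-major columns
    m: int
    q: int
    col_names: list
    level_ids: np.ndarray
    kinv: sparse.csc_matrix | None  # None = identity
    logdet_k: float


@dataclass
class ResidualSpec:
    classes: np.ndarray  # per-record class index (0-based)
    n_classes: int
    class_names: list
    pair_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pair_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pair_group: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_groups: int = 0
    group_names: list = field(default_factory=list)


@dataclass
class Assembled:
    y: np.ndarray
    X: sparse.csr_matrix
    x_names: list
    terms: list
    residual: ResidualSpec
    record_index: np.ndarray  # row labels of the source table that were kept
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _dummy_columns(table: pd.DataFrame, factors: tuple, prefix: str):
    """Reference-coded dummies for a factor or interaction (first level of
    the combined labels is the reference)."""
    lab = table[factors[0]].astype(str)
    for f in factors[1:]:
        lab = lab + ":" + table[f].astype(str)
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise DesignError(
            f"factor {prefix} has a single level ({levels[0]!r}) after row exclusion"
        )
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((lab == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def _fixed_design(spec: ModelSpec, table: pd.DataFrame):
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for factors in spec.fixed_factors:
        factors = tuple(factors) if not isinstance(factors, str) else (factors,)
        c, nm = _dummy_columns(table, factors, "x".join(factors))
        cols += c
        names += nm
    for cov in spec.fixed_covariates:
        cols.append(table[cov].to_numpy(dtype=float))
        names.append(cov)
    if spec.slope_col is not None:
        t = table[spec.slope_col].to_numpy(dtype=float)
        cols.append(t)
        names.append(spec.slope_col)
        for factors in spec.slope_by:
            factors = tuple(factors) if not isinstance(factors, str) else (factors,)
            c, nm = _dummy_columns(table, factors, "x".join(factors))
            cols += [t * ci for ci in c]
            names += [f"{spec.slope_col}.{n}" for n in nm]
    X = np.column_stack(cols)
    # full-rank check with identification of the offending columns
    zero = np.flatnonzero(np.abs(X).sum(axis=0) == 0)
    if len(zero):
        raise DesignError(
            "all-zero fixed-effect columns (no data in level): "
            + ", ".join(names[z] for z in zero)
        )
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        R = np.linalg.qr(X, mode="r")
        small = np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max())
        bad = ", ".join(names[int(s)] for s in small) or "unknown"
        raise DesignError(f"rank-deficient fixed design; confounded columns: {bad}")
    return sparse.csr_matrix(X), names


def _random_term(tspec: RandomTermSpec, table: pd.DataFrame, ped) -> RandomTerm:
    from . import pedigree as pedmod

    q = len(tspec.covariate_cols)
    covs = np.column_stack(
        [
            np.ones(len(table)) if c == "1" else table[c].to_numpy(dtype=float)
            for c in tspec.covariate_cols
        ]
    )
    if tspec.structure == "pedigree":
        if ped is None:
            raise DesignError(f"term {tspec.name!r} needs a pedigree")
        level_ids = ped.ids
        level_idx = np.array([ped.index_of(a) for a in table[tspec.level_col]])
        kinv = pedmod.build_a_inverse(ped)
        logdet_k = pedmod.log_det_a(ped)
        m = len(ped)
    elif tspec.structure == "iid":
        labels = table[tspec.level_col].astype(str).to_numpy()
        level_ids, level_idx = np.unique(labels, return_inverse=True)
        kinv = None
        logdet_k = 0.0
        m = len(level_ids)
    else:
        raise DesignError(f"unknown random structure {tspec.structure!r}")
    n = len(table)
    rows = np.repeat(np.arange(n), q)
    cols = (level_idx[:, None] * q + np.arange(q)[None, :]).ravel()
    Z = sparse.csr_matrix((covs.ravel(), (rows, cols)), shape=(n, m * q))
    col_names = list(tspec.col_names) if tspec.col_names else list(tspec.covariate_cols)
    return RandomTerm(
        name=tspec.name,
        Z=Z,
        m=m,
        q=q,
        col_names=col_names,
        level_ids=np.asarray(level_ids),
        kinv=kinv,
        logdet_k=logdet_k,
    )


def build_design(spec: ModelSpec, table: pd.DataFrame, ped=None) -> Assembled:
    """Assemble response, fixed and random designs for one trait.

    Rows with a missing response, missing covariate, or missing slope value
    are dropped (each trait is fitted on its available records).
    """
    needed = [spec.response] + list(spec.fixed_covariates)
    if spec.slope_col:
        needed.append(spec.slope_col)
    tab = table.dropna(subset=[c for c in needed if c in table.columns])
    if len(tab) == 0:
        raise DesignError(f"no records with non-missing {spec.response!r}")
    y = tab[spec.response].to_numpy(dtype=float)
    X, x_names = _fixed_design(spec, tab)
    terms = [_random_term(t, tab, ped) for t in spec.random]
    if spec.residual_classes is None:
        resid = ResidualSpec(
            classes=np.zeros(len(tab), dtype=np.int64),
            n_classes=1,
            class_names=["residual"],
        )
    else:
        cls = tab[spec.residual_classes].to_numpy(dtype=np.int64)
        ncl = int(cls.max()) + 1
        counts = np.bincount(cls, minlength=ncl)
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0)
            raise DesignError(f"empty residual class(es): {list(empty)}")
        resid = ResidualSpec(
            classes=cls, n_classes=ncl, class_names=[f"class{c+1}" for c in range(ncl)]
        )
    return Assembled(
        y=y,
        X=X,
        x_names=x_names,
        terms=terms,
        residual=resid,
        record_index=tab.index.to_numpy(),
        meta={"response": spec.response, "model": spec.name},
    )


def stack_bivariate(a: Assembled, b: Assembled, residual_cov: bool = True) -> Assembled:
    """Stack two single-trait designs into one multivariate design.

    Random terms with the same name are merged into a single term whose
    effect columns are the union (each trait's records load only on its own
    columns); the residual gets per-trait classes and, when `residual_cov`,
    one covariance parameter for same-animal cross-trait record pairs.
    Records are matched across traits by their source-table row label.
    """
    n_a, n_b = a.n, b.n
    y = np.concatenate([a.y, b.y])
    X = sparse.block_diag([a.X, b.X], format="csr")
    x_names = [f"{a.meta.get('response','t1')}.{n}" for n in a.x_names] + [
        f"{b.meta.get('response','t2')}.{n}" for n in b.x_names
    ]
    terms = []
    names_b = {t.name: t for t in b.terms}
    for ta in a.terms:
        tb = names_b.get(ta.name)
        if tb is None:
            continue
        if ta.m != tb.m or not np.array_equal(ta.level_ids, tb.level_ids):
            raise DesignError(
                f"term {ta.name!r} has different levels in the two traits; "
                "fit them on a shared pedigree/dam coding"
            )
        q = ta.q + tb.q
        m = ta.m
        # interleave columns level-major: level i -> [ta cols, tb cols]
        Za = _expand_cols(ta.Z, ta.q, q, 0)
        Zb = _expand_cols(tb.Z, tb.q, q, ta.q)
        Z = sparse.vstack([Za, Zb]).tocsr()
        pref_a = a.meta.get("response", "t1")
        pref_b = b.meta.get("response", "t2")
        col_names = [f"{pref_a}.{c}" for c in ta.col_names] + [
            f"{pref_b}.{c}" for c in tb.col_names
        ]
        terms.append(
            RandomTerm(
                name=ta.name,
                Z=Z,
                m=m,
                q=q,
                col_names=col_names,
                level_ids=ta.level_ids,
                kinv=ta.kinv,
                logdet_k=ta.logdet_k,
            )
        )
    classes = np.concatenate([a.residual.classes, a.residual.n_classes + b.residual.classes])
    class_names = [
        f"{a.meta.get('response','t1')}.{c}" for c in a.residual.class_names
    ] + [f"{b.meta.get('response','t2')}.{c}" for c in b.residual.class_names]
    resid = ResidualSpec(
        classes=classes,
        n_classes=a.residual.n_classes + b.residual.n_classes,
        class_names=class_names,
    )
    if residual_cov:
        pos_b = {lab: i for i, lab in enumerate(b.record_index)}
        pi, pj = [], []
        for i, lab in enumerate(a.record_index):
            j = pos_b.get(lab)
            if j is not None:
                pi.append(i)
                pj.append(n_a + j)
        resid.pair_i = np.asarray(pi, dtype=np.int64)
        resid.pair_j = np.asarray(pj, dtype=np.int64)
        resid.pair_group = np.zeros(len(pi), dtype=np.int64)
        resid.n_groups = 1
        resid.group_names = [
            f"cov({a.meta.get('response','t1')},{b.meta.get('response','t2')})"
        ]
    record_index = np.concatenate([a.record_index, b.record_index])
    return Assembled(
        y=y,
        X=X,
        x_names=x_names,
        terms=terms,
        residual=resid,
        record_index=record_index,
        meta={
            "response": f"{a.meta.get('response')}+{b.meta.get('response')}",
            "n_trait1": n_a,
            "n_trait2": n_b,
        },
    )


def _expand_cols(Z: sparse.csr_matrix, q_old: int, q_new: int, offset: int):
    """Re-index level-major columns from stride q_old to stride q_new."""
    Zc = Z.tocoo()
    lev = Zc.col // q_old
    within = Zc.col % q_old
    cols = lev * q_new + offset + within
    m = Z.shape[1] // q_old
    return sparse.coo_matrix((Zc.data, (Zc.row, cols)), shape=(Z.shape[0], m * q_new))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ParamInfo:
    name: str
    kind: str  # "g" (term covariance), "rvar", "rcov"
    term: int = -1
    a: int = -1
    b: int = -1
    cls: int = -1
    group: int = -1
    is_variance: bool = True


def _param_layout(asm: Assembled):
    infos = []
    for it, t in enumerate(asm.terms):
        for a in range(t.q):
            for b_ in range(a + 1):
                if a == b_:
                    nm = f"{t.name}:var({t.col_names[a]})"
                else:
                    nm = f"{t.name}:cov({t.col_names[a]},{t.col_names[b_]})"
                infos.append(
                    ParamInfo(nm, "g", term=it, a=a, b=b_, is_variance=(a == b_))
                )
    for c in range(asm.residual.n_classes):
        infos.append(
            ParamInfo(
                f"residual:var({asm.residual.class_names[c]})", "rvar", cls=c
            )
        )
    for g in range(asm.residual.n_groups):
        infos.append(
            ParamInfo(
                f"residual:{asm.residual.group_names[g]}", "rcov", group=g,
                is_variance=False,
            )
        )
    return infos


def _unpack(theta: np.ndarray, asm: Assembled):
    sigmas = []
    k = 0
    for t in asm.terms:
        S = np.empty((t.q, t.q))
        for a in range(t.q):
            for b_ in range(a + 1):
                S[a, b_] = S[b_, a] = theta[k]
                k += 1
        sigmas.append(S)
    rvar = theta[k : k + asm.residual.n_classes]
    k += asm.residual.n_classes
    rcov = theta[k : k + asm.residual.n_groups]
    return sigmas, rvar, rcov


#: |correlation| above this is reported with a boundary flag (a degenerate,
#: perfectly-correlated block is a boundary estimate, not an interior one)
CORR_BOUND = 0.985


def _feasible(theta: np.ndarray, asm: Assembled, floor_scale: np.ndarray) -> bool:
    sigmas, rvar, rcov = _unpack(theta, asm)
    k = 0
    for it, (t, S) in enumerate(zip(asm.terms, sigmas)):
        if np.any(np.diag(S) <= 0):
            return False
        w = np.linalg.eigvalsh(S)
        if w[0] <= 1e-12 * max(w[-1], 1e-300):
            return False
        k += t.q * (t.q + 1) // 2
    if np.any(rvar <= 0):
        return False
    # residual pair blocks must stay positive definite
    res = asm.residual
    for g in range(res.n_groups):
        mask = res.pair_group == g
        if not np.any(mask):
            continue
        ci = res.classes[res.pair_i[mask]]
        cj = res.classes[res.pair_j[mask]]
        if np.any(rvar[ci] * rvar[cj] - rcov[g] ** 2 <= 0):
            return False
    return True


# ---------------------------------------------------------------------------
# residual bookkeeping: everything is a weighted sum of precomputed Grams
# ---------------------------------------------------------------------------


class _ResidualAlgebra:
    """Precomputed record groupings so that R^-1, W' R^-1 W and all the
    derivative matrices W' R^-1 dR R^-1 W are weighted sums of fixed sparse
    Gram matrices (no per-iteration sparse products)."""

    def __init__(self, asm: Assembled, W: sparse.csr_matrix):
        res = asm.residual
        n = asm.n
        paired = np.zeros(n, dtype=bool)
        paired[res.pair_i] = True
        paired[res.pair_j] = True
        self.res = res
        self.n = n
        # unpaired atoms per class
        self.unpaired_rows = [
            np.flatnonzero((res.classes == c) & ~paired) for c in range(res.n_classes)
        ]
        # pair combos: unique (class_i, class_j, group)
        combos = {}
        for idx in range(len(res.pair_i)):
            key = (
                int(res.classes[res.pair_i[idx]]),
                int(res.classes[res.pair_j[idx]]),
                int(res.pair_group[idx]),
            )
            combos.setdefault(key, []).append(idx)
        self.combos = [
            (key, np.asarray(v, dtype=np.int64)) for key, v in sorted(combos.items())
        ]
        # Gram atoms; a parallel set on |W| provides cancellation-proof
        # sparsity patterns (scipy prunes exact zeros created by sums)
        Wc = W.tocsr()
        Wa = abs(Wc)
        self.gram_unpaired = [
            (Wc[r].T @ Wc[r]).tocsc() if len(r) else None for r in self.unpaired_rows
        ]
        self._pat_unpaired = [
            (Wa[r].T @ Wa[r]).tocsc() if len(r) else None for r in self.unpaired_rows
        ]
        self.gram_pairs = []
        self._pat_pairs = []
        for (ci, cj, g), idx in self.combos:
            I = res.pair_i[idx]
            J = res.pair_j[idx]
            GA = (Wc[I].T @ Wc[I]).tocsc()
            GB = (Wc[J].T @ Wc[J]).tocsc()
            GX = (Wc[I].T @ Wc[J]).tocsc()
            GX = (GX + GX.T).tocsc()
            self.gram_pairs.append((GA, GB, GX))
            PA = (Wa[I].T @ Wa[I]).tocsc()
            PB = (Wa[J].T @ Wa[J]).tocsc()
            PX = (Wa[I].T @ Wa[J]).tocsc()
            PX = (PX + PX.T).tocsc()
            self._pat_pairs.append((PA, PB, PX))
        # per-record y-side helpers are computed on the fly (cheap vectors)

    def pattern(self) -> sparse.csc_matrix:
        """Strictly positive union pattern of every Gram atom."""
        M = None
        for G in self._pat_unpaired:
            if G is None:
                continue
            M = G.copy() if M is None else M + G
        for (PA, PB, PX) in self._pat_pairs:
            part = PA + PB + PX
            M = part if M is None else M + part
        if M is None:
            raise DesignError("empty residual structure")
        M = M.tocsc()
        M.sort_indices()
        return M

    def coefficients(self, rvar: np.ndarray, rcov: np.ndarray):
        """Per-combo R^-1 block coefficients (a, b, x) and dets."""
        out = []
        for (ci, cj, g), idx in self.combos:
            det = rvar[ci] * rvar[cj] - rcov[g] ** 2
            out.append((rvar[cj] / det, rvar[ci] / det, -rcov[g] / det, det, len(idx)))
        return out

    def rinv_weights(self, rvar, rcov):
        """Weights over (unpaired grams, pair grams) reproducing W'R^-1 W."""
        wu = [1.0 / rvar[c] if self.gram_unpaired[c] is not None else 0.0
              for c in range(self.res.n_classes)]
        wp = [(a, b, x) for (a, b, x, det, m) in self.coefficients(rvar, rcov)]
        return wu, wp

    def assemble(self, wu, wp) -> sparse.csc_matrix:
        M = None
        for c, G in enumerate(self.gram_unpaired):
            if G is None or wu[c] == 0.0:
                continue
            M = G * wu[c] if M is None else M + G * wu[c]
        for (GA, GB, GX), (a, b, x) in zip(self.gram_pairs, wp):
            part = GA * a + GB * b + GX * x
            M = part if M is None else M + part
        if M is None:
            raise DesignError("empty residual structure")
        return M.tocsc()

    def h_weights(self, k_info: ParamInfo, rvar, rcov):
        """Gram weights for H_k = R^-1 (dR/dtheta_k) R^-1."""
        wu = [0.0] * self.res.n_classes
        wp = [(0.0, 0.0, 0.0)] * len(self.combos)
        coefs = self.coefficients(rvar, rcov)
        if k_info.kind == "rvar":
            c = k_info.cls
            if self.gram_unpaired[c] is not None:
                wu[c] = 1.0 / rvar[c] ** 2
            for ic, ((ci, cj, g), idx) in enumerate(self.combos):
                a, b, x, det, m = coefs[ic]
                if ci == c:
                    pa, pb, px = wp[ic]
                    wp[ic] = (pa + a * a, pb + x * x, px + a * x)
                if cj == c:
                    pa, pb, px = wp[ic]
                    wp[ic] = (pa + x * x, pb + b * b, px + b * x)
        else:  # rcov
            g0 = k_info.group
            for ic, ((ci, cj, g), idx) in enumerate(self.combos):
                if g != g0:
                    continue
                a, b, x, det, m = coefs[ic]
                wp[ic] = (2 * a * x, 2 * b * x, a * b + x * x)
        return wu, wp

    def rinv_apply(self, rvar, rcov, v: np.ndarray) -> np.ndarray:
        out = v.copy()
        cls = self.res.classes
        out /= rvar[cls]
        # fix up paired records
        res = self.res
        if len(res.pair_i):
            coefs = self.coefficients(rvar, rcov)
            for ic, ((ci, cj, g), idx) in enumerate(self.combos):
                a, b, x, det, m = coefs[ic]
                I = res.pair_i[idx]
                J = res.pair_j[idx]
                vi, vj = v[I], v[J]
                out[I] = a * vi + x * vj
                out[J] = b * vj + x * vi
        return out

    def logdet_r(self, rvar, rcov) -> float:
        cls = self.res.classes
        total = 0.0
        for c in range(self.res.n_classes):
            total += len(self.unpaired_rows[c]) * np.log(rvar[c])
        for ic, ((ci, cj, g), idx) in enumerate(self.combos):
            det = rvar[ci] * rvar[cj] - rcov[g] ** 2
            total += len(idx) * np.log(det)
        return total

    def tr_rinv_dr(self, k_info: ParamInfo, rvar, rcov) -> float:
        coefs = self.coefficients(rvar, rcov)
        if k_info.kind == "rvar":
            c = k_info.cls
            total = len(self.unpaired_rows[c]) / rvar[c]
            for ic, ((ci, cj, g), idx) in enumerate(self.combos):
                a, b, x, det, m = coefs[ic]
                if ci == c:
                    total += m * a
                if cj == c:
                    total += m * b
            return total
        g0 = k_info.group
        total = 0.0
        for ic, ((ci, cj, g), idx) in enumerate(self.combos):
            a, b, x, det, m = coefs[ic]
            if g == g0:
                total += 2 * m * x
        return total

    def dr_apply(self, k_info: ParamInfo, v: np.ndarray) -> np.ndarray:
        """(dR/dtheta_k) v."""
        res = self.res
        out = np.zeros_like(v)
        if k_info.kind == "rvar":
            mask = res.classes == k_info.cls
            out[mask] = v[mask]
        else:
            sel = res.pair_group == k_info.group
            I = res.pair_i[sel]
            J = res.pair_j[sel]
            out[I] += v[J]
            out[J] += v[I]
        return out


# ---------------------------------------------------------------------------
# the REML engine
# ---------------------------------------------------------------------------


@dataclass
class VarianceReport:
    """REML estimates with curvature-based standard errors and solutions."""

    names: list
    estimates: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    logl: float
    n_records: int
    n_fixed: int
    n_parameters: int
    converged: bool
    n_iter: int
    solutions: dict
    meta: dict = field(default_factory=dict)
    boundary: np.ndarray | None = None
    logl_ml: float = float("nan")

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    @property
    def aic(self) -> float:
        return -2.0 * self.logl + 2.0 * self.n_parameters

    @property
    def bic(self) -> float:
        return -2.0 * self.logl + self.n_parameters * np.log(self.n_records)

    # full-likelihood criteria (k counts fixed plus variance parameters);
    # REML likelihoods are not comparable between models whose covariate
    # values differ, so model scans over severity codings use these
    @property
    def aic_ml(self) -> float:
        k = self.n_parameters + self.n_fixed
        return -2.0 * self.logl_ml + 2.0 * k

    @property
    def bic_ml(self) -> float:
        k = self.n_parameters + self.n_fixed
        return -2.0 * self.logl_ml + k * np.log(self.n_records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": self.names, "estimate": self.estimates, "se": self.se}
        )

    def covariance_block(self, term: str, cols: list) -> np.ndarray:
        """Extract a q x q covariance block of a random term by column names."""
        q = len(cols)
        S = np.empty((q, q))
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                if i == j:
                    S[i, i] = self[f"{term}:var({a})"]
                else:
                    x, y_ = (a, b) if f"{term}:cov({a},{b})" in self.names else (b, a)
                    S[i, j] = self[f"{term}:cov({x},{y_})"]
        return S


class REMLModel:
    """Stateful fitter for one assembled design."""

    def __init__(self, asm: Assembled):
        self.asm = asm
        self.infos = _param_layout(asm)
        self.npar = len(self.infos)
        n = asm.n
        # W = [Z_1 ... Z_T X]; X last so the minimum-degree ordering pushes
        # its dense rows into the dense tail of the factor
        blocks = [t.Z for t in asm.terms] + [asm.X]
        self.W = sparse.hstack(blocks, format="csr")
        self.offsets = np.cumsum([0] + [t.Z.shape[1] for t in asm.terms])
        self.N = self.W.shape[1]
        self.p = asm.X.shape[1]
        self.ra = _ResidualAlgebra(asm, self.W)
        # fixed union pattern of C
        Wpat = self.ra.pattern()
        gpat = []
        for t in asm.terms:
            if t.kinv is not None:
                kp = t.kinv.copy()
                kp.data = np.abs(kp.data) + 1.0
                gpat.append(sparse.kron(kp, np.ones((t.q, t.q)), format="csc"))
            else:
                gpat.append(
                    sparse.kron(
                        sparse.identity(t.m, format="csc"), np.ones((t.q, t.q)),
                        format="csc",
                    )
                )
        Gpat = sparse.block_diag(
            gpat + [sparse.identity(self.p, format="csc")], format="csc"
        )
        pattern = (Wpat + Gpat).tocsc()
        # structure-aware elimination order: youngest animals first (their
        # equations touch only their parents and own records), founders and
        # dam effects later, dense fixed-effect rows last — dramatically
        # less fill than generic orderings on pedigree MMEs
        perm_parts = []
        for it, t in enumerate(asm.terms):
            eqs = np.arange(self.offsets[it], self.offsets[it + 1])
            if t.kinv is not None:
                eqs = eqs.reshape(t.m, t.q)[::-1].ravel()
            perm_parts.append(eqs)
        perm_parts.append(np.arange(self.offsets[-1], self.N))
        perm = np.concatenate(perm_parts)
        self.solver = LDLSolver(pattern, perm=perm)
        self._pattern = pattern

        # entry maps for trace computations
        self._g_maps = []
        for it, t in enumerate(asm.terms):
            base = self.offsets[it]
            if t.kinv is not None:
                kc = t.kinv.tocoo()
                ki, kj, kv = kc.row, kc.col, kc.data
            else:
                ki = kj = np.arange(t.m)
                kv = np.ones(t.m)
            q = t.q
            rows = (base + ki[:, None] * q + np.repeat(np.arange(q), q)[None, :]).ravel()
            cols = (base + kj[:, None] * q + np.tile(np.arange(q), q)[None, :]).ravel()
            aa = np.repeat(np.arange(q), q)
            bb = np.tile(np.arange(q), q)
            emap = self.solver.make_entry_map(rows, cols)
            self._g_maps.append((emap, np.repeat(kv, q * q), np.tile(aa, len(kv)),
                                 np.tile(bb, len(kv)), q))
        wcoo = Wpat.tocoo()
        self._w_map = self.solver.make_entry_map(wcoo.row, wcoo.col)
        self._w_rows, self._w_cols = wcoo.row, wcoo.col
        self._wpat_csc = Wpat.copy().tocsc()
        self._wpat_csc.sort_indices()
        self._wpat_csc.data[:] = 0.0

        # cache of the current evaluation
        self._cache_theta = None
        self._cache = None

    # -- likelihood -------------------------------------------------------

    def _ginv_total(self, sigmas):
        parts = []
        for t, S in zip(self.asm.terms, sigmas):
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                return None
            if t.kinv is not None:
                parts.append(sparse.kron(t.kinv, Sinv, format="csc"))
            else:
                parts.append(
                    sparse.kron(sparse.identity(t.m, format="csc"), Sinv, format="csc")
                )
        parts.append(sparse.csc_matrix((self.p, self.p)))
        return sparse.block_diag(parts, format="csc")

    def _evaluate(self, theta: np.ndarray):
        """Factor the MME at theta; return the cache dict (or None if the
        proposal is numerically infeasible)."""
        if self._cache_theta is not None and np.array_equal(theta, self._cache_theta):
            return self._cache
        asm = self.asm
        sigmas, rvar, rcov = _unpack(theta, asm)
        if np.any(~np.isfinite(theta)) or np.any(rvar <= 0):
            return None
        wu, wp = self.ra.rinv_weights(rvar, rcov)
        WRW = self.ra.assemble(wu, wp)
        ginv = self._ginv_total(sigmas)
        if ginv is None:
            return None
        C = (WRW + ginv).tocsc()
        try:
            self.solver.factor(C)
        except np.linalg.LinAlgError:
            return None
        if not self.solver.is_posdef:
            return None
        rinv_y = self.ra.rinv_apply(rvar, rcov, asm.y)
        rhs = self.W.T @ rinv_y
        sol = self.solver.solve(rhs)
        ypy = float(asm.y @ rinv_y - rhs @ sol)
        logdet_c = self.solver.logdet()
        logdet_r = self.ra.logdet_r(rvar, rcov)
        logdet_g = 0.0
        for t, S in zip(asm.terms, sigmas):
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                return None
            logdet_g += t.m * ld + t.q * t.logdet_k
        n, p = asm.n, self.p
        m2ll = (n - p) * np.log(2 * np.pi) + logdet_r + logdet_g + logdet_c + ypy
        resid = asm.y - self.W @ sol
        er = self.ra.rinv_apply(rvar, rcov, resid)  # = P y
        cache = {
            "theta": theta.copy(),
            "sigmas": sigmas,
            "rvar": rvar,
            "rcov": rcov,
            "sol": sol,
            "er": er,
            "resid": resid,
            "logl": -0.5 * m2ll,
            "WRW": WRW,
        }
        self._cache_theta = theta.copy()
        self._cache = cache
        return cache

    def loglik(self, theta: np.ndarray) -> float:
        c = self._evaluate(np.asarray(theta, dtype=float))
        return -np.inf if c is None else c["logl"]

    # -- derivatives ------------------------------------------------------

    def _iteration_quantities(self, cache):
        """Selected-inverse summaries used by scores and EM updates:
        S_t (q x q trace matrices) per term and the W-pattern inverse values."""
        asm = self.asm
        self.solver.takahashi()
        s_mats = []
        for (emap, kv, aa, bb, q) in self._g_maps:
            vals = self.solver.inv_entries(emap)
            S = np.zeros((q, q))
            np.add.at(S, (aa, bb), kv * vals)
            s_mats.append(0.5 * (S + S.T))
        w_inv_vals = self.solver.inv_entries(self._w_map)
        return s_mats, w_inv_vals

    def _q_mats(self, cache):
        """Q_t = U' K^-1 U per term (BLUP quadratic forms)."""
        out = []
        for it, t in enumerate(self.asm.terms):
            u = cache["sol"][self.offsets[it] : self.offsets[it + 1]]
            U = u.reshape(t.m, t.q)
            KU = U if t.kinv is None else t.kinv @ U
            out.append(U.T @ KU)
        return out

    def scores(self, cache, s_mats, w_inv_vals):
        """Exact REML first derivatives at the cached point."""
        asm = self.asm
        rvar, rcov = cache["rvar"], cache["rcov"]
        er = cache["er"]
        q_mats = self._q_mats(cache)
        g = np.zeros(self.npar)
        for k, info in enumerate(self.infos):
            if info.kind == "g":
                t = asm.terms[info.term]
                S = cache["sigmas"][info.term]
                Sinv = np.linalg.inv(S)
                E = np.zeros((t.q, t.q))
                E[info.a, info.b] = E[info.b, info.a] = 1.0
                B = Sinv @ E @ Sinv
                tr_pdv = t.m * np.trace(Sinv @ E) - np.sum(B * s_mats[info.term])
                quad = np.sum(B * q_mats[info.term])
                g[k] = -0.5 * (tr_pdv - quad)
            else:
                wu, wp = self.ra.h_weights(info, rvar, rcov)
                Mk = self.ra.assemble(wu, wp)
                tr_cm = float(np.dot(_aligned_data(Mk, self._wpat_csc), w_inv_vals))
                tr_pdv = self.ra.tr_rinv_dr(info, rvar, rcov) - tr_cm
                dr_er = self.ra.dr_apply(info, er)
                quad = float(er @ dr_er)
                g[k] = -0.5 * (tr_pdv - quad)
        return g

    def _f_vectors(self, cache):
        """Working variates f_k = (dV/dtheta_k) P y for the AI matrix."""
        asm = self.asm
        n = asm.n
        F = np.zeros((n, self.npar))
        er = cache["er"]
        for k, info in enumerate(self.infos):
            if info.kind == "g":
                it = info.term
                t = asm.terms[it]
                S = cache["sigmas"][it]
                Sinv = np.linalg.inv(S)
                E = np.zeros((t.q, t.q))
                E[info.a, info.b] = E[info.b, info.a] = 1.0
                Bm = E @ Sinv
                u = cache["sol"][self.offsets[it] : self.offsets[it + 1]]
                U = u.reshape(t.m, t.q)
                F[:, k] = t.Z @ (U @ Bm.T).ravel()
            else:
                F[:, k] = self.ra.dr_apply(info, er)
        return F

    def ai_matrix(self, cache):
        """Average information: AI_kl = f_k' P f_l / 2."""
        rvar, rcov = cache["rvar"], cache["rcov"]
        F = self._f_vectors(cache)
        RF = np.column_stack(
            [self.ra.rinv_apply(rvar, rcov, F[:, k]) for k in range(self.npar)]
        )
        T = self.W.T @ RF
        Sol = np.column_stack([self.solver.solve(T[:, k]) for k in range(self.npar)])
        PF = RF - np.column_stack(
            [
                self.ra.rinv_apply(rvar, rcov, self.W @ Sol[:, k])
                for k in range(self.npar)
            ]
        )
        return 0.5 * (F.T @ PF)

    def em_step(self, cache, s_mats, w_inv_vals) -> np.ndarray:
        """One EM-REML update (monotone, always feasible)."""
        asm = self.asm
        theta = np.empty(self.npar)
        q_mats = self._q_mats(cache)
        k = 0
        for it, t in enumerate(asm.terms):
            Snew = (q_mats[it] + s_mats[it]) / t.m
            for a in range(t.q):
                for b_ in range(a + 1):
                    theta[k] = Snew[a, b_]
                    k += 1
        # residual classes (diagonal-R EM; pair-covariance models keep the
        # previous residual values — the AI step handles those parameters)
        res = asm.residual
        if res.n_groups == 0:
            resid = cache["resid"]
            # tr(C^-1 W_c'W_c) from the aligned W-pattern inverse values
            for c in range(res.n_classes):
                rows = np.flatnonzero(res.classes == c)
                Wc = self.W[rows]
                G = (Wc.T @ Wc).tocsc()
                trc = float(np.dot(_aligned_data(G, self._wpat_csc), w_inv_vals))
                theta[k] = (float(resid[rows] @ resid[rows]) + trc) / len(rows)
                k += 1
        else:
            theta[k : k + res.n_classes] = cache["rvar"]
            k += res.n_classes
            theta[k : k + res.n_groups] = cache["rcov"]
            k += res.n_groups
        return theta

    # -- driver -----------------------------------------------------------

    def default_start(self) -> np.ndarray:
        asm = self.asm
        vy = float(np.var(asm.y))
        theta = []
        nterms = max(len(asm.terms), 1)
        for t in asm.terms:
            covs = np.asarray((t.Z.power(2)).sum(axis=0)).ravel()
            # mean squared covariate per effect column
            colscale = np.array(
                [
                    max(covs[c :: t.q].sum() / max(asm.n, 1), 1e-12)
                    for c in range(t.q)
                ]
            )
            for a in range(t.q):
                for b_ in range(a + 1):
                    theta.append(0.3 * vy / (nterms + 1) / np.sqrt(colscale[a] * colscale[b_])
                                 if a == b_ else 0.0)
        theta += [0.5 * vy] * asm.residual.n_classes
        theta += [0.0] * asm.residual.n_groups
        return np.asarray(theta)

    # -- log-Cholesky transform: every point of the transformed space maps
    #    to a PD covariance structure, so Newton steps cannot leave the
    #    parameter space no matter how aggressive they are

    def _theta_to_lambda(self, theta: np.ndarray) -> np.ndarray:
        sigmas, rvar, rcov = _unpack(theta, self.asm)
        lam = []
        for S in sigmas:
            q = S.shape[0]
            scale = max(np.abs(np.diag(S)).max(), 1e-300)
            L = np.linalg.cholesky(S + 1e-12 * scale * np.eye(q))
            for a in range(q):
                for b_ in range(a + 1):
                    lam.append(np.log(L[a, a]) if a == b_ else L[a, b_])
        lam += list(np.log(np.maximum(rvar, 1e-300)))
        lam += list(rcov)
        return np.asarray(lam)

    def _lambda_to_theta(self, lam: np.ndarray) -> np.ndarray:
        theta = np.empty(self.npar)
        k = 0
        for t in self.asm.terms:
            q = t.q
            L = np.zeros((q, q))
            for a in range(q):
                for b_ in range(a + 1):
                    L[a, b_] = np.exp(lam[k]) if a == b_ else lam[k]
                    k += 1
            S = L @ L.T
            kk = k - q * (q + 1) // 2
            for a in range(q):
                for b_ in range(a + 1):
                    theta[kk] = S[a, b_]
                    kk += 1
        nc = self.asm.residual.n_classes
        theta[k : k + nc] = np.exp(lam[k : k + nc])
        k += nc
        ng = self.asm.residual.n_groups
        theta[k : k + ng] = lam[k : k + ng]
        return theta

    def _jacobian(self, lam: np.ndarray) -> np.ndarray:
        """J[i, j] = d theta_i / d lambda_j (block diagonal)."""
        J = np.zeros((self.npar, self.npar))
        k = 0
        for t in self.asm.terms:
            q = t.q
            nb = q * (q + 1) // 2
            L = np.zeros((q, q))
            pos = []
            for a in range(q):
                for b_ in range(a + 1):
                    L[a, b_] = np.exp(lam[k + len(pos)]) if a == b_ else lam[k + len(pos)]
                    pos.append((a, b_))
            for j, (c, d) in enumerate(pos):
                dL = np.zeros((q, q))
                dL[c, d] = L[c, d] if c == d else 1.0
                dS = dL @ L.T + L @ dL.T
                for i, (a, b_) in enumerate(pos):
                    J[k + i, k + j] = dS[a, b_]
            k += nb
        nc = self.asm.residual.n_classes
        for c in range(nc):
            J[k + c, k + c] = np.exp(lam[k + c])
        k += nc
        for g in range(self.asm.residual.n_groups):
            J[k + g, k + g] = 1.0
        return J

    def fit(
        self,
        start: np.ndarray | None = None,
        max_iter: int = 200,
        tol_logl: float = 1e-8,
        tol_param: float = 1e-6,
        compute_se: bool = True,
        verbose: bool = False,
    ) -> VarianceReport:
        asm = self.asm
        theta = np.asarray(start, dtype=float) if start is not None else self.default_start()
        scale0 = np.abs(theta).max()
        if not _feasible(theta, asm, scale0):
            raise DesignError("infeasible starting values")
        cache = self._evaluate(theta)
        if cache is None:
            raise DesignError("starting values give a singular system")
        logl = cache["logl"]
        converged = False
        it = 0
        stall = 0
        # per-parameter scale for boundary detection and convergence metrics
        par_scale = np.maximum(np.abs(theta), 1e-8 * max(scale0, 1e-300))
        floor = 1e-6 * par_scale
        fixed = np.zeros(self.npar, dtype=bool)  # components held at a boundary
        free = ~fixed
        for it in range(1, max_iter + 1):
            s_mats, w_inv_vals = self._iteration_quantities(cache)
            grad = self.scores(cache, s_mats, w_inv_vals)

            # boundary bookkeeping: variance components collapsing to zero
            # with a non-positive score are pinned at a small floor; their
            # covariances are pinned at zero alongside
            for k, info in enumerate(self.infos):
                if fixed[k] or not info.is_variance:
                    continue
                if theta[k] <= 2.0 * floor[k] and grad[k] <= 0.0:
                    theta[k] = floor[k]
                    fixed[k] = True
                    if info.kind == "g":
                        for k2, i2 in enumerate(self.infos):
                            if (
                                i2.kind == "g"
                                and i2.term == info.term
                                and not i2.is_variance
                                and info.a in (i2.a, i2.b)
                            ):
                                theta[k2] = 0.0
                                fixed[k2] = True
            if fixed.any():
                cache = self._evaluate(theta)
                s_mats, w_inv_vals = self._iteration_quantities(cache)
                grad = self.scores(cache, s_mats, w_inv_vals)
                logl = cache["logl"]
            free = ~fixed
            if not free.any():
                converged = True
                break

            ai = self.ai_matrix(cache)
            lam = self._theta_to_lambda(theta)
            J = self._jacobian(lam)
            grad_l = (J.T @ grad)[free]
            ai_l = (J.T @ ai @ J)[np.ix_(free, free)]
            ridge = 1e-8 * max(np.trace(ai_l) / max(free.sum(), 1), 1e-300)
            new_theta = None
            try:
                step_f = np.linalg.solve(ai_l + ridge * np.eye(free.sum()), grad_l)
                step_l = np.zeros(self.npar)
                step_l[free] = step_f
            except np.linalg.LinAlgError:
                step_l = None
            if step_l is not None:
                # clip each log-scale coordinate: ill-identified directions
                # must not throttle progress in well-identified ones
                step_l = np.clip(step_l, -4.0, 4.0)
                alpha = 1.0
                for _ in range(10):
                    cand = self._lambda_to_theta(lam + alpha * step_l)
                    cand[fixed] = theta[fixed]
                    if _feasible(cand, asm, scale0):
                        cand_cache = self._evaluate(cand)
                        if cand_cache is not None and cand_cache["logl"] >= logl - 1e-10:
                            new_theta, new_cache = cand, cand_cache
                            break
                    alpha *= 0.5
            if new_theta is None:
                # EM fallback: guaranteed uphill
                cand = self.em_step(cache, s_mats, w_inv_vals)
                cand = np.where(np.isfinite(cand), cand, theta)
                cand[fixed] = theta[fixed]
                if not _feasible(cand, asm, scale0):
                    cand = 0.5 * (cand + theta)
                    cand[fixed] = theta[fixed]
                cand_cache = self._evaluate(cand)
                if cand_cache is None:
                    converged = False
                    break
                new_theta, new_cache = cand, cand_cache
            d_logl = new_cache["logl"] - logl
            rel = np.abs(new_theta - theta) / np.maximum(np.abs(theta), 0.05 * par_scale)
            d_par = np.max(rel[free]) if free.any() else 0.0
            theta, cache, logl = new_theta, new_cache, new_cache["logl"]
            if verbose:
                print(
                    f"iter {it:3d} logL {logl:.6f} dlogL {d_logl:.3e} "
                    f"dpar {d_par:.3e} fixed {int(fixed.sum())}"
                )
            if abs(d_logl) < tol_logl * (1.0 + abs(logl)) and d_par < 1e-3:
                converged = True
                break
            if d_par < tol_param:
                converged = True
                break
            # stalled AI/EM progress on a likelihood ridge: hand over to the
            # quasi-Newton polish below rather than crawling further
            stall = stall + 1 if d_logl < 2e-2 else 0
            if stall >= 10:
                break
        if not converged and free.any():
            theta2, ok = self._polish_lbfgs(theta, fixed, verbose=verbose)
            cache2 = self._evaluate(theta2)
            if cache2 is not None and cache2["logl"] >= logl - 1e-8:
                gain = cache2["logl"] - logl
                theta, cache, logl = theta2, cache2, cache2["logl"]
                # if a 300-evaluation quasi-Newton with exact gradients finds
                # no further improvement, the (possibly boundary-constrained)
                # optimum has been reached
                converged = ok or gain < 1e-5 * (1.0 + abs(logl))
        # final quantities
        se = np.full(self.npar, np.nan)
        vcov = np.full((self.npar, self.npar), np.nan)
        if compute_se:
            ai = self.ai_matrix(cache)
            try:
                vcov = np.linalg.inv(ai)
                se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(ai)
                se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        logl_ml = self._ml_loglik(cache)
        solutions = self._solutions(cache)
        boundary = fixed | np.array(
            [
                info.is_variance and est < 1e-6 * scale0
                for info, est in zip(self.infos, theta)
            ]
        )
        # flag covariances whose implied correlation sits at the PSD edge
        sigmas_f, _, _ = _unpack(theta, asm)
        for k, info in enumerate(self.infos):
            if info.kind == "g" and not info.is_variance:
                S = sigmas_f[info.term]
                denom = np.sqrt(S[info.a, info.a] * S[info.b, info.b])
                if denom > 0 and abs(S[info.a, info.b]) / denom > CORR_BOUND - 1e-6:
                    boundary[k] = True
        return VarianceReport(
            names=[i.name for i in self.infos],
            estimates=theta.copy(),
            se=se,
            vcov=vcov,
            logl=logl,
            n_records=asm.n,
            n_fixed=self.p,
            n_parameters=self.npar,
            converged=converged,
            n_iter=it,
            solutions=solutions,
            boundary=boundary,
            meta={**asm.meta, "record_labels": asm.record_index},
            logl_ml=logl_ml,
        )

    def _polish_lbfgs(self, theta, fixed, maxfun: int = 300, verbose: bool = False):
        """Quasi-Newton refinement in the log-Cholesky space with exact
        analytic gradients; used when AI/EM progress stalls on a ridge."""
        from scipy.optimize import minimize

        lam0 = self._theta_to_lambda(theta)
        bounds = [
            (lam0[k], lam0[k]) if fixed[k] else (None, None) for k in range(self.npar)
        ]

        def fun(lam):
            th = self._lambda_to_theta(np.clip(lam, -30.0, 30.0))
            th[fixed] = theta[fixed]
            cache = self._evaluate(th)
            if cache is None:
                return 1e30, np.zeros(self.npar)
            s_mats, w_inv = self._iteration_quantities(cache)
            g = self.scores(cache, s_mats, w_inv)
            gl = self._jacobian(lam).T @ g
            gl[fixed] = 0.0
            return -cache["logl"], -gl

        res = minimize(
            fun,
            lam0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": maxfun, "ftol": 1e-13, "gtol": 1e-7},
        )
        if verbose:
            print(f"polish: {res.nit} iters, logL {-res.fun:.6f}, |g| {np.abs(res.jac).max():.2e}")
        th = self._lambda_to_theta(res.x)
        th[fixed] = theta[fixed]
        ok = bool(res.success) or np.abs(res.jac).max() < 1e-4 * (1.0 + abs(res.fun))
        return th, ok

    def _ml_loglik(self, cache) -> float:
        """Full (ML) log-likelihood at the current variance estimates.

        Uses -2 l_ML = n log 2pi + log|V| + (y - X beta)' V^-1 (y - X beta)
        and log|X' V^-1 X| = log|C| - log|C_uu| (C_uu the random-effect
        block of the MME, i.e. the fixed-block Schur identity)."""
        from scipy.sparse.linalg import splu as _splu

        nrand = self.offsets[-1]
        if nrand == 0:
            log_xvx = self.solver.logdet()
        else:
            theta = cache["theta"]
            sigmas, rvar, rcov = _unpack(theta, self.asm)
            wu, wp = self.ra.rinv_weights(rvar, rcov)
            WRW = self.ra.assemble(wu, wp)
            C = (WRW + self._ginv_total(sigmas)).tocsc()
            Cuu = C[:nrand, :nrand].tocsc()
            try:
                lu = _splu(Cuu)
                ld_uu = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
            except RuntimeError:
                return float("nan")
            # refactor the full C: the solver may hold the factorization of
            # a rejected trial point
            try:
                self.solver.factor(C)
            except np.linalg.LinAlgError:
                return float("nan")
            log_xvx = self.solver.logdet() - ld_uu
        p = self.p
        return cache["logl"] - 0.5 * p * np.log(2 * np.pi) + 0.5 * log_xvx

    def _solutions(self, cache) -> dict:
        asm = self.asm
        sol = cache["sol"]
        out = {}
        for it, t in enumerate(asm.terms):
            u = sol[self.offsets[it] : self.offsets[it + 1]].reshape(t.m, t.q)
            out[t.name] = pd.DataFrame(u, columns=t.col_names, index=t.level_ids)
        beta = sol[self.offsets[-1] :]
        out["fixed"] = pd.Series(beta, index=asm.x_names)
        return out


def _aligned_data(M: sparse.spmatrix, pattern: sparse.csc_matrix) -> np.ndarray:
    """Data of M scattered into the slot order of `pattern` (M's pattern must
    be a subset of pattern's; both canonical CSC)."""
    M = M.tocsc()
    M.sort_indices()
    pos = subset_positions(M.indptr, M.indices, pattern.indptr, pattern.indices,
                            pattern.shape[1])
    if np.any(pos < 0):
        raise ValueError("matrix pattern not contained in the reference pattern")
    out = np.zeros(pattern.nnz)
    out[pos] = M.data
    return out


def reml_fit(asm: Assembled, start=None, **options) -> VarianceReport:
    """Fit an assembled mixed model by AI-REML. See :class:`REMLModel`."""
    return REMLModel(asm).fit(start=start, **options)


def information_criteria(report: VarianceReport) -> tuple:
    """(AIC, BIC) from the REML log-likelihood; k counts variance parameters
    and n the records used — the usual mixed-model software convention."""
    return report.aic, report.bic


def delta_se(report: VarianceReport, func) -> float:
    """First-order (delta-method) standard error of func(component dict).

    `func` maps {component name: value} to a scalar. Returns NaN when the
    curvature matrix was unavailable or singular.
    """
    if not np.all(np.isfinite(report.vcov)):
        return float("nan")
    theta = report.estimates
    names = report.names
    h = np.maximum(np.abs(theta), 1.0) * 1e-6
    grad = np.zeros(len(theta))
    for k in range(len(theta)):
        up = dict(zip(names, theta))
        dn = dict(zip(names, theta))
        up[names[k]] = theta[k] + h[k]
        dn[names[k]] = theta[k] - h[k]
        grad[k] = (func(up) - func(dn)) / (2 * h[k])
    var = float(grad @ report.vcov @ grad)
    return float(np.sqrt(var)) if var >= 0 else float("nan")
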