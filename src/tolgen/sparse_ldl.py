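"""Sparse symmetric LDL' factorization with a Takahashi selected inverse.

The mixed-model equations (MME) of an animal model are sparse, symmetric
and positive definite. REML needs, per iteration: log|C|, solves C x = b,
and — for exact first derivatives and EM updates — selected entries of
C^-1 on the sparsity pattern of C. scipy offers none of these for
symmetric matrices (splu discards symmetry and cannot return selected
inverses), so this module implements the classical up-looking simplicial
LDL' (elimination-tree symbolic analysis + numeric factorization) and the
Takahashi recurrences for the inverse restricted to the filled pattern.

Pedigree MMEs factor with a characteristic shape under a minimum-degree
ordering: thousands of short columns (offspring equations) followed by a
nearly dense tail (parent, dam and fixed-effect equations). The selected
inverse exploits this: the tail block of C^-1 is the inverse of its Schur
complement, computed densely with BLAS, and only the short columns run
through the sparse Takahashi recurrences.

All sequential kernels are numba-compiled; the symbolic step is done once
per model structure and reused across REML iterations.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.linalg import solve_triangular
from scipy.sparse.linalg import splu


@njit(cache=True)
def _symbolic(n, Ap, Ai):
    """Elimination tree and column counts from the upper-triangular pattern."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    Lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                Lnz[i] += 1
                flag[i] = k
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + Lnz[k]
    return parent, Lp


@njit(cache=True)
def _numeric(n, Ap, Ai, Ax, Lp, parent, Li, Lx, D):
    """Up-looking LDL' numeric factorization. Returns -1 on success, else
    the column index of the first zero pivot."""
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz_cur = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        Dk = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            if i == k:
                Dk += Ax[p]
                continue
            Y[i] += Ax[p]
            # walk up the elimination tree to collect the row-k pattern
            ln = 0
            while flag[i] != k:
                stack[ln] = i
                ln += 1
                flag[i] = k
                i = parent[i]
            while ln > 0:
                ln -= 1
                top -= 1
                pattern[top] = stack[ln]
        # sparse triangular solve along the pattern (topological order)
        for s in range(top, n):
            j = pattern[s]
            yj = Y[j]
            Y[j] = 0.0
            p2 = Lp[j] + lnz_cur[j]
            for p in range(Lp[j], p2):
                Y[Li[p]] -= Lx[p] * yj
            ljk = yj / D[j]
            Dk -= ljk * yj
            Li[p2] = k
            Lx[p2] = ljk
            lnz_cur[j] += 1
        D[k] = Dk
        if Dk == 0.0:
            return k
    return -1


@njit(cache=True)
def _solve(n, Lp, Li, Lx, D, b):
    for j in range(n):
        bj = b[j]
        if bj != 0.0:
            for p in range(Lp[j], Lp[j + 1]):
                b[Li[p]] -= Lx[p] * bj
    for j in range(n):
        b[j] /= D[j]
    for j in range(n - 1, -1, -1):
        s = b[j]
        for p in range(Lp[j], Lp[j + 1]):
            s -= Lx[p] * b[Li[p]]
        b[j] = s


@njit(cache=True)
def _lookup(Lp, Li, col, row):
    """Binary search for `row` in column `col` of L; -2 if absent."""
    lo = Lp[col]
    hi = Lp[col + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        v = Li[mid]
        if v == row:
            return mid
        if v < row:
            lo = mid + 1
        else:
            hi = mid
    return -2


@njit(cache=True)
def _takahashi_sparse(n1, Lp, Li, Lx, D, T22, Zx, Zd):
    """Takahashi recurrences for columns j < n1; columns >= n1 are served
    by the dense tail inverse T22 (already scattered into Zx/Zd).

      Z_ij = - sum_k L_kj Z(max(i,k), min(i,k)),  i in struct(col j), i > j
      Z_jj = 1/d_j - sum_k L_kj Z_kj

    Every referenced pair has both indices > j, so it lives either in an
    already-finished sparse column or in the dense tail.
    """
    for j in range(n1 - 1, -1, -1):
        p0 = Lp[j]
        p1 = Lp[j + 1]
        for p in range(p0, p1):
            i = Li[p]
            s = 0.0
            for q in range(p0, p1):
                k = Li[q]
                if k == i:
                    if i >= n1:
                        zki = T22[i - n1, i - n1]
                    else:
                        zki = Zd[i]
                else:
                    a, b = (k, i) if k > i else (i, k)
                    if b >= n1:
                        zki = T22[a - n1, b - n1]
                    else:
                        zki = Zx[_lookup(Lp, Li, b, a)]
                s += Lx[q] * zki
            Zx[p] = -s
        s = 0.0
        for q in range(p0, p1):
            s += Lx[q] * Zx[q]
        Zd[j] = 1.0 / D[j] - s


@njit(cache=True)
def _scatter_tail(n1, n, Lp, Li, T22, Zx, Zd):
    for j in range(n1, n):
        Zd[j] = T22[j - n1, j - n1]
        for p in range(Lp[j], Lp[j + 1]):
            Zx[p] = T22[Li[p] - n1, j - n1]


@njit(cache=True)
def _extract_tail_factor(n1, n, Lp, Li, Lx):
    m = n - n1
    L22 = np.zeros((m, m))
    for j in range(n1, n):
        L22[j - n1, j - n1] = 1.0
        for p in range(Lp[j], Lp[j + 1]):
            L22[Li[p] - n1, j - n1] = Lx[p]
    return L22


@njit(cache=True)
def subset_positions(Mp, Mi, Pp, Pi, ncols):
    """Positions of the entries of a CSC pattern M inside the data array of
    a CSC pattern P that contains it (both with sorted indices)."""
    pos = np.empty(len(Mi), dtype=np.int64)
    for j in range(ncols):
        p = Pp[j]
        hi = Pp[j + 1]
        for q in range(Mp[j], Mp[j + 1]):
            r = Mi[q]
            while p < hi and Pi[p] != r:
                p += 1
            if p == hi:
                pos[q] = -1  # entry missing from the containing pattern
            else:
                pos[q] = p
                p += 1
    return pos


@njit(cache=True)
def _map_entries(rows_p, cols_p, Lp, Li):
    """Map permuted (row, col) pairs to positions in the Z/L storage.

    Returns (pos, isdiag): pos indexes Zx when isdiag == 0, Zd when 1.
    pos == -2 flags an entry outside the factor pattern (never the case for
    entries of C itself, whose pattern the factor contains).
    """
    m = len(rows_p)
    pos = np.empty(m, dtype=np.int64)
    isdiag = np.zeros(m, dtype=np.int64)
    for t in range(m):
        i = rows_p[t]
        j = cols_p[t]
        if i == j:
            pos[t] = i
            isdiag[t] = 1
        else:
            if i < j:
                i, j = j, i
            pos[t] = _lookup(Lp, Li, j, i)
    return pos, isdiag


def mmd_ordering(pattern: sparse.spmatrix) -> np.ndarray:
    """Fill-reducing ordering via SuperLU's minimum degree on A'+A.

    The matrix values are replaced by a diagonally dominant surrogate so
    that the (discarded) numeric factorization cannot break down.
    """
    n = pattern.shape[0]
    C = pattern.tocsc().copy()
    C.data = np.ones_like(C.data, dtype=float)
    C = (C + C.T + sparse.identity(n, format="csc") * (n + 1.0)).tocsc()
    lu = splu(C, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
    return np.asarray(lu.perm_c, dtype=np.int64)


class LDLSolver:
    """Reusable LDL' factorization of a fixed-pattern symmetric matrix.

    Parameters
    ----------
    C_pattern : scipy sparse matrix
        Symmetric matrix carrying the (fixed) union pattern of everything
        that will be factored. Values are ignored.
    perm : ndarray, optional
        Fill-reducing permutation (perm[k] = original index placed k-th).
        Defaults to minimum degree via :func:`mmd_ordering`.
    """

    # relative cost weights used to pick the sparse/dense split point
    _SPARSE_W = 12.0
    _DENSE_W = 0.02

    def __init__(self, C_pattern: sparse.spmatrix, perm: np.ndarray | None = None):
        C = C_pattern.tocoo()
        n = C.shape[0]
        self.n = n
        if perm is None:
            perm = mmd_ordering(C_pattern)
        self.perm = np.asarray(perm, dtype=np.int64)
        self.iperm = np.empty(n, dtype=np.int64)
        self.iperm[self.perm] = np.arange(n)

        # upper-triangular pattern of the permuted matrix, as CSC
        pi = self.iperm[C.row]
        pj = self.iperm[C.col]
        keep = pi <= pj
        ui, uj = pi[keep], pj[keep]
        order = np.lexsort((ui, uj))
        ui, uj = ui[order], uj[order]
        self.Ai = ui.astype(np.int64)
        self.Ap = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.Ap, uj + 1, 1)
        self.Ap = np.cumsum(self.Ap)

        self.parent, self.Lp = _symbolic(n, self.Ap, self.Ai)
        nnzL = int(self.Lp[n])
        self.Li = np.empty(nnzL, dtype=np.int64)
        self.Lx = np.empty(nnzL)
        self.D = np.empty(n)
        self._choose_split()
        # structural factorization with a diagonally dominant surrogate to
        # populate the row indices Li (the pattern does not depend on values)
        Ax = np.ones(len(self.Ai))
        Ax[self.Ai == np.repeat(np.arange(n), np.diff(self.Ap))] = n + 1.0
        _numeric(n, self.Ap, self.Ai, Ax, self.Lp, self.parent, self.Li, self.Lx, self.D)
        self._Zx = None
        self._Zd = None

    def _choose_split(self) -> None:
        """Pick n1 so that columns >= n1 are inverted densely."""
        n = self.n
        lnz = np.diff(self.Lp).astype(float)
        # cost of running column j through the sparse recurrence vs the
        # cumulative dense-inverse cost of the (n - n1)^3 tail
        sparse_cost = np.concatenate([[0.0], np.cumsum(self._SPARSE_W * lnz**2)])
        m = n - np.arange(n + 1)
        dense_cost = self._DENSE_W * m.astype(float) ** 3
        self.n1 = int(np.argmin(sparse_cost + dense_cost))

    @property
    def factor_nnz(self) -> int:
        return int(self.Lp[self.n])

    def factor(self, C: sparse.spmatrix) -> None:
        """Numerically factor C (pattern contained in the symbolic pattern)."""
        Cc = C.tocoo()
        pi = self.iperm[Cc.row]
        pj = self.iperm[Cc.col]
        keep = pi <= pj
        ui, uj = pi[keep], pj[keep]
        order = np.lexsort((ui, uj))
        ui, uj = ui[order], uj[order]
        Mp = np.zeros(self.n + 1, dtype=np.int64)
        np.add.at(Mp, uj + 1, 1)
        Mp = np.cumsum(Mp)
        pos = subset_positions(Mp, ui.astype(np.int64), self.Ap, self.Ai, self.n)
        if np.any(pos < 0):
            raise ValueError("matrix pattern not contained in the symbolic pattern")
        Ax = np.zeros(len(self.Ai))
        Ax[pos] = Cc.data[keep][order]
        bad = _numeric(
            self.n, self.Ap, self.Ai, Ax, self.Lp, self.parent, self.Li, self.Lx, self.D
        )
        if bad >= 0:
            raise np.linalg.LinAlgError(f"zero pivot in LDL at permuted column {bad}")
        self._Zx = None
        self._Zd = None

    def logdet(self) -> float:
        if np.any(self.D <= 0):
            return np.nan  # factored matrix was not positive definite
        return float(np.sum(np.log(self.D)))

    @property
    def is_posdef(self) -> bool:
        return bool(np.all(self.D > 0))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            x = b[self.perm].copy()
            _solve(self.n, self.Lp, self.Li, self.Lx, self.D, x)
            out = np.empty_like(x)
            out[self.perm] = x
            return out
        out = np.empty_like(b, dtype=float)
        for k in range(b.shape[1]):
            out[:, k] = self.solve(b[:, k])
        return out

    def takahashi(self) -> None:
        """Selected inverse on the factor pattern (cached per factorization)."""
        if self._Zx is not None:
            return
        n, n1 = self.n, self.n1
        m = n - n1
        Zx = np.zeros(self.factor_nnz)
        Zd = np.zeros(n)
        if m > 0:
            L22 = _extract_tail_factor(n1, n, self.Lp, self.Li, self.Lx)
            W = solve_triangular(L22, np.eye(m), lower=True, unit_diagonal=True)
            T22 = W.T @ (W / self.D[n1:, None])
            _scatter_tail(n1, n, self.Lp, self.Li, T22, Zx, Zd)
        else:
            T22 = np.zeros((0, 0))
        _takahashi_sparse(n1, self.Lp, self.Li, self.Lx, self.D, T22, Zx, Zd)
        self._Zx, self._Zd = Zx, Zd

    def make_entry_map(self, rows: np.ndarray, cols: np.ndarray):
        """Precompute Z-storage positions of original-index (row, col) pairs."""
        pos, isdiag = _map_entries(
            self.iperm[np.asarray(rows)], self.iperm[np.asarray(cols)], self.Lp, self.Li
        )
        if np.any(pos == -2):
            raise ValueError("requested inverse entry outside the factor pattern")
        return pos, isdiag

    def inv_entries(self, entry_map) -> np.ndarray:
        """Selected C^-1 values for a map from :meth:`make_entry_map`."""
        self.takahashi()
        pos, isdiag = entry_map
        out = np.empty(len(pos))
        dmask = isdiag == 1
        out[dmask] = self._Zd[pos[dmask]]
        out[~dmask] = self._Zx[pos[~dmask]]
        return out
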