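"""Pedigree algebra for animal models.

A pedigree is a list of (animal, sire, dam) triplets. Everything the mixed
models need from it — inbreeding coefficients F, additive (numerator)
relationships a_ij, and the sparse inverse of the relationship matrix A —
is derived here. A has diagonal 1 + F and the animal model uses
var(additive effects) = sigma^2_G * A, so a correct, inbreeding-aware
A-inverse is the foundation of every fit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: tokens accepted as "parent unknown" in pedigree/phenotype files
MISSING_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "-"}

UNKNOWN = -1  # internal index for an unknown parent


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree (every parent precedes its offspring).

    Attributes
    ----------
    ids : array of animal identifiers (as strings), in sorted order
    sire, dam : integer positions of each animal's parents (-1 = unknown)
    inbreeding : coefficient F per animal, founders 0
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray = field(default=None, repr=False)
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self._index is None:
            self._index = {a: i for i, a in enumerate(self.ids)}
        if self.inbreeding is None:
            self.inbreeding = inbreeding_coefficients(self)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id) -> int:
        try:
            return self._index[str(animal_id)]
        except KeyError:
            raise PedigreeError(f"unknown animal id: {animal_id!r}") from None

    def __contains__(self, animal_id) -> bool:
        return str(animal_id) in self._index

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        blank = np.array([""], dtype=object)
        ids_ext = np.concatenate([blank, self.ids])
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": ids_ext[self.sire + 1],
                "dam": ids_ext[self.dam + 1],
            }
        )

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _toposort(ids, sires, dams):
    """Order animals parents-first; raise listing a cycle if none exists."""
    n = len(ids)
    pos = {a: i for i, a in enumerate(ids)}
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p is not None:
                j = pos[p]
                children[j].append(i)
                indeg[i] += 1
    order = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        i = order[head]
        head += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) < n:
        cyc = sorted(str(ids[i]) for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {', '.join(cyc)}")
    return order


def make_pedigree(triplets) -> Pedigree:
    """Build a validated, sorted :class:`Pedigree` from (animal, sire, dam) triplets.

    Parent ids may be ``None`` (unknown). Parents referenced but never listed
    as animals are added as founders.
    """
    seen = set()
    animals, sire_of, dam_of = [], {}, {}
    for a, s, d in triplets:
        a = None if a is None else str(a)
        s = None if s is None or str(s) in MISSING_TOKENS else str(s)
        d = None if d is None or str(d) in MISSING_TOKENS else str(d)
        if a is None or a in MISSING_TOKENS:
            raise PedigreeError("blank animal id in pedigree")
        if a in seen:
            raise PedigreeError(f"duplicate animal id: {a!r}")
        seen.add(a)
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} is recorded as its own parent")
        animals.append(a)
        sire_of[a] = s
        dam_of[a] = d
    # implicit founders: referenced parents without their own record
    for a in list(animals):
        for p in (sire_of[a], dam_of[a]):
            if p is not None and p not in seen:
                seen.add(p)
                animals.append(p)
                sire_of[p] = None
                dam_of[p] = None
    sires = [sire_of[a] for a in animals]
    dams = [dam_of[a] for a in animals]
    order = _toposort(animals, sires, dams)
    ids = np.array([animals[i] for i in order], dtype=object)
    pos = {a: k for k, a in enumerate(ids)}
    sire_idx = np.array(
        [pos[s] if (s := sire_of[a]) is not None else UNKNOWN for a in ids], dtype=np.int64
    )
    dam_idx = np.array(
        [pos[d] if (d := dam_of[a]) is not None else UNKNOWN for a in ids], dtype=np.int64
    )
    return Pedigree(ids=ids, sire=sire_idx, dam=dam_idx)


def load_pedigree(path) -> Pedigree:
    """Read a 3-column delimited pedigree file (animal, sire, dam).

    Comma or tab separation is autodetected; a header line is optional.
    Unknown parents may be coded "0", "NA", "-", "." or left blank.
    """
    if isinstance(path, io.IOBase):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PedigreeError("empty pedigree file")
    sep = "\t" if "\t" in lines[0] else ","
    rows = [[c.strip() for c in ln.split(sep)] for ln in lines]
    if any(len(r) < 3 for r in rows):
        raise PedigreeError("pedigree file must have 3 columns: animal, sire, dam")
    first = [c.lower() for c in rows[0][:3]]
    if first[0] in {"animal", "animal_id", "id"}:
        rows = rows[1:]
    return make_pedigree((r[0], r[1], r[2]) for r in rows)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = a(sire_i, dam_i) / 2.

    Meuwissen & Luo style recursion over the L (gametic contribution)
    decomposition: for each animal the ancestor contributions are
    accumulated youngest-first, giving F without forming the full A.
    Linear memory; fast for shallow commercial pedigrees.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    # Mendelian-sampling variance term d for each ancestor, filled as we go
    d = np.empty(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else 0.0
        Fd = F[m] if m != UNKNOWN else 0.0
        if s == UNKNOWN and m == UNKNOWN:
            d[i] = 1.0
        elif s == UNKNOWN or m == UNKNOWN:
            d[i] = 0.75 - 0.25 * (Fs + Fd)
        else:
            d[i] = 0.5 - 0.25 * (Fs + Fd)
        if s == UNKNOWN or m == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate gametic contributions L_ij of every ancestor j to i,
        # processing descendants before ancestors (indices are topological)
        L = {i: 1.0}
        pending = {i}
        acc = d[i]  # the j = i term of a_ii = sum_j L_ij^2 d_j
        while pending:
            j = max(pending)
            pending.discard(j)
            lj = L.pop(j)
            if j != i:
                acc += lj * lj * d[j]
            sj, mj = sire[j], dam[j]
            if sj != UNKNOWN:
                L[sj] = L.get(sj, 0.0) + 0.5 * lj
                pending.add(sj)
            if mj != UNKNOWN:
                L[mj] = L.get(mj, 0.0) + 0.5 * lj
                pending.add(mj)
        F[i] = acc - 1.0  # a_ii = 1 + F_i
    return F


def relationship(ped: Pedigree, i, j) -> float:
    """Additive relationship a_ij by the recursive tabular method.

    Intended as an exact oracle on small pedigrees; O(exp) without
    memoisation, so results are cached per call tree.
    """
    ii, jj = ped.index_of(i), ped.index_of(j)
    sire, dam = ped.sire, ped.dam
    cache: dict[tuple[int, int], float] = {}

    def a(p: int, q: int) -> float:
        if p == UNKNOWN or q == UNKNOWN:
            return 0.0
        if p > q:
            p, q = q, p
        key = (p, q)
        if key in cache:
            return cache[key]
        if p == q:
            val = 1.0 + 0.5 * a(sire[p], dam[p])
        else:
            # q is the younger (later) animal
            val = 0.5 * (a(p, sire[q]) + a(p, dam[q]))
        cache[key] = val
        return val

    return a(ii, jj)


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Full numerator relationship matrix by the tabular method (dense).

    Test oracle only; quadratic memory.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            val = 0.0
            if s != UNKNOWN:
                val += 0.5 * A[j, s]
            if d != UNKNOWN:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


def mendelian_sampling_variances(ped: Pedigree) -> np.ndarray:
    """Variance d_i of the Mendelian-sampling deviation, per animal.

    A = T D T' with unit-triangular T and D = diag(d); hence
    log|A| = sum(log d) and Henderson's A-inverse rules weight by 1/d.
    """
    F = ped.inbreeding
    sire, dam = ped.sire, ped.dam
    Fs = np.where(sire != UNKNOWN, F[np.clip(sire, 0, None)], 0.0)
    Fd = np.where(dam != UNKNOWN, F[np.clip(dam, 0, None)], 0.0)
    both = (sire != UNKNOWN) & (dam != UNKNOWN)
    one = (sire != UNKNOWN) ^ (dam != UNKNOWN)
    d = np.ones(len(ped))
    d[one] = 0.75 - 0.25 * (Fs + Fd)[one]
    d[both] = 0.5 - 0.25 * (Fs + Fd)[both]
    return d


def build_a_inverse(ped: Pedigree) -> sparse.csc_matrix:
    """Sparse inverse of the numerator relationship matrix A.

    Henderson's rules with the inbreeding adjustment: for each animal i with
    Mendelian-sampling variance d_i, add w = 1/d_i to (i,i), -w/2 to the
    animal-parent cells and w/4 to the parent-parent cells.
    """
    n = len(ped)
    d = mendelian_sampling_variances(ped)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        w = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        add(i, i, w)
        for p in parents:
            add(i, p, -0.5 * w)
            add(p, i, -0.5 * w)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * w)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    Ainv.sum_duplicates()
    return Ainv


def log_det_a(ped: Pedigree) -> float:
    """log|A| from the Mendelian-sampling variances."""
    return float(np.sum(np.log(mendelian_sampling_variances(ped))))
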