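"""Pedigree handling and pedigree-based relationship matrices.

The numerator relationship matrix ``A`` holds expected additive genetic
relationships between animals given the pedigree; its diagonal is ``1 + F``
where ``F`` is the inbreeding coefficient.  Unknown parents are treated as
unrelated, non-inbred base-population animals (the model carries no genetic
groups).  ``A`` itself is built by the tabular method, ``F`` by the recursive
kinship algorithm of Meuwissen & Luo, and the sparse inverse ``A^-1`` by
Henderson's rules with inbreeding-adjusted Mendelian-sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

UNKNOWN = -1
#: Sentinel strings read as "parent unknown" in pedigree files.
UNKNOWN_TOKENS = {"", "0", ".", "NA", "na", "none", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """A renumbered, topologically ordered pedigree.

    Attributes
    ----------
    ids
        Animal identifiers in topological order (parents before offspring).
    sire, dam
        Integer indices into ``ids`` (``UNKNOWN`` = -1 for base parents).
    f
        Inbreeding coefficient per animal, in ``[0, 1)``.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    f: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if self.f is None:
            self.f = compute_inbreeding(self)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animals: Iterable) -> np.ndarray:
        """Positions of ``animals`` in the pedigree order; error on absentees."""
        missing = [str(a) for a in animals if str(a) not in self._index]
        if missing:
            raise PedigreeError(
                f"animals absent from pedigree: {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        return np.array([self._index[str(a)] for a in animals], dtype=np.int64)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))


def _normalize_parent(p) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in UNKNOWN_TOKENS else p


def renumber_pedigree(raw_records: Sequence[tuple]) -> Pedigree:
    """Topologically order raw ``(animal, sire, dam)`` triples.

    Parents that never appear as animals are registered as base-population
    founders (unknown parents themselves).  Ordering is deterministic: a
    stable Kahn traversal that releases animals in input order among peers.

    Raises
    ------
    PedigreeError
        On duplicated animal ids or on a cycle (an animal its own ancestor);
        the cycle error names the animals involved.
    """
    animals: list[str] = []
    parents: dict[str, tuple[str | None, str | None]] = {}
    for rec in raw_records:
        a, s, d = rec
        a = str(a).strip()
        if a in parents:
            raise PedigreeError(f"duplicated animal id: {a}")
        animals.append(a)
        parents[a] = (_normalize_parent(s), _normalize_parent(d))

    # Implicit founders: ids seen only as parents, in order of first mention.
    for a in list(animals):
        for p in parents[a]:
            if p is not None and p not in parents:
                animals.append(p)
                parents[p] = (None, None)

    # Kahn topological sort, releasing animals in input order among peers
    # (a heap keyed by input position), so renumbering is deterministic and
    # growing a pedigree by appending offspring preserves the prefix order.
    import heapq

    input_pos = {a: i for i, a in enumerate(animals)}
    n_deps = {a: sum(p is not None for p in parents[a]) for a in animals}
    children: dict[str, list[str]] = {a: [] for a in animals}
    for a in animals:
        for p in parents[a]:
            if p is not None:
                children[p].append(a)
    order: list[str] = []
    ready = [input_pos[a] for a in animals if n_deps[a] == 0]
    heapq.heapify(ready)
    while ready:
        a = animals[heapq.heappop(ready)]
        order.append(a)
        for c in children[a]:
            n_deps[c] -= 1
            if n_deps[c] == 0:
                heapq.heappush(ready, input_pos[c])
    if len(order) < len(animals):
        cyc = sorted(a for a in animals if n_deps[a] > 0)
        raise PedigreeError(
            f"pedigree cycle: animal(s) are their own ancestors: {', '.join(cyc)}"
        )

    idx = {a: i for i, a in enumerate(order)}
    sire = np.array(
        [idx[parents[a][0]] if parents[a][0] is not None else UNKNOWN for a in order]
    )
    dam = np.array(
        [idx[parents[a][1]] if parents[a][1] is not None else UNKNOWN for a in order]
    )
    return Pedigree(ids=order, sire=sire, dam=dam)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients via the Meuwissen & Luo recursive algorithm.

    Uses the ``A = L D L'`` decomposition implied by the pedigree:
    ``a_ii = sum_j c_j^2 d_j`` accumulated over the ancestors ``j`` of ``i``
    (coefficients ``c`` halve per meiosis) and ``F_i = a_ii - 1``.  The
    Mendelian-sampling term ``d_j`` is ``0.5 - 0.25 (F_s + F_d)`` with unknown
    parents entering as ``F = -1``.  Exact; results for full sibs are cached
    per (sire, dam) pair, which makes family-structured pedigrees cheap.
    """
    n = len(ped.ids)
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.zeros(n)
    cache: dict[tuple[int, int], float] = {}
    for i in range(n):
        s, dd = sire[i], dam[i]
        fs = f[s] if s != UNKNOWN else -1.0
        fd = f[dd] if dd != UNKNOWN else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s == UNKNOWN or dd == UNKNOWN:
            f[i] = 0.0
            continue
        key = (int(s), int(dd))
        if key in cache:
            f[i] = cache[key]
            continue
        # a_ii accumulated over ancestors of i, processed newest-first so
        # every ancestor is visited once with its total path coefficient.
        pending: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        for j in range(i, -1, -1):
            cj = pending.pop(j, None)
            if cj is None:
                continue
            a_ii += cj * cj * d[j]
            js, jd = sire[j], dam[j]
            if js != UNKNOWN:
                pending[js] = pending.get(js, 0.0) + 0.5 * cj
            if jd != UNKNOWN:
                pending[jd] = pending.get(jd, 0.0) + 0.5 * cj
        f[i] = a_ii - 1.0
        cache[key] = f[i]
    return f


def build_A(ped: Pedigree, subset: Sequence | None = None) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular method (dense).

    ``a_ij = (a_{i,sire(j)} + a_{i,dam(j)}) / 2`` for ``i < j``; diagonal
    ``1 + F``.  Row-vectorised; ~O(n^2).  With ``subset`` the full-pedigree
    matrix is restricted to those animals (labels preserved, in subset order).

    Returns the matrix and its row/column labels.
    """
    n = len(ped.ids)
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        row = np.zeros(j)
        if s != UNKNOWN:
            row += 0.5 * A[s, :j]
        if d != UNKNOWN:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[j, j] = 1.0 + 0.5 * a_sd
    if subset is None:
        return A, list(ped.ids)
    idx = ped.index_of(subset)
    return A[np.ix_(idx, idx)], [str(a) for a in subset]


def build_A_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse ``A^-1`` by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal ``i`` is
    ``0.5 - 0.25 (F_s + F_d)`` with both parents known, ``0.75 - 0.25 F_p``
    with one, and ``1`` for founders; its reciprocal ``b_i`` is scattered
    into the (animal, sire, dam) equations.
    """
    n = len(ped.ids)
    sire, dam, f = ped.sire, ped.dam, ped.f
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        known = [p for p in (s, d) if p != UNKNOWN]
        if len(known) == 2:
            m = 0.5 - 0.25 * (f[s] + f[d])
        elif len(known) == 1:
            m = 0.75 - 0.25 * f[known[0]]
        else:
            m = 1.0
        b = 1.0 / m
        add(i, i, b)
        for p in known:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in known:
            for q in known:
                add(p, q, 0.25 * b)
    return sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )


def read_pedigree_csv(path) -> Pedigree:
    """Read and renumber a pedigree CSV with columns animal, sire, dam.

    "0" or an empty field means an unknown parent.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    return renumber_pedigree(list(df[["animal", "sire", "dam"]].itertuples(index=False)))


def genotyped_blocks(
    ped: Pedigree, genotyped: Sequence
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """``(A22, A22^-1, index)`` for the genotyped subset of the pedigree.

    ``A22`` is the dense restriction of ``A`` to the genotyped animals and is
    inverted directly (the genotyped subset is small enough for that at the
    scales this package targets).
    """
    idx = ped.index_of(genotyped)
    A, _ = build_A(ped)
    A22 = A[np.ix_(idx, idx)]
    A22_inv = np.linalg.inv(A22)
    return A22, A22_inv, idx
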