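"""Pedigree handling for the animal model.

A pedigree is a list of (animal, sire, dam) triples with ``0`` marking an
unknown parent.  Internally animals are remapped to contiguous 0-based
indices in a topological order (parents before offspring), which is what
the recursive algorithms below require.  All user-facing output reports
the original identifiers.

The module provides

* :func:`read_pedigree` / :meth:`Pedigree.from_records` -- validated input,
* :meth:`Pedigree.inbreeding` -- inbreeding coefficients by the
  Meuwissen & Luo recursion on the Cholesky decomposition A = L D L',
* :meth:`Pedigree.a_matrix_tabular` -- the dense tabular-method numerator
  relationship matrix (desk-scale oracle),
* :meth:`Pedigree.a_inverse` -- the sparse inverse of A by Henderson's
  rules, accounting for inbreeding.
"""

from __future__ import annotations

import heapq
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

UNKNOWN = 0


class PedigreeError(ValueError):
    """Invalid pedigree input."""


class CycleError(PedigreeError):
    """An animal is its own ancestor."""

    def __init__(self, path):
        self.path = list(path)
        super().__init__(
            "pedigree contains a cycle: " + " -> ".join(str(a) for a in self.path)
        )


@dataclass
class SparseSymmetric:
    """Symmetric sparse matrix (full storage) with triplet export.

    Used for the numerator relationship matrix A, its inverse, and the
    mixed-model coefficient matrix.
    """

    csr: sp.csr_matrix

    @property
    def dim(self) -> int:
        return self.csr.shape[0]

    def toarray(self) -> np.ndarray:
        return self.csr.toarray()

    def triplets_upper(self):
        """Upper-triangle (row, col, value) triplets, 0-based."""
        coo = sp.triu(self.csr).tocoo()
        return coo.row, coo.col, coo.data

    def write(self, path, ids=None) -> None:
        """Write 1-based upper-triangle triplets as text ``i j value``.

        If ``ids`` is given, rows/columns are labelled with those
        identifiers instead of 1-based indices.
        """
        r, c, v = self.triplets_upper()
        with open(path, "w") as fh:
            for i, j, x in zip(r, c, v):
                a = ids[i] if ids is not None else i + 1
                b = ids[j] if ids is not None else j + 1
                fh.write(f"{a} {b} {x:.12g}\n")

    @classmethod
    def from_triplets(cls, dim, rows, cols, vals):
        """Build from triplets; entries are mirrored across the diagonal."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        vals = np.asarray(vals, dtype=float)
        off = rows != cols
        r = np.concatenate([rows, cols[off]])
        c = np.concatenate([cols, rows[off]])
        v = np.concatenate([vals, vals[off]])
        m = sp.coo_matrix((v, (r, c)), shape=(dim, dim)).tocsr()
        m.sum_duplicates()
        return cls(m)


@dataclass
class Pedigree:
    """Topologically ordered pedigree with contiguous internal indices.

    Attributes
    ----------
    ids : ndarray
        Original animal identifiers in internal order.
    sire, dam : ndarray of int
        Internal parent indices; ``-1`` for an unknown parent.  By
        construction ``sire[i] < i`` and ``dam[i] < i``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _f: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Map original identifiers to internal indices."""
        try:
            return np.array([self._index[a] for a in np.atleast_1d(animal_ids)])
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]} not in pedigree") from None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Validate and topologically order (animal, sire, dam) triples.

        Unknown parents are coded 0.  A parent that never appears as an
        animal is inserted as a founder with a warning; duplicate animal
        ids and cycles are rejected.
        """
        records = [(a, s, d) for a, s, d in records]
        seen = set()
        for a, _, _ in records:
            if a == UNKNOWN:
                raise PedigreeError("animal id 0 is reserved for unknown parents")
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a}")
            seen.add(a)
        extra = []
        for _, s, d in records:
            for p in (s, d):
                if p != UNKNOWN and p not in seen:
                    warnings.warn(
                        f"parent {p} never declared as an animal; "
                        "inserted as founder",
                        stacklevel=2,
                    )
                    seen.add(p)
                    extra.append((p, UNKNOWN, UNKNOWN))
        records = extra + records
        parents = {a: (s, d) for a, s, d in records}

        # Kahn's algorithm; ties broken by input order.
        indeg = {}
        children = {a: [] for a in parents}
        for a, s, d in records:
            known = {p for p in (s, d) if p != UNKNOWN}
            indeg[a] = len(known)
            for p in known:
                children[p].append(a)
        queue = deque(a for a, _, _ in records if indeg[a] == 0)
        order = []
        while queue:
            a = queue.popleft()
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) < len(records):
            raise CycleError(_find_cycle(parents, {a for a in indeg if indeg[a] > 0}))

        idx = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for a in order:
            s, d = parents[a]
            if s != UNKNOWN:
                sire[idx[a]] = idx[s]
            if d != UNKNOWN:
                dam[idx[a]] = idx[d]
        return cls(ids=np.asarray(order), sire=sire, dam=dam, _index=idx)

    # ------------------------------------------------------------------
    # genetics
    # ------------------------------------------------------------------

    def mendelian_d(self, f: np.ndarray | None = None) -> np.ndarray:
        """Mendelian-sampling variance ratio d per animal.

        d = 0.5 - 0.25 (f_s + f_d) with both parents known; a missing
        parent contributes 0.25 (1 + f) less, i.e. d = 0.75 - 0.25 f for
        one known parent and d = 1 for founders.
        """
        if f is None:
            f = self.inbreeding()
        d = np.ones(self.n)
        for par in (self.sire, self.dam):
            known = par >= 0
            d[known] -= 0.25 * (1.0 + f[par[known]])
        return d

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen & Luo recursion.

        For each animal the diagonal a_ii = 1 + f_i of A = L D L' is
        accumulated by tracing the ancestor list with the L-coefficients,
        re-using the Mendelian variances d_j of already-processed animals.
        Founders and animals with an unknown parent have f = 0.
        """
        if self._f is not None:
            return self._f
        n = self.n
        f = np.zeros(n)
        d = np.empty(n)
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, m = sire[i], dam[i]
            di = 1.0
            if s >= 0:
                di -= 0.25 * (1.0 + f[s])
            if m >= 0:
                di -= 0.25 * (1.0 + f[m])
            d[i] = di
            if s < 0 or m < 0:
                continue  # f stays 0
            coeff = {i: 1.0}
            heap = [-i]
            aii = 0.0
            while heap:
                j = -heapq.heappop(heap)
                lj = coeff.pop(j, None)
                if lj is None:
                    continue
                aii += lj * lj * d[j]
                for p in (sire[j], dam[j]):
                    if p >= 0:
                        if p not in coeff:
                            heapq.heappush(heap, -int(p))
                            coeff[p] = 0.0
                        coeff[p] += 0.5 * lj
            f[i] = aii - 1.0
        self._f = f
        return f

    def a_matrix_tabular(self, max_animals: int = 2000) -> SparseSymmetric:
        """Numerator relationship matrix by the tabular method (oracle).

        Dense recursion a(i,j) = 0.5 (a(j,s_i) + a(j,d_i)),
        a(i,i) = 1 + 0.5 a(s_i,d_i); intended as a desk-scale reference,
        hence the size guard.
        """
        n = self.n
        if n > max_animals:
            raise PedigreeError(
                f"tabular method is an oracle for <= {max_animals} animals; got {n}"
            )
        a = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * a[s, :i]
            if d >= 0:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
            a[i, i] = 1.0
            if s >= 0 and d >= 0:
                a[i, i] += 0.5 * a[s, d]
        return SparseSymmetric(sp.csr_matrix(a))

    def a_inverse(self, f: np.ndarray | None = None) -> SparseSymmetric:
        """Sparse inverse of A by Henderson's rules with inbreeding.

        Each animal contributes 1/d on its diagonal, -0.5/d to the
        animal x parent cells and 0.25/d to the parent x parent cells,
        where d is the Mendelian-sampling variance ratio; terms for an
        unknown parent are dropped (d absorbs the adjustment).
        """
        if f is None:
            f = self.inbreeding()
        d = self.mendelian_d(f)
        assert np.all(d > 0), "non-positive Mendelian variance on a valid pedigree"
        alpha = 1.0 / d
        n = self.n
        rows, cols, vals = [], [], []
        idx = np.arange(n)
        rows.append(idx)
        cols.append(idx)
        vals.append(alpha)
        for par in (self.sire, self.dam):
            known = par >= 0
            rows.append(idx[known])
            cols.append(par[known])
            vals.append(-0.5 * alpha[known])
            rows.append(par[known])
            cols.append(idx[known])
            vals.append(-0.5 * alpha[known])
        for pa, pb in ((self.sire, self.sire), (self.dam, self.dam),
                       (self.sire, self.dam), (self.dam, self.sire)):
            known = (pa >= 0) & (pb >= 0)
            rows.append(pa[known])
            cols.append(pb[known])
            vals.append(0.25 * alpha[known])
        m = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        m.sum_duplicates()
        return SparseSymmetric(m)

    def chol_apply(self, z: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
        """Apply L_A = (I - P)' D^{-1/2} to a vector, where A^{-1} = L_A L_A'.

        P holds 0.5 at (animal, parent) cells and D the Mendelian
        variances; used to draw pedigree-structured noise in O(n).
        """
        if d is None:
            d = self.mendelian_d()
        v = z / np.sqrt(d)
        out = v.copy()
        for par in (self.sire, self.dam):
            known = par >= 0
            np.subtract.at(out, par[known], 0.5 * v[known])
        return out

    def prune_generations(self, focal_ids, generations: int) -> "Pedigree":
        """Restrict to ancestors within ``generations`` of the focal animals.

        Utility for studies that cap pedigree depth; animals outside the
        kept set become unknown parents.
        """
        keep = set(self.index_of(focal_ids))
        frontier = set(keep)
        for _ in range(generations):
            nxt = set()
            for i in frontier:
                for p in (self.sire[i], self.dam[i]):
                    if p >= 0 and p not in keep:
                        nxt.add(int(p))
            keep |= nxt
            frontier = nxt
        keep_sorted = sorted(keep)
        sub = []
        for i in keep_sorted:
            s = self.ids[self.sire[i]] if self.sire[i] in keep else UNKNOWN
            d = self.ids[self.dam[i]] if self.dam[i] in keep else UNKNOWN
            sub.append((self.ids[i], s, d))
        return Pedigree.from_records(sub)


def _find_cycle(parents, remaining):
    """Extract one explicit cycle among the nodes Kahn could not order."""
    remaining = set(remaining)
    start = min(remaining, key=str)
    path, seen = [], {}
    node = start
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        s, d = parents[node]
        node = s if s in remaining else d
    return path[seen[node]:] + [node]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file: columns animal, sire, dam; 0 = unknown.

    Comma- or whitespace-delimited; an optional header line is skipped.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            toks = line.replace(",", " ").split()
            if len(toks) != 3:
                raise PedigreeError(f"line {lineno}: expected 3 columns, got {len(toks)}")
            try:
                a, s, d = (int(t) for t in toks)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise PedigreeError(f"line {lineno}: non-integer id in {toks}")
            records.append((a, s, d))
    if not records:
        raise PedigreeError(f"no pedigree records in {path}")
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam\n")
        for i in range(ped.n):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else UNKNOWN
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else UNKNOWN
            fh.write(f"{ped.ids[i]},{s},{d}\n")


def inbreeding(ped: Pedigree) -> np.ndarray:
    return ped.inbreeding()


def a_matrix_tabular(ped: Pedigree, max_animals: int = 2000) -> SparseSymmetric:
    return ped.a_matrix_tabular(max_animals)


def a_inverse(ped: Pedigree, f: np.ndarray | None = None) -> SparseSymmetric:
    return ped.a_inverse(f)
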