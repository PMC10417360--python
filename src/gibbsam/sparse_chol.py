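"""Sparse Cholesky factorization with a reusable symbolic analysis.

The location sampler refactorizes the mixed-model coefficient matrix at
every Gibbs iteration while its sparsity pattern never changes.  General
sparse LU routines redo their fill-reducing ordering and symbolic
analysis on each call, which dominates the runtime of a chain.  Here the
elimination tree and the pattern of the Cholesky factor L are computed
once from the pattern (up-looking scheme of Davis' CSparse), after which
each refactorization and triangular solve runs in O(flops of L) through
numba-compiled kernels.

No fill-reducing ordering is applied internally: the caller is expected
to supply the matrix in a good elimination order (the Gibbs sampler
orders breeding values youngest-animal-first with fixed effects last,
which keeps fill low on pedigree problems).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    def __init__(self, col):
        self.col = col
        super().__init__(f"matrix not positive definite at column {col}")


@njit(cache=True)
def _etree(n, uptr, urow):
    """Elimination tree of a symmetric matrix given its upper triangle."""
    parent = np.full(n, -1, np.int64)
    ancestor = np.full(n, -1, np.int64)
    for k in range(n):
        for p in range(uptr[k], uptr[k + 1]):
            i = urow[p]
            while i != -1 and i < k:
                inext = ancestor[i]
                ancestor[i] = k
                if inext == -1:
                    parent[i] = k
                i = inext
    return parent


@njit(cache=True)
def _row_patterns(n, uptr, urow, parent):
    """Pattern of each row of L (ereach), topologically ordered.

    Returns (rowptr, rowcols, colcount): row k of L has off-diagonal
    pattern rowcols[rowptr[k]:rowptr[k+1]]; colcount[j] counts entries
    of column j of L including the diagonal.
    """
    w = np.full(n, -1, np.int64)
    stack = np.empty(n, np.int64)
    out = np.empty(n, np.int64)
    # pass 1: sizes
    rowlen = np.zeros(n, np.int64)
    for k in range(n):
        w[k] = k
        cnt = 0
        for p in range(uptr[k], uptr[k + 1]):
            i = urow[p]
            if i >= k:
                continue
            while w[i] != k:
                w[i] = k
                cnt += 1
                i = parent[i]
        rowlen[k] = cnt
    rowptr = np.zeros(n + 1, np.int64)
    for k in range(n):
        rowptr[k + 1] = rowptr[k] + rowlen[k]
    rowcols = np.empty(rowptr[n], np.int64)
    colcount = np.ones(n, np.int64)  # diagonals
    # pass 2: fill patterns
    w[:] = -1
    for k in range(n):
        w[k] = k
        top = n
        for p in range(uptr[k], uptr[k + 1]):
            i = urow[p]
            if i >= k:
                continue
            ln = 0
            while w[i] != k:
                stack[ln] = i
                ln += 1
                w[i] = k
                i = parent[i]
            while ln > 0:
                ln -= 1
                top -= 1
                out[top] = stack[ln]
        base = rowptr[k]
        for t in range(n - top):
            j = out[top + t]
            rowcols[base + t] = j
            colcount[j] += 1
    return rowptr, rowcols, colcount


@njit(cache=True)
def _numeric(n, uptr, urow, udat, Cdata, rowptr, rowcols, Lp, Li, Lx, x, c):
    """Up-looking numeric factorization; returns -1 on success else the
    column where positive definiteness failed."""
    for j in range(n):
        c[j] = Lp[j] + 1  # slot 0 of each column holds the diagonal
    for i in range(n):
        x[i] = 0.0
    for k in range(n):
        d = 0.0
        for p in range(uptr[k], uptr[k + 1]):
            i = urow[p]
            v = Cdata[udat[p]]
            if i == k:
                d = v
            else:
                x[i] = v
        for t in range(rowptr[k], rowptr[k + 1]):
            i = rowcols[t]
            xi = x[i]
            x[i] = 0.0
            lki = xi / Lx[Lp[i]]
            for p in range(Lp[i] + 1, c[i]):
                x[Li[p]] -= Lx[p] * lki
            d -= lki * lki
            Li[c[i]] = k
            Lx[c[i]] = lki
            c[i] += 1
        if d <= 0.0:
            return k
        Li[Lp[k]] = k
        Lx[Lp[k]] = np.sqrt(d)
    return -1


@njit(cache=True)
def _lsolve(n, Lp, Li, Lx, b):
    for j in range(n):
        bj = b[j] / Lx[Lp[j]]
        b[j] = bj
        for p in range(Lp[j] + 1, Lp[j + 1]):
            b[Li[p]] -= Lx[p] * bj


@njit(cache=True)
def _ltsolve(n, Lp, Li, Lx, b):
    for j in range(n - 1, -1, -1):
        s = b[j]
        for p in range(Lp[j] + 1, Lp[j + 1]):
            s -= Lx[p] * b[Li[p]]
        b[j] = s / Lx[Lp[j]]


class SparseCholesky:
    """Cholesky factor of symmetric positive definite matrices sharing
    one sparsity pattern.

    Parameters
    ----------
    pattern : csc_matrix
        Full (both triangles) symmetric pattern; only the structure is
        used at construction.  Subsequent calls to :meth:`factor` pass
        the ``data`` array of a matrix with this exact structure.
    """

    def __init__(self, pattern: sp.csc_matrix):
        A = pattern.tocsc()
        A.sort_indices()
        n = A.shape[0]
        self.n = n
        cols = np.repeat(np.arange(n), np.diff(A.indptr))
        upper = A.indices <= cols
        self._uptr = np.zeros(n + 1, np.int64)
        np.add.at(self._uptr, cols[upper] + 1, 1)
        self._uptr = np.cumsum(self._uptr)
        self._urow = A.indices[upper].astype(np.int64)
        self._udat = np.nonzero(upper)[0].astype(np.int64)
        parent = _etree(n, self._uptr, self._urow)
        rowptr, rowcols, colcount = _row_patterns(n, self._uptr, self._urow, parent)
        self._rowptr, self._rowcols = rowptr, rowcols
        self._Lp = np.zeros(n + 1, np.int64)
        self._Lp[1:] = np.cumsum(colcount)
        nnz = self._Lp[n]
        self._Li = np.empty(nnz, np.int64)
        self._Lx = np.empty(nnz)
        self._x = np.empty(n)
        self._c = np.empty(n, np.int64)
        self.nnz_L = int(nnz)

    def factor(self, data: np.ndarray) -> "SparseCholesky":
        """Numeric factorization from the data array of the matrix."""
        bad = _numeric(
            self.n, self._uptr, self._urow, self._udat, data,
            self._rowptr, self._rowcols, self._Lp, self._Li, self._Lx,
            self._x, self._c,
        )
        if bad >= 0:
            raise NotPositiveDefiniteError(bad)
        return self

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve A x = b with the current numeric factor."""
        x = np.array(b, dtype=float)
        _lsolve(self.n, self._Lp, self._Li, self._Lx, x)
        _ltsolve(self.n, self._Lp, self._Li, self._Lx, x)
        return x

    def logdet(self) -> float:
        """Log-determinant of A from the current factor."""
        return 2.0 * float(np.sum(np.log(self._Lx[self._Lp[:-1]])))


def structural_union(mats) -> sp.csc_matrix:
    """Union pattern of several equally-shaped sparse matrices."""
    acc = None
    for m in mats:
        s = m.tocsc().copy()
        s.data = np.ones_like(s.data)
        acc = s if acc is None else acc + s
    acc.sort_indices()
    return acc


def embed_positions(union: sp.csc_matrix, comp: sp.spmatrix) -> np.ndarray:
    """Positions of ``comp``'s entries inside ``union.data``.

    Both matrices must be csc with sorted indices and ``comp``'s pattern
    a subset of the union's.
    """
    comp = comp.tocsc()
    comp.sort_indices()
    pos = np.empty(comp.nnz, dtype=np.int64)
    for j in range(union.shape[1]):
        lo, hi = union.indptr[j], union.indptr[j + 1]
        clo, chi = comp.indptr[j], comp.indptr[j + 1]
        if chi == clo:
            continue
        pos[clo:chi] = lo + np.searchsorted(
            union.indices[lo:hi], comp.indices[clo:chi]
        )
    return pos
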