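"""Selected inversion of sparse symmetric positive definite systems.

Exact prediction-error variances require diagonal entries (or small diagonal
blocks) of the inverse mixed-model coefficient matrix.  Forming the full
inverse is infeasible beyond a few thousand equations, but every entry of
``C^-1`` lying on the sparsity pattern of the Cholesky factor can be computed
at factorization cost with the Takahashi recurrences: if ``P C P' = L D L'``
then, writing ``Z = (P C P')^-1``,

    Z_ji = delta_ji / d_j  -  sum_{k in struct(L[:,j])} L_kj Z_ki ,   j <= i,

evaluated column by column from the last to the first.  Every entry needed on
the right-hand side lies inside the clique formed by column j's structure in
the filled graph, so the recursion closes on the factor pattern — provided the
pattern is the exact symbolic fill (no entries dropped by numerical
cancellation).  The factorization is therefore done here with an up-looking
sparse LDL' that keeps the full symbolic pattern; a fill-reducing ordering is
borrowed from SuperLU's symmetric-mode column permutation.  Small systems
fall back to a dense inverse.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

__all__ = ["SelectedInverse", "selected_inverse"]

_DENSE_CAP = 1500


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Column counts and elimination tree of the LDL' factor.

    ``(Ap, Ai)`` hold the upper triangle (diagonal included) of the permuted
    matrix in CSC order.
    """
    parent = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        parent[k] = -1
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                flag[i] = k
                i = parent[i]
    return parent, lnz


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):
    """Numeric up-looking LDL'; returns (Li, Lx, d) with sorted columns."""
    nnz = Lp[n]
    Li = np.zeros(nnz, dtype=np.int64)
    Lx = np.zeros(nnz)
    d = np.zeros(n)
    y = np.zeros(n)
    pattern = np.zeros(n, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        y[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        d[k] = y[k]
        y[k] = 0.0
        for s in range(top, n):
            i = pattern[s]
            yi = y[i]
            y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                y[Li[p]] -= Lx[p] * yi
            lki = yi / d[i]
            d[k] -= lki * yi
            Li[p2] = k
            Lx[p2] = lki
            lnz[i] += 1
        if d[k] <= 0.0:
            return Li, Lx, d * 0 - 1.0  # signal failure via negative d
    return Li, Lx, d


@njit(cache=True)
def _takahashi(indptr, indices, lx, d, c0, ztail):
    """Z on the pattern of L (strict lower triangle) plus its diagonal.

    Parameters are the CSC arrays of the unit lower factor L (diagonal
    excluded, row indices sorted ascending) and the pivot vector d.  Columns
    ``>= c0`` form the trailing block whose inverse ``ztail`` was computed
    densely; the scalar recurrence runs over the sparse leading columns and
    may read entries from either store.  Returns (zx, zdiag) aligned to
    (indptr, indices); entries with both coordinates ``>= c0`` stay in
    ``ztail`` only.
    """
    m = d.shape[0]
    zx = np.zeros(lx.shape[0])
    zdiag = np.zeros(m)
    for j in range(c0, m):
        zdiag[j] = ztail[j - c0, j - c0]
    for j in range(c0 - 1, -1, -1):
        p0, p1 = indptr[j], indptr[j + 1]
        # off-diagonal entries Z_ij for i in struct(col j), i > j
        for t in range(p1 - 1, p0 - 1, -1):
            i = indices[t]
            acc = 0.0
            for q in range(p0, p1):
                k = indices[q]
                lkj = lx[q]
                if k == i:
                    acc += lkj * zdiag[i]
                elif k >= c0 and i >= c0:
                    acc += lkj * ztail[k - c0, i - c0]
                else:
                    a, b = (k, i) if k < i else (i, k)
                    lo, hi = indptr[a], indptr[a + 1]
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if indices[mid] < b:
                            lo = mid + 1
                        else:
                            hi = mid
                    if lo < indptr[a + 1] and indices[lo] == b:
                        acc += lkj * zx[lo]
            zx[t] = -acc
        acc = 1.0 / d[j]
        for q in range(p0, p1):
            acc -= lx[q] * zx[q]
        zdiag[j] = acc
    return zx, zdiag


@njit(cache=True)
def _gather_blocks(indptr, indices, zx, zdiag, pidx, c0, ztail):
    n, k = pidx.shape
    out = np.zeros((n, k, k))
    for r in range(n):
        for a in range(k):
            pa = pidx[r, a]
            out[r, a, a] = zdiag[pa]
            for b in range(a + 1, k):
                pb = pidx[r, b]
                x, y = (pa, pb) if pa < pb else (pb, pa)
                if x >= c0:
                    val = ztail[x - c0, y - c0]
                else:
                    lo, hi = indptr[x], indptr[x + 1]
                    val = 0.0
                    while lo < hi:
                        mid = (lo + hi) // 2
                        if indices[mid] < y:
                            lo = mid + 1
                        else:
                            hi = mid
                    if lo < indptr[x + 1] and indices[lo] == y:
                        val = zx[lo]
                out[r, a, b] = val
                out[r, b, a] = val
    return out


def _fill_reducing_order(c: sp.csc_matrix) -> np.ndarray:
    """Symmetric fill-reducing permutation (original index at each position).

    Borrowed from SuperLU's MMD-on-``A'+A`` column ordering; falls back to
    reverse Cuthill-McKee if the LU call fails.
    """
    try:
        lu = spla.splu(
            c,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
        return np.argsort(lu.perm_c).astype(np.int64)
    except Exception:
        from scipy.sparse.csgraph import reverse_cuthill_mckee

        return reverse_cuthill_mckee(c, symmetric_mode=True).astype(np.int64)


class SelectedInverse:
    """Entries of ``C^-1`` on the symbolic factor pattern of ``C``.

    Use :meth:`diagonal` for scalar prediction-error variances and
    :meth:`block`/:meth:`blocks` for per-animal trait blocks.  Every
    structural nonzero of ``C`` lies on the factor pattern and is exact;
    entries outside the pattern are not available (reported as 0).
    """

    def __init__(self, c: sp.spmatrix, dense_cap: int = _DENSE_CAP,
                 order: np.ndarray | None = None):
        c = sp.csc_matrix(c)
        if (abs(c - c.T) > 1e-10 * max(1.0, abs(c).max())).nnz:
            raise ValueError("matrix must be symmetric")
        m = c.shape[0]
        self.m = m
        if m <= dense_cap:
            self._dense = np.linalg.inv(c.toarray())
            self._sparse = None
            return
        self._dense = None
        if order is None:
            order = _fill_reducing_order(c)  # position -> original index
        else:
            order = np.asarray(order, dtype=np.int64)
        iperm = np.argsort(order)  # original index -> position
        cp = c[order, :][:, order]
        upper = sp.triu(cp, format="csc")
        upper.sort_indices()
        ap = upper.indptr.astype(np.int64)
        ai = upper.indices.astype(np.int64)
        ax = upper.data
        parent, lnz = _ldl_symbolic(m, ap, ai)
        lp = np.zeros(m + 1, dtype=np.int64)
        np.cumsum(lnz, out=lp[1:])
        li, lx, d = _ldl_numeric(m, ap, ai, ax, parent, lp)
        if np.any(d <= 0):
            raise RuntimeError("matrix is not positive definite (non-positive pivot)")
        c0, ztail = self._dense_tail(m, lp, li, lx, d)
        zx, zdiag = _takahashi(lp, li, lx, d, c0, ztail)
        self._indptr = lp
        self._indices = li
        self._zx = zx
        self._zdiag = zdiag
        self._c0 = c0
        self._ztail = ztail
        self._iperm = iperm.astype(np.int64)

    @staticmethod
    def _dense_tail(m, lp, li, lx, d, max_tail=6000):
        """Dense inverse of the trailing factor block.

        Fill-reducing orderings push the densely connected equations (heavily
        used sires and their mates) to the end of the elimination sequence,
        where clique-by-clique recursion is quadratic in the clique size.
        ``(C^-1)[c0:, c0:] = L_t'^-T D_t^-1 L_t^-1`` holds for any split, so
        the trailing block is inverted with dense BLAS instead.  The split is
        chosen where trailing columns stop being mostly filled.
        """
        from scipy.linalg import solve_triangular

        colsize = np.diff(lp)
        c0 = m
        while c0 > 0 and m - c0 < max_tail:
            j = c0 - 1
            trailing = m - 1 - j
            if trailing <= 256 or colsize[j] >= 0.4 * trailing:
                c0 = j
            else:
                break
        c0 = max(c0, m - max_tail)
        nc = m - c0
        if nc == 0:
            return m, np.zeros((0, 0))
        lt = np.eye(nc)
        for j in range(c0, m):
            rows = li[lp[j]:lp[j + 1]]
            lt[rows - c0, j - c0] = lx[lp[j]:lp[j + 1]]
        linv = solve_triangular(lt, np.eye(nc), lower=True, unit_diagonal=True,
                                check_finite=False)
        ztail = linv.T @ (linv / d[c0:, None])
        return c0, ztail

    def _entry_perm(self, a: int, b: int) -> float:
        if a == b:
            return float(self._zdiag[a])
        if a > b:
            a, b = b, a
        if a >= self._c0:
            return float(self._ztail[a - self._c0, b - self._c0])
        lo, hi = self._indptr[a], self._indptr[a + 1]
        t = np.searchsorted(self._indices[lo:hi], b)
        if t < hi - lo and self._indices[lo + t] == b:
            return float(self._zx[lo + t])
        return 0.0

    def entry(self, i: int, j: int) -> float:
        """``(C^-1)_ij`` for an entry on the factor pattern."""
        if self._dense is not None:
            return float(self._dense[i, j])
        return self._entry_perm(int(self._iperm[i]), int(self._iperm[j]))

    def diagonal(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Diagonal of the inverse (optionally a subset of indices)."""
        if self._dense is not None:
            d = np.diag(self._dense)
            return d.copy() if idx is None else d[idx]
        if idx is None:
            idx = np.arange(self.m)
        return self._zdiag[self._iperm[idx]]

    def block(self, idx: np.ndarray) -> np.ndarray:
        """Dense ``k x k`` block of the inverse for index set ``idx``."""
        idx = np.asarray(idx)
        if self._dense is not None:
            return self._dense[np.ix_(idx, idx)].copy()
        return self.blocks(idx[None, :])[0]

    def blocks(self, idx: np.ndarray) -> np.ndarray:
        """Stacked ``(n, k, k)`` diagonal blocks for row-sets ``idx[n, k]``."""
        idx = np.asarray(idx)
        if self._dense is not None:
            return np.stack([self._dense[np.ix_(r, r)] for r in idx])
        p = self._iperm[idx]
        return _gather_blocks(self._indptr, self._indices, self._zx, self._zdiag,
                              p.astype(np.int64), self._c0, self._ztail)


def selected_inverse(c: sp.spmatrix, dense_cap: int = _DENSE_CAP,
                     order: np.ndarray | None = None) -> SelectedInverse:
    """Factor ``c`` and expose entries of its inverse on the factor pattern.

    ``order`` optionally supplies a symmetric fill-reducing permutation
    (original index at each eliminated position); callers that know the block
    structure of ``c`` can compute it on a collapsed graph far more cheaply
    than the generic ordering.
    """
    return SelectedInverse(c, dense_cap=dense_cap, order=order)
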