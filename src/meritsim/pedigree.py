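"""Pedigree container and additive-relationship algebra.

The numerator relationship matrix ``A`` and its sparse inverse underpin every
mixed model in this package.  Inbreeding is computed exactly with the
Meuwissen & Luo (1992) algorithm, the inverse with Henderson's rules including
inbreeding, and a dense tabular-method ``A`` is provided for small pedigrees
as an oracle and for selection-index style computations.

Conventions
-----------
Animals are stored with consecutive internal ids ``0..n-1`` in topological
order (parents before offspring).  Unknown parents are coded ``-1`` and are
treated as unrelated, non-inbred base-population founders; there are no
genetic groups.  External ids are mapped at the I/O boundary
(:mod:`meritsim.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

__all__ = [
    "Pedigree",
    "compute_inbreeding",
    "build_a_inverse",
    "relationship_matrix",
]

UNKNOWN = -1

MALE = 1
FEMALE = 2

_TABULAR_CAP = 2000


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Parameters
    ----------
    sire, dam : arrays of internal parent indices (``-1`` = unknown founder).
    sex : array with 1 = male, 2 = female.
    birth_year : integer year index per animal (base animals may be <= 0).
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    external_id: np.ndarray | None = None
    _f: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        n = self.sire.shape[0]
        if not (self.dam.shape[0] == self.sex.shape[0] == self.birth_year.shape[0] == n):
            raise ValueError("pedigree arrays must have equal length")
        if self.external_id is None:
            self.external_id = np.arange(1, n + 1, dtype=np.int64)
        self.validate()

    @property
    def n(self) -> int:
        return int(self.sire.shape[0])

    def validate(self) -> None:
        """Check ordering, parent sexes and id ranges; raise on violation."""
        idx = np.arange(self.n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.where((par != UNKNOWN) & ((par < 0) | (par >= self.n)))[0]
            if bad.size:
                raise ValueError(f"animal {bad[0]}: {name} id {par[bad[0]]} not in pedigree")
            # topological order also rules out an animal being its own ancestor
            cyc = np.where((par != UNKNOWN) & (par >= idx))[0]
            if cyc.size:
                raise ValueError(
                    f"pedigree not topologically ordered (possible cycle) at animal "
                    f"{cyc[0]}: {name} {par[cyc[0]]} does not precede it"
                )
        s = self.sire[self.sire != UNKNOWN]
        if s.size and np.any(self.sex[s] != MALE):
            off = int(np.where(self.sire != UNKNOWN)[0][np.where(self.sex[s] != MALE)[0][0]])
            raise ValueError(f"sire of animal {off} is not male")
        d = self.dam[self.dam != UNKNOWN]
        if d.size and np.any(self.sex[d] != FEMALE):
            off = int(np.where(self.dam != UNKNOWN)[0][np.where(self.sex[d] != FEMALE)[0][0]])
            raise ValueError(f"dam of animal {off} is not female")

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient ``F`` (cached)."""
        if self._f is None:
            self._f = compute_inbreeding(self)
        return self._f

    def progeny_counts(self) -> np.ndarray:
        """Number of offspring recorded in this pedigree per animal."""
        cnt = np.zeros(self.n, dtype=np.int64)
        for par in (self.sire, self.dam):
            p = par[par != UNKNOWN]
            np.add.at(cnt, p, 1)
        return cnt


@njit(cache=True)
def _meuwissen_luo_full(sire: np.ndarray, dam: np.ndarray, f: np.ndarray,
                        start: int) -> np.ndarray:
    """Meuwissen–Luo: F_i from A_ii = sum_j l_ij^2 d_j.

    Entries of ``f`` before ``start`` are taken as already computed, which
    makes year-by-year extension of a growing pedigree linear overall.
    """
    n = sire.shape[0]
    dcoef = np.zeros(n)
    lrow = np.zeros(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        fs = f[s] if s >= 0 else 0.0
        fd = f[dm] if dm >= 0 else 0.0
        if s >= 0 and dm >= 0:
            dcoef[i] = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or dm >= 0:
            dcoef[i] = 0.75 - 0.25 * (fs + fd)
        else:
            dcoef[i] = 1.0
        if i < start:
            continue
        if s < 0 or dm < 0:
            f[i] = 0.0
            continue
        lrow[: i + 1] = 0.0
        lrow[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lij = lrow[j]
            if lij == 0.0:
                continue
            aii += lij * lij * dcoef[j]
            if sire[j] >= 0:
                lrow[sire[j]] += 0.5 * lij
            if dam[j] >= 0:
                lrow[dam[j]] += 0.5 * lij
        f[i] = aii - 1.0
    return f


def compute_inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Exact inbreeding coefficients ``F`` for a topologically ordered pedigree.

    Founders have ``F = 0``; for all animals ``A_ii = 1 + F_i`` of the tabular
    relationship matrix.
    """
    f = np.zeros(pedigree.n)
    return _meuwissen_luo_full(pedigree.sire, pedigree.dam, f, 0)


def extend_inbreeding(sire: np.ndarray, dam: np.ndarray, f_prev: np.ndarray) -> np.ndarray:
    """Inbreeding of a grown pedigree, reusing coefficients already computed."""
    f = np.zeros(sire.shape[0])
    f[: f_prev.shape[0]] = f_prev
    return _meuwissen_luo_full(np.asarray(sire, dtype=np.int64),
                               np.asarray(dam, dtype=np.int64), f, f_prev.shape[0])


def build_a_inverse(pedigree: Pedigree, f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix.

    Henderson's rules with inbreeding: for each animal with Mendelian-sampling
    variance coefficient ``d_i`` the triple (animal, sire, dam) contributes at
    most nine entries, with coefficients ``1/d_i`` times
    (1, -.5, -.5; -.5, .25, .25; -.5, .25, .25) on (i, s, d) x (i, s, d).

    The result is symmetric positive definite.
    """
    if f is None:
        f = pedigree.inbreeding
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    fs = np.where(sire >= 0, f[np.clip(sire, 0, None)], 0.0)
    fd = np.where(dam >= 0, f[np.clip(dam, 0, None)], 0.0)
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    d = np.where(both, 0.5 - 0.25 * (fs + fd), np.where(one, 0.75 - 0.25 * (fs + fd), 1.0))
    inv_d = 1.0 / d

    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [inv_d.copy()]

    for par, other in ((sire, dam), (dam, sire)):
        has = par >= 0
        i = np.where(has)[0]
        p = par[i]
        # animal-parent cross terms (both triangles)
        rows += [i, p]
        cols += [p, i]
        vals += [-0.5 * inv_d[i]] * 2
        # parent-parent diagonal quarter
        rows += [p]
        cols += [p]
        vals += [0.25 * inv_d[i]]
    # sire-dam cross terms where both known
    i = np.where(both)[0]
    rows += [sire[i], dam[i]]
    cols += [dam[i], sire[i]]
    vals += [0.25 * inv_d[i]] * 2

    ai = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    ai.sum_duplicates()
    return ai


def relationship_matrix(pedigree: Pedigree, cap: int = _TABULAR_CAP) -> np.ndarray:
    """Dense tabular-method numerator relationship matrix (small pedigrees).

    ``A_ij`` is the additive relationship, ``A_ii = 1 + F_i``.  Intended as a
    test oracle and for selection-index style computations; refuses pedigrees
    larger than ``cap`` animals.
    """
    n = pedigree.n
    if n > cap:
        raise ValueError(f"pedigree has {n} animals, exceeding the tabular cap {cap}")
    a = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        asd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
    return a
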