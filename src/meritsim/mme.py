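"""Henderson's mixed model equations for univariate and multitrait animal models.

The linear model is ``y = Xb + Za + e`` with one fixed factor per trait
(herd-year, birth-year, or an overall mean), a random animal effect with
covariance ``G0 (x) A`` and residual covariance built from ``R0`` restricted
to each animal's observed traits.  Per-record weights ``w`` scale residual
precision: an animal's residual covariance is
``diag(1/sqrt(w)) R0[S,S] diag(1/sqrt(w))`` over its observed trait set
``S``, which in the univariate case reduces to ``sigma_e^2 / w``.

The coefficient matrix

    [ X'R⁻¹X   X'R⁻¹Z                    ]
    [ Z'R⁻¹X   Z'R⁻¹Z + A⁻¹ (x) G0⁻¹     ]

is assembled sparse; systems are solved either by sparse factorization or by
Jacobi-preconditioned conjugate gradients.  Reliabilities come from exact
prediction-error variances: ``r²_it = 1 - PEV_it / (sigma²_a,t (1 + F_i))``
with PEV taken from the inverse coefficient matrix via selected inversion.

Every fixed factor choice partitions the records it applies to (each record
belongs to exactly one level), so ``X`` has full column rank and no explicit
constraint is needed; one useful consequence is that precision-weighted
residuals sum to zero within every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from meritsim.params import GeneticParams
from meritsim.pedigree import Pedigree, build_a_inverse
from meritsim.sparse_inverse import SelectedInverse, _fill_reducing_order, selected_inverse

__all__ = [
    "RecordSet",
    "ModelSpec",
    "MMESystem",
    "EvalResult",
    "build_mme",
    "solve_mme",
    "pev_reliabilities",
    "pev_blocks",
    "univariate_evaluation",
    "multitrait_evaluation",
]


@dataclass
class RecordSet:
    """Phenotype or pseudo-phenotype records, one row per animal x trait.

    ``animal`` holds internal pedigree indices, ``trait`` global trait
    indices, ``herd`` and ``year`` the contemporary-group coordinates (used
    when the model's fixed factor is herd-year), ``weight`` the per-record
    precision multiplier.
    """

    animal: np.ndarray
    trait: np.ndarray
    value: np.ndarray
    herd: np.ndarray | None = None
    year: np.ndarray | None = None
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.trait = np.asarray(self.trait, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        n = self.animal.shape[0]
        if self.weight is None:
            self.weight = np.ones(n)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        for nm in ("herd", "year"):
            v = getattr(self, nm)
            if v is not None:
                setattr(self, nm, np.asarray(v, dtype=np.int64))
        if np.any(self.weight <= 0):
            raise ValueError("record weights must be positive (drop zero-weight records)")

    @property
    def n(self) -> int:
        return int(self.animal.shape[0])

    def subset(self, mask: np.ndarray) -> "RecordSet":
        return RecordSet(
            self.animal[mask],
            self.trait[mask],
            self.value[mask],
            None if self.herd is None else self.herd[mask],
            None if self.year is None else self.year[mask],
            self.weight[mask],
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which traits, which fixed factor, which variance components."""

    params: GeneticParams
    traits: tuple[int, ...] = (0, 1, 2, 3, 4)
    fixed: str = "herd_year"  # "herd_year" | "birth_year" | "mean"

    def __post_init__(self) -> None:
        if self.fixed not in ("herd_year", "birth_year", "mean"):
            raise ValueError("fixed must be herd_year, birth_year or mean")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("duplicate traits")

    @property
    def k(self) -> int:
        return len(self.traits)


@dataclass
class MMESystem:
    """Assembled sparse mixed-model system plus its index bookkeeping."""

    c: sp.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    fixed_keys: np.ndarray  # (n_fixed, 2): local trait, level code
    spec: ModelSpec
    pedigree: Pedigree
    records: RecordSet
    order: np.ndarray | None = None  # fill-reducing permutation hint
    _factor: object = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return int(self.c.shape[0])

    @property
    def k(self) -> int:
        return self.spec.k

    def animal_eq(self, animal: np.ndarray, tloc: np.ndarray) -> np.ndarray:
        """Equation index of (animal, local trait)."""
        return self.n_fixed + np.asarray(animal) * self.k + np.asarray(tloc)

    def animal_eq_blocks(self) -> np.ndarray:
        """(n, k) equation indices of every animal's trait block."""
        n = self.pedigree.n
        return self.n_fixed + np.arange(n)[:, None] * self.k + np.arange(self.k)[None, :]


@dataclass
class EvalResult:
    """Solutions of one evaluation: EBV, fixed effects, and reliabilities."""

    ebv: np.ndarray  # (n_animals, k)
    fixed: np.ndarray  # (n_fixed,)
    fixed_keys: np.ndarray
    traits: tuple[int, ...]
    rel: np.ndarray | None = None  # (n_animals, k)
    pev: np.ndarray | None = None  # (n_animals, k, k) when requested

    def fixed_solution_map(self) -> dict[tuple[int, int], float]:
        """(local trait, level code) -> estimate."""
        return {
            (int(t), int(lv)): float(v)
            for (t, lv), v in zip(self.fixed_keys, self.fixed)
        }


def _fixed_level_codes(records: RecordSet, pedigree: Pedigree, spec: ModelSpec,
                       tloc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-record fixed-level index and the (tloc, code) key table."""
    if spec.fixed == "herd_year":
        if records.herd is None or records.year is None:
            raise ValueError("herd_year model requires herd and year columns")
        raw = records.herd * 10000 + records.year
    elif spec.fixed == "birth_year":
        raw = pedigree.birth_year[records.animal]
    else:
        raw = np.zeros(records.n, dtype=np.int64)
    key = tloc * 100000000 + (raw - raw.min())
    uniq, level = np.unique(key, return_inverse=True)
    keys = np.stack([uniq // 100000000, uniq % 100000000 + raw.min()], axis=1)
    return level, keys


def build_mme(records: RecordSet, pedigree: Pedigree, spec: ModelSpec,
              a_inv: sp.spmatrix | None = None) -> MMESystem:
    """Assemble the sparse mixed-model equations.

    Residual precision couples each animal's observed traits through the
    inverse of the corresponding ``R0`` submatrix (missing traits are treated
    as missing at random); the additive part is ``A⁻¹ (x) G0⁻¹`` over the
    model's traits.
    """
    params = spec.params
    k = spec.k
    gl = np.asarray(spec.traits)
    glob2loc = {int(g): i for i, g in enumerate(gl)}
    if np.any(records.animal < 0) or np.any(records.animal >= pedigree.n):
        bad = records.animal[(records.animal < 0) | (records.animal >= pedigree.n)][0]
        raise ValueError(f"record references unknown animal index {bad}")
    try:
        tloc = np.array([glob2loc[int(t)] for t in records.trait], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - guarded input
        raise ValueError(f"record trait {e} not in model traits {spec.traits}") from e

    level, fixed_keys = _fixed_level_codes(records, pedigree, spec, tloc)
    n_fixed = fixed_keys.shape[0]
    n = pedigree.n
    m = n_fixed + n * k

    r0 = params.r0[np.ix_(gl, gl)]
    g0 = params.g0[np.ix_(gl, gl)]
    g0_inv = np.linalg.inv(g0)

    # sort records by animal, then local trait, and group by trait pattern
    srt = np.lexsort((tloc, records.animal))
    a_s, t_s = records.animal[srt], tloc[srt]
    v_s, l_s, w_s = records.value[srt], level[srt], records.weight[srt]
    # duplicate animal x trait records are not allowed
    if np.any((np.diff(a_s) == 0) & (np.diff(t_s) == 0)):
        raise ValueError("more than one record per animal and trait")
    ua, starts = np.unique(a_s, return_index=True)
    counts = np.diff(np.append(starts, a_s.shape[0]))
    masks = np.zeros(ua.shape[0], dtype=np.int64)
    np.add.at(masks, np.repeat(np.arange(ua.shape[0]), counts), 1 << t_s)

    rows, cols, vals = [], [], []
    rhs = np.zeros(m)

    for mask in np.unique(masks):
        g_sel = np.where(masks == mask)[0]
        s = bin(int(mask)).count("1")
        traits_in = np.array([t for t in range(k) if mask >> t & 1])
        q = np.linalg.inv(r0[np.ix_(traits_in, traits_in)])
        # per-animal record slices are contiguous and trait-sorted
        idx = (starts[g_sel][:, None] + np.arange(s)[None, :]).ravel()
        ng = g_sel.shape[0]
        y_g = v_s[idx].reshape(ng, s)
        lvl_g = l_s[idx].reshape(ng, s)
        w_g = w_s[idx].reshape(ng, s)
        sw = np.sqrt(w_g)
        p_g = q[None, :, :] * sw[:, :, None] * sw[:, None, :]  # (ng, s, s)
        aeq = n_fixed + ua[g_sel][:, None] * k + traits_in[None, :]  # (ng, s)

        # Z'R⁻¹Z animal blocks
        rows.append(np.repeat(aeq, s, axis=1).ravel())
        cols.append(np.tile(aeq, (1, s)).ravel())
        vals.append(p_g.ravel())
        # X'R⁻¹X fixed blocks
        rows.append(np.repeat(lvl_g, s, axis=1).ravel())
        cols.append(np.tile(lvl_g, (1, s)).ravel())
        vals.append(p_g.ravel())
        # cross blocks, both triangles
        rows.append(np.repeat(lvl_g, s, axis=1).ravel())
        cols.append(np.tile(aeq, (1, s)).ravel())
        vals.append(p_g.ravel())
        rows.append(np.repeat(aeq, s, axis=1).ravel())
        cols.append(np.tile(lvl_g, (1, s)).ravel())
        vals.append(p_g.ravel())
        # right-hand side
        py = np.einsum("gst,gt->gs", p_g, y_g)
        np.add.at(rhs, aeq.ravel(), py.ravel())
        np.add.at(rhs, lvl_g.ravel(), py.ravel())

    if a_inv is None:
        a_inv = build_a_inverse(pedigree)
    pedpart = sp.kron(sp.coo_matrix(a_inv), sp.coo_matrix(g0_inv), format="coo")

    rows = np.concatenate(rows + [pedpart.row + n_fixed])
    cols = np.concatenate(cols + [pedpart.col + n_fixed])
    vals = np.concatenate(vals + [pedpart.data])
    c = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsc()
    c.sum_duplicates()

    order = _block_order(a_inv, records, level, n_fixed, n, k)
    return MMESystem(c, rhs, n_fixed, fixed_keys, spec, pedigree, records, order)


def _block_order(a_inv: sp.spmatrix, records: RecordSet, level: np.ndarray,
                 n_fixed: int, n: int, k: int) -> np.ndarray:
    """Fill-reducing ordering computed on the collapsed animal graph.

    One node per animal (its k trait equations are interchangeable) plus one
    per fixed level; the ordering of the collapsed graph is expanded to
    equation indices.  This is much cheaper than ordering the full system and
    keeps each animal's trait block contiguous, which the selected inversion
    exploits.
    """
    nn = n_fixed + n
    ai = sp.coo_matrix(a_inv)
    r = [ai.row + n_fixed, records.animal + n_fixed, level]
    c = [ai.col + n_fixed, level, records.animal + n_fixed]
    v = [np.ones_like(ai.data)] * 1 + [np.ones(records.n)] * 2
    g = sp.coo_matrix((np.concatenate(v), (np.concatenate(r), np.concatenate(c))),
                      shape=(nn, nn)).tocsc()
    g = g + g.T + sp.eye(nn) * (2.0 * g.shape[0])
    node_order = _fill_reducing_order(sp.csc_matrix(g))
    out = np.empty(n_fixed + n * k, dtype=np.int64)
    pos = 0
    for node in node_order:
        if node < n_fixed:
            out[pos] = node
            pos += 1
        else:
            a = node - n_fixed
            out[pos:pos + k] = n_fixed + a * k + np.arange(k)
            pos += k
    return out


def solve_mme(system: MMESystem, tol: float = 1e-10, method: str = "auto",
              x0: np.ndarray | None = None, max_iter: int = 5000,
              direct_cap: int = 300000) -> EvalResult:
    """Solve the assembled system to relative residual ``tol``.

    ``method`` may be ``direct`` (sparse LU), ``pcg`` (Jacobi-preconditioned
    conjugate gradients) or ``auto`` (direct below ``direct_cap`` equations).
    Raises on non-convergence, reporting the residual history.
    """
    m = system.m
    if method == "auto":
        method = "direct" if m <= direct_cap else "pcg"
    if method == "direct":
        if system._factor is None:
            if system.order is not None:
                # factor under the precomputed fill-reducing block order;
                # SuperLU's own column ordering is poor on these systems
                perm = system.order
                cp = system.c[perm, :][:, perm].tocsc()
                lu = spla.splu(cp, permc_spec="NATURAL", diag_pivot_thresh=0.0,
                               options={"SymmetricMode": True})
                system._factor = (lu, perm, np.argsort(perm))
            else:
                system._factor = (spla.splu(system.c), None, None)
        lu, perm, iperm = system._factor
        if perm is None:
            x = lu.solve(system.rhs)
        else:
            x = lu.solve(system.rhs[perm])[iperm]
    elif method == "pcg":
        dinv = 1.0 / system.c.diagonal()
        pre = spla.LinearOperator((m, m), matvec=lambda r: dinv * r)
        hist: list[float] = []
        x, info = spla.cg(system.c, system.rhs, x0=x0, rtol=tol, atol=0.0,
                          maxiter=max_iter, M=pre,
                          callback=lambda xk: hist.append(1.0))
        if info != 0:
            res = np.linalg.norm(system.rhs - system.c @ x)
            raise RuntimeError(
                f"conjugate gradients did not converge in {len(hist)} iterations "
                f"(residual {res:.3e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    rel_res = np.linalg.norm(system.rhs - system.c @ x) / max(np.linalg.norm(system.rhs), 1e-300)
    if rel_res > max(tol * 50, 1e-8):
        raise RuntimeError(f"solution residual {rel_res:.3e} exceeds tolerance")
    n, k = system.pedigree.n, system.k
    ebv = x[system.n_fixed:].reshape(n, k)
    return EvalResult(ebv, x[:system.n_fixed], system.fixed_keys, system.spec.traits)


def _selected_inverse_of(system: MMESystem, dense_cap: int = 1500) -> SelectedInverse:
    return selected_inverse(system.c, dense_cap=dense_cap, order=system.order)


def pev_reliabilities(system: MMESystem, si: SelectedInverse | None = None) -> np.ndarray:
    """Exact per-animal, per-trait reliabilities from the inverse diagonal.

    ``r²_it = 1 - PEV_it / (sigma²_a,t (1 + F_i))``; animals with no
    information and unknown parents get exactly 0.
    """
    if si is None:
        si = _selected_inverse_of(system)
    eq = system.animal_eq_blocks()
    pev = si.diagonal(eq.ravel()).reshape(eq.shape)
    sa2 = system.spec.params.sigma_a2[list(system.spec.traits)]
    denom = sa2[None, :] * (1.0 + system.pedigree.inbreeding)[:, None]
    rel = 1.0 - pev / denom
    return np.clip(rel, 0.0, 1.0 - 1e-12)


def pev_blocks(system: MMESystem, si: SelectedInverse | None = None) -> np.ndarray:
    """Exact (n, k, k) prediction-error covariance blocks per animal."""
    if si is None:
        si = _selected_inverse_of(system)
    return si.blocks(system.animal_eq_blocks())


def univariate_evaluation(records: RecordSet, pedigree: Pedigree, trait: int,
                          params: GeneticParams, fixed: str = "herd_year",
                          a_inv: sp.spmatrix | None = None,
                          reliabilities: bool = True,
                          tol: float = 1e-10) -> EvalResult:
    """Single-trait animal model: ``G = A sigma²_a``, ``R = I sigma²_e / w``."""
    mask = records.trait == trait
    spec = ModelSpec(params=params, traits=(trait,), fixed=fixed)
    system = build_mme(records.subset(mask), pedigree, spec, a_inv=a_inv)
    result = solve_mme(system, tol=tol)
    if reliabilities:
        result.rel = pev_reliabilities(system)
    result._system = system  # kept for downstream pseudo-record machinery
    return result


def multitrait_evaluation(records: RecordSet, pedigree: Pedigree,
                          params: GeneticParams, fixed: str = "herd_year",
                          traits: tuple[int, ...] = (0, 1, 2, 3, 4),
                          a_inv: sp.spmatrix | None = None,
                          reliabilities: bool = True,
                          pev: bool = False,
                          tol: float = 1e-10) -> EvalResult:
    """Joint animal model over ``traits`` with full ``G0``/``R0`` structure."""
    spec = ModelSpec(params=params, traits=tuple(traits), fixed=fixed)
    system = build_mme(records, pedigree, spec, a_inv=a_inv)
    result = solve_mme(system, tol=tol)
    if reliabilities or pev:
        si = _selected_inverse_of(system)
        result.rel = pev_reliabilities(system, si)
        if pev:
            result.pev = pev_blocks(system, si)
    result._system = system
    return result
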