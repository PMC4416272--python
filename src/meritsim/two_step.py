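"""Approximate multitrait two-step machinery: yield deviations and de-regression.

Routine evaluations often cannot fit one multitrait model to all phenotypes.
The two-step workaround first runs univariate evaluations per trait, then
condenses each animal's data into one weighted pseudo-record per trait —
either a *yield deviation* (the phenotype minus estimated fixed effects) or a
*de-regressed EBV* (the pseudo-observation that, fed back through a weighted
mean-only animal model, reproduces the univariate EBV) — and finally runs a
5-trait animal model on the pseudo-records with a birth-year fixed effect.

Weights
-------
* EOP (effective own performance), the second-step record weight:
  ``EOP = alpha / (1 - r²) - alpha`` with ``alpha = sigma²_e / sigma²_a`` and
  ``r²`` the reliability of the animal's own performance.  With a single own
  record ``r² = h²`` and the weight is exactly 1.
* EDC (effective daughter contribution), the de-regression weight:
  ``EDC = kappa r²/(1 - r²)``, ``kappa = (4 - h²)/h²``, applied to the
  animal's own-information reliability (full reliability with the
  parent-average contribution removed), so that progeny information — which
  is exactly what a proven sire's EBV carries — is expressed in daughter
  equivalents.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from meritsim.mme import (
    EvalResult,
    ModelSpec,
    RecordSet,
    build_mme,
    pev_reliabilities,
    solve_mme,
)
from meritsim.params import GeneticParams
from meritsim.pedigree import Pedigree, build_a_inverse

__all__ = [
    "yield_deviations",
    "eop",
    "own_performance_reliability",
    "edc",
    "own_information_reliability",
    "deregress",
    "second_step_multitrait",
]


def yield_deviations(records: RecordSet, fixed_solutions: dict[int, dict[int, float]]
                     ) -> RecordSet:
    """Pseudo-records ``y* = y - Xb`` from univariate herd-year estimates.

    ``fixed_solutions`` maps trait -> {herd-year level code -> estimate}, as
    produced by the univariate first step; a record whose level has no
    estimate is an error.  Weights are left at 1 (they are set by the caller
    from EOP).
    """
    if records.herd is None or records.year is None:
        raise ValueError("yield deviations require herd-year structured records")
    yd = np.empty(records.n)
    for r in range(records.n):
        t = int(records.trait[r])
        lv = int(records.herd[r]) * 10000 + int(records.year[r])
        try:
            b = fixed_solutions[t][lv]
        except KeyError:
            raise ValueError(
                f"no herd-year solution for trait {t}, level {lv}"
            ) from None
        yd[r] = records.value[r] - b
    return RecordSet(records.animal.copy(), records.trait.copy(), yd,
                     records.herd.copy(), records.year.copy())


def fixed_solution_levels(result: EvalResult) -> dict[int, float]:
    """Herd-year level code -> estimate for a univariate result."""
    return {int(lv): float(v) for (_, lv), v in zip(result.fixed_keys, result.fixed)}


def eop(alpha: float, r2: np.ndarray | float) -> np.ndarray | float:
    """Effective own performance: ``alpha/(1-r²) - alpha``.

    ``r²`` is the reliability of the animal's own performance; a single own
    record (``r² = h²``) yields exactly 1.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 >= 1.0) or np.any(r2 < 0.0):
        raise ValueError("own-performance reliability must lie in [0, 1)")
    if alpha <= 0:
        raise ValueError("variance ratio alpha must be positive")
    out = alpha / (1.0 - r2) - alpha
    return float(out) if out.ndim == 0 else out


def own_performance_reliability(n_records: np.ndarray | int, h2: float,
                                repeatability: float | None = None) -> np.ndarray:
    """Reliability of the mean of ``n`` own records: ``n h² / (1 + (n-1) t)``.

    With no permanent-environment effect the repeatability ``t`` defaults to
    ``h²``; with a single record this is ``h²`` itself.
    """
    t = h2 if repeatability is None else repeatability
    n = np.asarray(n_records, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(n > 0, n * h2 / (1.0 + (n - 1.0) * t), 0.0)
    return r2


def edc(r2: np.ndarray | float, h2: float) -> np.ndarray | float:
    """Effective daughter contributions: ``(4-h²)/h² * r²/(1-r²)``."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 >= 1.0) or np.any(r2 < 0.0):
        raise ValueError("reliability must lie in [0, 1)")
    kappa = (4.0 - h2) / h2
    out = kappa * r2 / (1.0 - r2)
    return float(out) if out.ndim == 0 else out


def own_information_reliability(rel: np.ndarray, rel_sire: np.ndarray,
                                rel_dam: np.ndarray, h2: float) -> np.ndarray:
    """Reliability from an animal's own information (parent average removed).

    Standard daughter-equivalent decomposition: total and parent-average
    reliabilities are converted to record-equivalents
    ``kappa r²/(1-r²)``, subtracted, and converted back; the parent-average
    reliability is ``(r²_s + r²_d)/4``.
    """
    kappa = (4.0 - h2) / h2
    de_tot = kappa * rel / (1.0 - rel)
    rel_pa = 0.25 * (rel_sire + rel_dam)
    de_pa = kappa * rel_pa / (1.0 - rel_pa)
    de_own = np.maximum(de_tot - de_pa, 0.0)
    return de_own / (de_own + kappa)


def deregress(ebv: np.ndarray, weights: np.ndarray, pedigree: Pedigree,
              sigma_a2: float, sigma_e2: float,
              a_inv: sp.spmatrix | None = None,
              verify_tol: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Univariate de-regression of EBV into weighted pseudo-observations.

    Solves for pseudo-records ``y`` and mean ``mu`` such that a weighted
    univariate animal model (general mean as the only fixed effect, record
    weights ``w``) applied to ``y`` reproduces the input EBV.  From the
    mixed-model identity,

        (w_i/sigma²_e)(y_i - mu) = [(W/sigma²_e + A⁻¹/sigma²_a) u]_i

    for every weighted animal.  When the input EBV come from a model whose
    fixed factor partitions the records (always the case here), zero-weight
    animals satisfy their equations automatically and the round trip is
    exact up to solver precision.

    Returns ``(values, animal_indices, mu)`` for animals with positive
    weight; if ``verify_tol`` is given, re-runs the evaluation model on the
    pseudo-records and raises when the maximum round-trip EBV discrepancy
    exceeds it.
    """
    ebv = np.asarray(ebv, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ebv.shape[0] != pedigree.n or weights.shape[0] != pedigree.n:
        raise ValueError("ebv and weights must cover the whole pedigree")
    if a_inv is None:
        a_inv = build_a_inverse(pedigree)
    k_u = weights * ebv / sigma_e2 + (a_inv @ ebv) / sigma_a2
    idx = np.where(weights > 0)[0]
    wsum = weights[idx].sum()
    mu = float(weights[idx] @ ebv[idx] / wsum) if wsum > 0 else 0.0
    y = mu + sigma_e2 / weights[idx] * k_u[idx]
    if verify_tol is not None:
        resid = _roundtrip_residual(y, idx, weights, pedigree, sigma_a2, sigma_e2,
                                    a_inv, ebv)
        if resid > verify_tol:
            raise RuntimeError(
                f"de-regression round trip residual {resid:.3e} exceeds {verify_tol:.1e}"
            )
    return y, idx, mu


def _roundtrip_residual(y, idx, weights, pedigree, sigma_a2, sigma_e2, a_inv, ebv):
    """Max |EBV' - EBV| after re-evaluating the pseudo-records."""
    params = _scalar_params(sigma_a2, sigma_e2)
    rs = RecordSet(idx, np.zeros_like(idx), y, weight=weights[idx])
    spec = ModelSpec(params=params, traits=(0,), fixed="mean")
    system = build_mme(rs, pedigree, spec, a_inv=a_inv)
    res = solve_mme(system, tol=1e-12)
    return float(np.abs(res.ebv[:, 0] - ebv).max())


def _scalar_params(sigma_a2: float, sigma_e2: float) -> GeneticParams:
    """One-trait parameter shim used by the round-trip verification."""
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    return GeneticParams(
        trait_names=("X",),
        h2=np.array([h2]),
        genetic_corr=np.eye(1),
        genetic_sd=np.array([np.sqrt(sigma_a2)]),
        econ_weights=np.array([100.0]),
        residual_fraction=0.0,
    )


def second_step_multitrait(pseudo: RecordSet, pedigree: Pedigree,
                           params: GeneticParams,
                           a_inv: sp.spmatrix | None = None,
                           reliabilities: bool = False,
                           tol: float = 1e-10) -> EvalResult:
    """5-trait animal model on pseudo-records with a birth-year fixed effect.

    Record weights (EOP) scale the residual precision built from ``R0``
    exactly as in the reference multitrait model; the birth-year effect
    absorbs over- or under-estimated genetic trend in the pseudo-records.
    """
    spec = ModelSpec(params=params, traits=tuple(range(params.n_traits)),
                     fixed="birth_year")
    system = build_mme(pseudo, pedigree, spec, a_inv=a_inv)
    result = solve_mme(system, tol=tol)
    if reliabilities:
        from meritsim.mme import _selected_inverse_of, pev_blocks

        si = _selected_inverse_of(system)
        result.rel = pev_reliabilities(system, si)
        result.pev = pev_blocks(system, si)
    result._system = system
    return result
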