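"""Total merit index construction: aggregation, selection index, standardization.

The aggregate genotype is ``T = sum_t (omega_t / sigma_a,t) a_t`` with
relative economic weights ``omega`` expressed per additive genetic standard
deviation.  For multitrait evaluations the TMI is simply the weighted EBV
sum; the selection-index method instead combines univariate EBV ``u`` with
per-animal weights ``b = P*⁻¹ G* v`` where

    P*_ij = r_g,ij r²_i r²_j sigma_a,i sigma_a,j   (i != j),
    P*_ii = r²_i sigma²_a,i,
    G*_ij = r²_i r_g,ij sigma_a,i sigma_a,j,

i.e. residual correlations between the univariate EBV are neglected.  The
variant using accuracies (``r_i r_j`` instead of ``r²_i r²_j``) is available
behind a flag for sensitivity analysis.

Indexes are reported raw (aggregate-genotype units) and standardized to mean
100 in a base cohort (birth years 18-22) with an additive genetic standard
deviation of 12.
"""

from __future__ import annotations

import numpy as np

from meritsim.params import GeneticParams

__all__ = [
    "tmi_from_ebv",
    "si_covariance",
    "si_index",
    "multitrait_tmi_reliability",
    "standardize",
]


def tmi_from_ebv(ebv: np.ndarray, params: GeneticParams) -> np.ndarray:
    """Raw TMI per animal: ``sum_t (omega_t/sigma_a,t) ebv_t``."""
    ebv = np.atleast_2d(np.asarray(ebv, dtype=float))
    if ebv.shape[1] != params.n_traits:
        raise ValueError(
            f"expected EBV for all {params.n_traits} traits, got {ebv.shape[1]}"
        )
    return ebv @ params.index_weights


def si_covariance(r_g: float, r2_i: float, r2_j: float,
                  sd_i: float = 1.0, sd_j: float = 1.0) -> float:
    """Covariance between univariate EBV of two traits (residuals neglected)."""
    return r_g * r2_i * r2_j * sd_i * sd_j


def _si_matrices(rel: np.ndarray, params: GeneticParams,
                 use_accuracy: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal P* (EBV covariance) and G* (EBV-TBV covariance) stacks."""
    sd = params.genetic_sd
    corr = params.genetic_corr
    n, k = rel.shape
    w = np.sqrt(rel) if use_accuracy else rel
    outer = w[:, :, None] * w[:, None, :]  # r²_i r²_j (or r_i r_j)
    scale = np.outer(sd, sd)
    p = outer * corr[None, :, :] * scale[None, :, :]
    d = rel * (sd**2)[None, :]
    ii = np.arange(k)
    p[:, ii, ii] = d
    g = rel[:, :, None] * corr[None, :, :] * scale[None, :, :]
    return p, g


def si_index(ebv_univariate: np.ndarray, reliabilities: np.ndarray,
             params: GeneticParams, use_accuracy: bool = False,
             cond_limit: float = 1e12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Selection-index TMI from univariate EBV.

    Returns ``(tmi_raw, tmi_reliability, b)``; the per-animal index weights
    ``b`` solve ``P* b = G* v``.  Near-singular ``P*`` (animals with
    vanishing reliabilities) is ridge-regularized by ``1e-8 sigma²_a,i`` on
    the diagonal.
    """
    ebv = np.atleast_2d(np.asarray(ebv_univariate, dtype=float))
    rel = np.atleast_2d(np.asarray(reliabilities, dtype=float))
    if np.any(rel < 0) or np.any(rel > 1):
        raise ValueError("reliabilities must lie in [0, 1]")
    v = params.index_weights
    p, g = _si_matrices(rel, params, use_accuracy)
    gv = g @ v
    ridge = 1e-8 * params.sigma_a2
    # regularize where conditioning is poor (including exactly singular)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(p)
    bad = ~np.isfinite(cond) | (cond > cond_limit)
    p_reg = p
    if bad.any():
        p_reg = p.copy()
        p_reg[bad] = p[bad] + np.diag(ridge)[None, :, :]
    try:
        b = np.linalg.solve(p_reg, gv[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as e:
        raise RuntimeError(f"singular index covariance after regularization: {e}") from e
    tmi = np.einsum("nk,nk->n", b, ebv)
    denom = float(v @ params.g0 @ v)
    rel_tmi = np.einsum("nk,nk->n", b, gv) / denom
    return tmi, np.clip(rel_tmi, 0.0, 1.0), b


def multitrait_tmi_reliability(pev_block: np.ndarray, params: GeneticParams) -> np.ndarray:
    """TMI reliability from per-animal PEV blocks: ``1 - v'PEVv / v'G0v``."""
    pev = np.asarray(pev_block, dtype=float)
    single = pev.ndim == 2
    if single:
        pev = pev[None, :, :]
    v = params.index_weights
    num = np.einsum("i,nij,j->n", v, pev, v)
    if np.any(num < -1e-8):
        raise ValueError("PEV block is not positive semidefinite")
    den = float(v @ params.g0 @ v)
    out = np.clip(1.0 - num / den, 0.0, 1.0)
    return float(out[0]) if single else out


def standardize(tmi_raw: np.ndarray, birth_year: np.ndarray,
                base_years: tuple[int, int] = (18, 22),
                sd_genetic: float | None = None,
                true_tmi: np.ndarray | None = None,
                mean_rel: float | None = None,
                target_mean: float = 100.0, target_sd: float = 12.0) -> np.ndarray:
    """Affine map to the published scale: base-cohort mean 100, genetic SD 12.

    The scale factor uses the additive genetic standard deviation of the
    aggregate genotype *within the base cohort* — from ``true_tmi`` when
    truth is available (simulation), from ``sd_genetic`` when supplied
    directly, or, as a fallback, from the raw index SD deflated by the mean
    reliability (the raw EBV spread understates or overstates the genetic
    spread depending on shrinkage and inflation, which is exactly what the
    deflation corrects at first order).
    """
    tmi_raw = np.asarray(tmi_raw, dtype=float)
    birth_year = np.asarray(birth_year)
    base = (birth_year >= base_years[0]) & (birth_year <= base_years[1])
    if not base.any():
        raise ValueError(f"no animals born in base years {base_years}")
    mean_base = tmi_raw[base].mean()
    if sd_genetic is None:
        if true_tmi is not None:
            sd_genetic = float(np.std(np.asarray(true_tmi)[base]))
        else:
            raw_sd = float(np.std(tmi_raw[base]))
            if mean_rel is None:
                raise ValueError("need sd_genetic, true_tmi, or mean_rel to set the scale")
            sd_genetic = raw_sd / np.sqrt(max(mean_rel, 1e-12))
    if sd_genetic <= 0:
        raise ValueError("genetic SD of the base cohort must be positive")
    return target_mean + target_sd * (tmi_raw - mean_base) / sd_genetic
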