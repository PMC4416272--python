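"""Genetic parameters and breeding-scheme configuration.

Defaults describe the simulated dual-purpose dairy population: five normally
distributed traits — fat yield (FY), protein yield (PY), net daily gain
(NDG), somatic cell count (SCC) and non-return rate of cows (NRR) — with
heritabilities 0.40/0.39/0.27/0.12/0.02, the genetic correlation matrix
below, and relative economic weights 5.4/53.6/4.3/19.7/17 % per additive
genetic standard deviation.  Genetic standard deviations default to 1 per
trait (economic weights are expressed per genetic SD, so all comparison
statistics are scale-free).

Residual-covariance scenarios are indexed by ``residual_fraction``: residual
correlations equal that fraction of the genetic correlations (0 = scenario 0,
0.5 = scenario 1, 1.0 = scenario 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TRAITS",
    "GeneticParams",
    "SchemeConfig",
    "residual_covariance_matrix",
]

TRAITS = ("FY", "PY", "NDG", "SCC", "NRR")

_H2 = np.array([0.40, 0.39, 0.27, 0.12, 0.02])

_GENETIC_CORR = np.array(
    [
        [1.00, 0.85, 0.10, 0.25, -0.20],
        [0.85, 1.00, 0.10, 0.25, -0.20],
        [0.10, 0.10, 1.00, 0.00, 0.00],
        [0.25, 0.25, 0.00, 1.00, -0.10],
        [-0.20, -0.20, 0.00, -0.10, 1.00],
    ]
)

_ECON_WEIGHTS = np.array([5.4, 53.6, 4.3, 19.7, 17.0])

# female-recorded traits and the single male-recorded trait (indices in TRAITS)
FEMALE_TRAITS = np.array([0, 1, 3, 4])
MALE_TRAITS = np.array([2])


def _check_pd(m: np.ndarray, what: str) -> None:
    w = np.linalg.eigvalsh(m)
    if w.min() <= 0:
        raise ValueError(f"{what} is not positive definite (smallest eigenvalue {w.min():.3e})")


@dataclass(frozen=True)
class GeneticParams:
    """Trait parameters of the simulated population.

    ``econ_weights`` are relative economic values per additive genetic SD (sum
    100 by default); the merit-index weight vector on the trait scale is
    ``v = econ_weights / genetic_sd``.
    """

    trait_names: tuple[str, ...] = TRAITS
    h2: np.ndarray = field(default_factory=lambda: _H2.copy())
    genetic_corr: np.ndarray = field(default_factory=lambda: _GENETIC_CORR.copy())
    genetic_sd: np.ndarray = field(default_factory=lambda: np.ones(5))
    econ_weights: np.ndarray = field(default_factory=lambda: _ECON_WEIGHTS.copy())
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        h2 = np.asarray(self.h2, dtype=float)
        corr = np.asarray(self.genetic_corr, dtype=float)
        sd = np.asarray(self.genetic_sd, dtype=float)
        w = np.asarray(self.econ_weights, dtype=float)
        object.__setattr__(self, "h2", h2)
        object.__setattr__(self, "genetic_corr", corr)
        object.__setattr__(self, "genetic_sd", sd)
        object.__setattr__(self, "econ_weights", w)
        k = len(self.trait_names)
        if not (h2.shape == (k,) and sd.shape == (k,) and w.shape == (k,) and corr.shape == (k, k)):
            raise ValueError("parameter dimensions inconsistent with trait list")
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise ValueError("heritabilities must lie in (0, 1]")
        if np.any(sd <= 0):
            raise ValueError("genetic SDs must be positive")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("genetic correlation matrix must be symmetric with unit diagonal")
        _check_pd(corr, "genetic correlation matrix")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")
        # R0 positive definiteness is scenario-dependent; validated on build
        residual_covariance_matrix(self)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def g0(self) -> np.ndarray:
        """Additive genetic covariance matrix ``G0``."""
        d = np.diag(self.genetic_sd)
        return d @ self.genetic_corr @ d

    @property
    def sigma_a2(self) -> np.ndarray:
        return self.genetic_sd**2

    @property
    def sigma_e2(self) -> np.ndarray:
        """Residual variances implied by h²: sigma_e² = sigma_a² (1-h²)/h²."""
        return self.sigma_a2 * (1.0 - self.h2) / self.h2

    @property
    def sigma_p2(self) -> np.ndarray:
        return self.sigma_a2 / self.h2

    @property
    def alpha(self) -> np.ndarray:
        """Variance ratios sigma_e²/sigma_a² per trait."""
        return self.sigma_e2 / self.sigma_a2

    @property
    def r0(self) -> np.ndarray:
        return residual_covariance_matrix(self)

    @property
    def index_weights(self) -> np.ndarray:
        """Merit weights on the trait scale, v_t = omega_t / sigma_a,t."""
        return self.econ_weights / self.genetic_sd

    @property
    def true_index_sd(self) -> float:
        """Genetic SD of the aggregate genotype, sqrt(v' G0 v), in the base."""
        v = self.index_weights
        return float(np.sqrt(v @ self.g0 @ v))

    def with_scenario(self, residual_fraction: float) -> "GeneticParams":
        return replace(self, residual_fraction=residual_fraction)


def residual_covariance_matrix(params: GeneticParams) -> np.ndarray:
    """Residual covariance matrix ``R0`` for the configured scenario.

    Off-diagonal residual correlations equal ``residual_fraction`` times the
    genetic correlations; diagonals follow from the heritabilities.  Raises if
    the resulting matrix is not positive definite.
    """
    se = np.sqrt(params.sigma_a2 * (1.0 - params.h2) / params.h2)
    corr = params.residual_fraction * params.genetic_corr
    np.fill_diagonal(corr, 1.0)
    r0 = np.outer(se, se) * corr
    w = np.linalg.eigvalsh(r0)
    if w.min() <= 0:
        raise ValueError(
            f"residual covariance matrix not positive definite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    return r0


@dataclass(frozen=True)
class SchemeConfig:
    """Structure and intensities of the simulated closed breeding scheme.

    The full-scale population comprises 1,710 herds of 30 cows; desk-scale
    presets shrink the herd count, never the 30-year horizon.  Matings are
    split 25 % to young (unproven) bulls and 75 % to proven bulls; net daily
    gain is recorded on 60 % of male calves; cows enter the milking herd after
    their first record and stay ``cow_lifespan_years`` years, each mated once
    per year with a single offspring at a 50:50 sex ratio.
    """

    n_herds: int = 1710
    cows_per_herd: int = 30
    n_years: int = 30
    young_bull_fraction: float = 0.25
    proven_bull_fraction: float = 0.75
    male_ndg_recording_rate: float = 0.60
    n_proven_sires: int = 40
    n_young_sires: int = 40
    cow_lifespan_years: int = 4
    min_proven_daughters: int = 10
    herd_year_sd_frac: float = 0.5  # herd-year effect SD, fraction of phenotypic SD
    base_years: tuple[int, int] = (18, 22)
    analysis_years: tuple[int, int] = (11, 30)
    selection_criterion: str = "blup"  # "blup" | "pedigree_index" | "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.young_bull_fraction <= 1.0:
            raise ValueError("young_bull_fraction must lie in [0, 1]")
        if abs(self.young_bull_fraction + self.proven_bull_fraction - 1.0) > 1e-9:
            raise ValueError("young and proven bull fractions must sum to 1")
        if not 0.0 <= self.male_ndg_recording_rate <= 1.0:
            raise ValueError("male_ndg_recording_rate must lie in [0, 1]")
        if min(self.n_herds, self.cows_per_herd, self.n_years) <= 0:
            raise ValueError("population sizes and years must be positive")
        if self.selection_criterion not in ("blup", "pedigree_index", "random"):
            raise ValueError("selection_criterion must be blup, pedigree_index or random")

    @property
    def n_cows(self) -> int:
        return self.n_herds * self.cows_per_herd

    @classmethod
    def full_scale(cls) -> "SchemeConfig":
        """Cluster-scale preset mirroring the full simulated population."""
        return cls()

    @classmethod
    def scaled(cls) -> "SchemeConfig":
        """Mid-scale preset (200 herds x 30 cows)."""
        return cls(n_herds=200, cows_per_herd=30, n_proven_sires=25, n_young_sires=25)

    @classmethod
    def desk(cls) -> "SchemeConfig":
        """Desk-scale preset used by the shipped reproduction script.

        Herd size stays at the realistic 30 cows; sire numbers are scaled so
        proven bulls still accumulate daughter groups of realistic size
        (tens per year), which is what creates the high-reliability classes
        a progeny-testing scheme is defined by.
        """
        return cls(n_herds=20, cows_per_herd=30, n_proven_sires=8, n_young_sires=12,
                   min_proven_daughters=5)

    @classmethod
    def smoke(cls) -> "SchemeConfig":
        """Tiny preset for fast tests."""
        return cls(n_herds=12, cows_per_herd=30, n_proven_sires=6, n_young_sires=8,
                   min_proven_daughters=4)
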