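"""Unit system and parameter containers shared by all modules.

The trait is measured internally in units of ``delta = sqrt(VS / 2N)``, the
magnitude of mean-phenotype fluctuations at mutation-selection-drift balance
(MSDB).  In these units the squared width of the Gaussian fitness function is
``VS = 2N``, and an allele with effect ``a`` has population-scaled selection
coefficient ``Se = 2N a^2 / VS = a^2`` at MSDB.  Every other module operates
in internal units; raw trait units are converted on the way in and out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterError",
    "TraitScale",
    "EffectSize",
    "EffectDistribution",
    "PointMassEffects",
    "ExponentialEffects",
    "Scenario",
    "to_internal",
    "from_internal",
    "DEFAULT_SE_MIN",
    "SE_NEARLY_NEUTRAL",
]

#: Boundary between (nearly) neutral and strongly selected dynamics under the
#: under-dominant stabilizing-selection term: Se ~ 5 rather than the usual 1.
SE_NEARLY_NEUTRAL = 5.0

#: Default lower bound on Se for the "large effect" mutational distribution.
#: "Large" means Se >> 5; 20 keeps a safety margin above the nearly neutral band.
DEFAULT_SE_MIN = 20.0


class ParameterError(ValueError):
    """Invalid model parameterization."""


@dataclass(frozen=True)
class TraitScale:
    """Population size and fitness-function width tying raw trait units to delta.

    Parameters
    ----------
    N : int
        Diploid population size (>= 2).
    VS : float
        Squared width of the Gaussian fitness function in raw trait units
        squared.  Environmental noise is assumed absorbed into VS.
    """

    N: int
    VS: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ParameterError(f"N must be an integer >= 2, got {self.N!r}")
        if not (math.isfinite(self.VS) and self.VS > 0):
            raise ParameterError(f"VS must be finite and positive, got {self.VS!r}")

    @property
    def delta(self) -> float:
        """Unit of measurement: sqrt(VS / 2N) in raw trait units."""
        return math.sqrt(self.VS / (2 * self.N))

    @property
    def vs_internal(self) -> float:
        """VS in internal (delta^2) units; equals 2N by construction."""
        return 2.0 * self.N


def to_internal(value: float, scale: TraitScale, power: int = 1) -> float:
    """Convert a raw-trait-unit quantity to internal delta-based units.

    ``power`` is the exponent of the trait dimension: 1 for trait values and
    allele effects, 2 for variances.
    """
    if power not in (1, 2):
        raise ParameterError(f"power must be 1 or 2, got {power!r}")
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("non-finite value passed to to_internal")
    out = arr / scale.delta**power
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def from_internal(value: float, scale: TraitScale, power: int = 1) -> float:
    """Inverse of :func:`to_internal`."""
    if power not in (1, 2):
        raise ParameterError(f"power must be 1 or 2, got {power!r}")
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("non-finite value passed to from_internal")
    out = arr * scale.delta**power
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass(frozen=True)
class EffectSize:
    """A single allele effect in internal units; Se = a^2 by construction."""

    a: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a >= 0):
            raise ParameterError(f"effect a must be finite and >= 0, got {self.a!r}")

    @property
    def Se(self) -> float:
        return self.a * self.a

    @classmethod
    def from_Se(cls, Se: float) -> "EffectSize":
        if Se < 0:
            raise ParameterError(f"Se must be >= 0, got {Se!r}")
        return cls(math.sqrt(Se))

    @property
    def regime(self) -> str:
        """Crude Se classification: small / intermediate / large."""
        if self.Se < SE_NEARLY_NEUTRAL / 2:
            return "small"
        if self.Se <= 2 * SE_NEARLY_NEUTRAL:
            return "intermediate"
        return "large"


class EffectDistribution:
    """Distribution over squared effects Se of new mutations.

    Subclasses define a density over Se on ``[Se_min, Se_max]``.  The sign of
    an effect (aligned/opposing the eventual shift, orientation +-1) is always
    assigned symmetrically with probability 1/2 each, independent of
    magnitude: mutation is unbiased with respect to trait direction.
    """

    Se_min: float
    Se_max: float

    def pdf(self, Se: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample_Se(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def quad_nodes(self, n: int = 48) -> tuple[np.ndarray, np.ndarray]:
        """(Se nodes, probability weights) approximating the distribution.

        Weights sum to 1; a point mass returns a single node.
        """
        raise NotImplementedError

    def sample_orientation(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.array([-1, 1], dtype=np.int8), size=size)

    def _check_support(self) -> None:
        if not (0 <= self.Se_min <= self.Se_max):
            raise ParameterError(
                f"invalid Se support [{self.Se_min}, {self.Se_max}]"
            )


class PointMassEffects(EffectDistribution):
    """All mutations share one squared effect Se (single-effect experiments)."""

    def __init__(self, Se: float):
        if Se < 0:
            raise ParameterError(f"Se must be >= 0, got {Se!r}")
        self.Se = float(Se)
        self.Se_min = self.Se_max = self.Se
        self._check_support()

    def pdf(self, Se):  # Dirac mass; pdf only meaningful under quadrature
        Se = np.asarray(Se, dtype=float)
        return np.where(Se == self.Se, np.inf, 0.0)

    def sample_Se(self, rng, size):
        return np.full(size, self.Se)

    def quad_nodes(self, n: int = 48):
        return np.array([self.Se]), np.array([1.0])

    def __repr__(self):
        return f"PointMassEffects(Se={self.Se})"


class ExponentialEffects(EffectDistribution):
    """Exponential density in Se truncated to [Se_min, Se_max].

    pdf(Se) proportional to exp(-Se / mean_Se) on the support; the default
    large-effect support keeps every mutation well inside the strongly
    selected range Se >> 5.
    """

    def __init__(self, mean_Se: float, Se_min: float = DEFAULT_SE_MIN, Se_max: float = 2000.0):
        if mean_Se <= 0:
            raise ParameterError(f"mean_Se must be > 0, got {mean_Se!r}")
        if not Se_max > Se_min:
            raise ParameterError("Se_max must exceed Se_min")
        self.mean_Se = float(mean_Se)
        self.Se_min = float(Se_min)
        self.Se_max = float(Se_max)
        self._check_support()
        r = 1.0 / self.mean_Se
        self._lo_cdf = -math.expm1(-r * self.Se_min)
        self._mass = math.exp(-r * self.Se_min) - math.exp(-r * self.Se_max)

    def pdf(self, Se):
        Se = np.asarray(Se, dtype=float)
        r = 1.0 / self.mean_Se
        inside = (Se >= self.Se_min) & (Se <= self.Se_max)
        return np.where(inside, r * np.exp(-r * Se) / self._mass, 0.0)

    def sample_Se(self, rng, size):
        u = rng.random(size)
        r = 1.0 / self.mean_Se
        # inverse CDF of the truncated exponential
        return -np.log(math.exp(-r * self.Se_min) - u * self._mass) / r

    def quad_nodes(self, n: int = 48):
        # Gauss-Legendre in log-Se: resolves the density near Se_min where
        # most of the mass sits, without wasting nodes in the thin tail.
        from numpy.polynomial.legendre import leggauss

        z, w = leggauss(n)
        lo, hi = math.log(self.Se_min), math.log(self.Se_max)
        u = 0.5 * (hi - lo) * (z + 1.0) + lo
        Se = np.exp(u)
        weights = self.pdf(Se) * Se * 0.5 * (hi - lo) * w  # d(Se) = Se d(log Se)
        weights = weights / weights.sum()
        return Se, weights

    def __repr__(self):
        return (
            f"ExponentialEffects(mean_Se={self.mean_Se}, "
            f"Se_min={self.Se_min}, Se_max={self.Se_max})"
        )


@dataclass(frozen=True)
class Scenario:
    """One optimum-shift experiment in internal (delta) units.

    Parameters
    ----------
    Lambda : float
        Shift in the optimum, delta units, >= 0.
    sigma2 : float
        Variance of the Fisherian (infinitesimal) genetic background in
        delta^2 units; summarizes small/intermediate-effect alleles.
    twoNU : float
        Population-scaled mutational input of tracked alleles per generation.
    effect_dist : EffectDistribution
        Distribution of squared effects Se of tracked mutations.
    scale : TraitScale
        Population size and fitness-width bookkeeping.
    Se_min_cutoff : float
        Configured lower bound for "large effect"; the tracked distribution's
        support must respect it unless ``allow_small`` is set (the fully
        polygenic engine tracks all effect sizes explicitly).
    """

    Lambda: float
    sigma2: float
    twoNU: float
    effect_dist: EffectDistribution
    scale: TraitScale
    Se_min_cutoff: float = DEFAULT_SE_MIN
    allow_small: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Lambda) and self.Lambda >= 0):
            raise ParameterError(f"Lambda must be finite and >= 0, got {self.Lambda!r}")
        if not (math.isfinite(self.sigma2) and self.sigma2 >= 0):
            raise ParameterError(f"sigma2 must be finite and >= 0, got {self.sigma2!r}")
        if not (math.isfinite(self.twoNU) and self.twoNU >= 0):
            raise ParameterError(f"twoNU must be finite and >= 0, got {self.twoNU!r}")
        if not self.allow_small and self.effect_dist.Se_min < self.Se_min_cutoff:
            raise ParameterError(
                "effect distribution support extends below the large-effect "
                f"cutoff Se_min={self.Se_min_cutoff} (distribution starts at "
                f"{self.effect_dist.Se_min}); small/intermediate effects belong "
                "in sigma2 for the hybrid engine, or pass allow_small=True for "
                "the fully polygenic engine"
            )
        if self.Lambda > math.sqrt(self.scale.vs_internal):
            warnings.warn(
                f"Lambda={self.Lambda:.3g} exceeds sqrt(VS)="
                f"{math.sqrt(self.scale.vs_internal):.3g}: the Gaussian "
                "fitness function may no longer approximate true fitness "
                "(shift larger than the width of the fitness function)",
                UserWarning,
                stacklevel=2,
            )

    @property
    def N(self) -> int:
        return self.scale.N

    @property
    def VS(self) -> float:
        """VS in internal units (= 2N)."""
        return self.scale.vs_internal
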