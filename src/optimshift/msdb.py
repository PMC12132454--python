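"""Mutation-selection-drift balance (MSDB): the pre-shift standing architecture.

Before the optimum shifts the population mean sits at the optimum (D = 0), so
a tracked allele only feels the under-dominant stabilizing-selection term of
the single-generation moments,

    E[dx] = -(a^2/VS) (1/2 - x) x(1-x),      V[dx] = x(1-x) / 2N.

The expected time a new mutant entering at frequency 1/2N spends in each
frequency class (the sojourn-time density) follows from the standard
diffusion formula with scale density G(x) = exp(Se * x(1-x)), Se = 2N a^2/VS.
With mutational input 2NU per generation, the equilibrium number of
segregating alleles in (x, x+dx) is 2NU * t(x) dx, which is what
:func:`sample_standing` draws from.  :func:`burnin_engine` provides the same
architecture by brute-force forward simulation and serves as a cross-check.

All quantities are in internal delta units (see :mod:`optimshift.core_units`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_units import (
    EffectSize,
    ParameterError,
    Scenario,
    TraitScale,
)

__all__ = [
    "SojournDensity",
    "sojourn_density",
    "StandingArchitecture",
    "sample_standing",
    "burnin_engine",
    "variance_per_unit_input",
]


class NumericalError(RuntimeError):
    """Quadrature or integration failure with diagnostics."""


def _log_trapz_cumulative(logf: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log of the cumulative trapezoid integral of exp(logf) along x.

    Returns an array c with c[0] = -inf and c[i] = log(int_{x0}^{xi} exp(logf)).
    Accumulation happens in log space so integrands spanning hundreds of
    e-folds (G(x) for large Se) stay finite.
    """
    inc = np.logaddexp(logf[:-1], logf[1:]) - math.log(2.0) + np.log(np.diff(x))
    out = np.empty(len(x))
    out[0] = -np.inf
    out[1:] = np.logaddexp.accumulate(inc)
    return out


class SojournDensity:
    """Sojourn-time density t(x) of a new mutant under stabilizing selection.

    Parameters
    ----------
    Se : float
        Population-scaled selection coefficient a^2 (internal units), >= 0.
    N : int
        Diploid population size; the mutant enters at frequency 1/2N and
        "segregating" means x in [1/2N, 1 - 1/2N].
    grid_size : int
        Number of logit-spaced grid points used for quadrature and sampling.
    """

    def __init__(self, Se: float, N: int, grid_size: int = 4001):
        if Se < 0:
            raise ParameterError(f"Se must be >= 0, got {Se!r}")
        if N < 2:
            raise ParameterError(f"N must be >= 2, got {N!r}")
        self.Se = float(Se)
        self.N = int(N)
        p = 1.0 / (2 * N)
        self.x_init = p
        # the segregating range covers the lattice cells of copy numbers
        # 1 .. 2N-1, i.e. [1/4N, 1 - 1/4N]: integrating over full cells makes
        # the continuum total sojourn time agree with the discrete chain's
        # expected lifetime (the 1/x divergence makes the half-cell below
        # the entry frequency a ~20% effect for strongly selected alleles)
        lo = p / 2.0
        self.x_support = (lo, 1.0 - lo)

        # logit-spaced grid covers both boundaries at resolution ~1/(4N)
        u = np.linspace(logit(lo / 2), logit(1 - lo / 2), grid_size)
        y = expit(u)
        y[0], y[-1] = 0.0, 1.0  # endpoints for the scale-function integrals
        self._y = y
        f = self.Se * y * (1.0 - y)  # log G(y)

        logS_fwd = _log_trapz_cumulative(f, y)          # log S(y_i)
        logS_rev = _log_trapz_cumulative(f[::-1], 1.0 - y[::-1])[::-1]
        self._logS1 = logS_fwd[-1]
        # S(p): p lies within the grid resolution of the lower boundary; the
        # integrand is ~1 there (Se * p << Se/4), so S(p) ~= p.
        self._logSp = math.log(p) + 0.5 * self.Se * p * (1 - p)
        self.log_fixation_prob = self._logSp - self._logS1

        inside = (y >= lo) & (y <= 1 - lo)
        self._x = y[inside]
        with np.errstate(divide="ignore"):
            log_v = np.log(self._x) + np.log1p(-self._x) - math.log(2 * N)
        # standard two-branch sojourn formula for entry at p:
        #   x >= p: t = 2 S(p) (S(1) - S(x)) / (S(1) v G)
        #   x <  p: t = 2 (S(1) - S(p)) S(x) / (S(1) v G)
        log_high = self._logSp + logS_rev[inside]
        # log(S(1) - S(p)) via log1p; S(p)/S(1) = fixation prob, always < 1
        log_s1_minus_sp = self._logS1 + math.log1p(
            -math.exp(min(self.log_fixation_prob, -1e-300)))
        log_low = log_s1_minus_sp + logS_fwd[inside]
        self._log_t = (
            math.log(2.0)
            + np.where(self._x >= p, log_high, log_low)
            - self._logS1
            - log_v
            - self.Se * self._x * (1.0 - self._x)
        )
        if not np.all(np.isfinite(self._log_t)):
            raise NumericalError(
                f"non-finite sojourn density (Se={Se}, N={N}); "
                f"bad nodes: {np.count_nonzero(~np.isfinite(self._log_t))}"
            )

        m = self._log_t.max()
        t_scaled = np.exp(self._log_t - m)
        self.total_time = float(np.exp(m) * np.trapezoid(t_scaled, self._x))
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (t_scaled[:-1] + t_scaled[1:]) * np.diff(self._x))])
        self._cdf = cdf / cdf[-1]

    # -- evaluation ---------------------------------------------------------
    def log_density(self, x) -> np.ndarray:
        """log t(x), interpolated in logit coordinates on the grid."""
        x = np.asarray(x, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ParameterError("sojourn density is defined on open (0,1)")
        return np.interp(logit(x), logit(self._x), self._log_t)

    def __call__(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))

    def moment(self, g) -> float:
        """int g(x) t(x) dx over the segregating range."""
        m = self._log_t.max()
        return float(
            np.exp(m) * np.trapezoid(g(self._x) * np.exp(self._log_t - m), self._x)
        )

    def tail_mass(self, x_star: float) -> float:
        """Fraction of sojourn time spent above x_star, P(x > x_star | segregating)."""
        return 1.0 - float(np.interp(logit(x_star), logit(self._x), self._cdf))

    def normalized_pdf(self, x) -> np.ndarray:
        return self(x) / self.total_time

    def ppf(self, q) -> np.ndarray:
        """Inverse CDF of the normalized sojourn density (for sampling x0)."""
        q = np.asarray(q, dtype=float)
        return expit(np.interp(q, self._cdf, logit(self._x)))

    @property
    def variance_contribution(self) -> float:
        """int 2 a^2 x(1-x) t(x) dx: trait variance per unit mutational input."""
        return self.moment(lambda x: 2.0 * self.Se * x * (1.0 - x))


_SOJOURN_CACHE: dict[tuple, SojournDensity] = {}


def sojourn_density(effect: EffectSize | float, scale: TraitScale, grid_size: int = 4001) -> SojournDensity:
    """Cached constructor; ``effect`` may be an EffectSize or a bare Se value."""
    Se = effect.Se if isinstance(effect, EffectSize) else float(effect)
    key = (round(Se, 10), scale.N, grid_size)
    if key not in _SOJOURN_CACHE:
        if len(_SOJOURN_CACHE) > 256:
            _SOJOURN_CACHE.clear()
        _SOJOURN_CACHE[key] = SojournDensity(Se, scale.N, grid_size)
    return _SOJOURN_CACHE[key]


def variance_per_unit_input(scenario: Scenario) -> float:
    """Expected MSDB variance from tracked alleles per unit 2NU.

    Integrates the per-mutation variance contribution over the effect
    distribution; multiply by 2NU for the standing large-effect variance.
    """
    nodes, weights = scenario.effect_dist.quad_nodes()
    return float(sum(
        w * sojourn_density(Se, scenario.scale).variance_contribution
        for Se, w in zip(nodes, weights)
    ))


@dataclass
class StandingArchitecture:
    """Tracked alleles segregating at the moment of the shift."""

    Se: np.ndarray          # squared effects, internal units
    orientation: np.ndarray  # +-1; +1 = aligned with the (future) shift
    x0: np.ndarray          # frequencies, strictly in (0,1)

    def __post_init__(self):
        self.Se = np.asarray(self.Se, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=np.int8)
        self.x0 = np.asarray(self.x0, dtype=float)
        if np.any((self.x0 <= 0) | (self.x0 >= 1)):
            raise ParameterError("standing frequencies must lie strictly in (0,1)")
        if self.Se.shape != self.orientation.shape or self.Se.shape != self.x0.shape:
            raise ParameterError("field lengths differ")

    @property
    def a(self) -> np.ndarray:
        return np.sqrt(self.Se)

    def __len__(self) -> int:
        return len(self.Se)

    @property
    def total_large_variance(self) -> float:
        """Sum of 2 a^2 x(1-x) over alleles (delta^2 units)."""
        return float(np.sum(2.0 * self.Se * self.x0 * (1.0 - self.x0)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele_id": np.arange(len(self)),
                "Se": self.Se,
                "a": self.a,
                "orientation": self.orientation.astype(int),
                "x0": self.x0,
                "origin": "standing",
            }
        )

    @classmethod
    def empty(cls) -> "StandingArchitecture":
        return cls(np.empty(0), np.empty(0, dtype=np.int8), np.empty(0))


def sample_standing(scenario: Scenario, rng: np.random.Generator) -> StandingArchitecture:
    """Draw the standing tracked-allele architecture at MSDB.

    The number of segregating alleles is Poisson with mean
    2NU * int effect_dist(Se) T_soj(Se) dSe; each allele's (Se, x0) comes
    from the joint density effect_dist(Se) * t(x | Se), discretized on the
    distribution's quadrature nodes; orientations are symmetric +-1.
    """
    if scenario.twoNU < 0:
        raise ParameterError("twoNU must be >= 0")
    if scenario.twoNU == 0:
        return StandingArchitecture.empty()
    nodes, weights = scenario.effect_dist.quad_nodes()
    densities = [sojourn_density(Se, scenario.scale) for Se in nodes]
    means = scenario.twoNU * weights * np.array([d.total_time for d in densities])
    counts = rng.poisson(means)
    Se_out, x_out = [], []
    for Se, d, k in zip(nodes, densities, counts):
        if k == 0:
            continue
        Se_out.append(np.full(k, Se))
        x_out.append(d.ppf(rng.random(k)))
    if not Se_out:
        return StandingArchitecture.empty()
    Se_all = np.concatenate(Se_out)
    x_all = np.concatenate(x_out)
    orient = scenario.effect_dist.sample_orientation(rng, len(Se_all))
    return StandingArchitecture(Se_all, orient, x_all)


def expected_standing_count(scenario: Scenario) -> float:
    """Poisson mean of the number of segregating tracked alleles at MSDB."""
    nodes, weights = scenario.effect_dist.quad_nodes()
    return float(scenario.twoNU * sum(
        w * sojourn_density(Se, scenario.scale).total_time
        for Se, w in zip(nodes, weights)
    ))


def burnin_engine(
    scenario: Scenario,
    generations: int,
    rng: np.random.Generator,
    convergence_check: bool = True,
) -> StandingArchitecture:
    """Forward-simulate to MSDB and return the segregating tracked alleles.

    Recurrent mutation injects Poisson(2NU) new alleles per generation at
    frequency 1/2N; every segregating allele gets a binomial(2N) update with
    mean x + E[dx] under the stabilizing term only (D = 0).  Fixed and lost
    alleles are discarded (the infinite-sites bookkeeping of the equilibrium
    state only needs the segregating set).  This is the brute-force oracle
    for :func:`sample_standing`.
    """
    N = scenario.N
    VS = scenario.VS
    two_n = 2 * N
    if generations < 20 * N:
        warnings.warn(
            f"burn-in of {generations} generations is below the recommended "
            f"20N = {20 * N}; the returned architecture may not be at MSDB",
            UserWarning,
            stacklevel=2,
        )
    Se = np.empty(0)
    orient = np.empty(0, dtype=np.int8)
    x = np.empty(0)
    va_history = []
    checkpoint = max(1, generations // 80)
    for gen in range(generations):
        if len(x):
            ex = x + (-(Se / VS) * (0.5 - x)) * x * (1.0 - x)
            x = rng.binomial(two_n, np.clip(ex, 0.0, 1.0)) / two_n
            seg = (x > 0.0) & (x < 1.0)
            if not seg.all():
                Se, orient, x = Se[seg], orient[seg], x[seg]
        k = rng.poisson(scenario.twoNU)
        if k:
            Se = np.concatenate([Se, scenario.effect_dist.sample_Se(rng, k)])
            orient = np.concatenate(
                [orient, scenario.effect_dist.sample_orientation(rng, k)])
            x = np.concatenate([x, np.full(k, 1.0 / two_n)])
        if convergence_check and gen % checkpoint == 0:
            va_history.append(float(np.sum(2.0 * Se * x * (1.0 - x))))
    if convergence_check and len(va_history) >= 40:
        q = len(va_history) // 4
        recent = float(np.mean(va_history[-q:]))
        previous = float(np.mean(va_history[-2 * q : -q]))
        denom = max(abs(previous), 1e-12)
        if abs(recent - previous) / denom > 0.05 and scenario.twoNU > 0:
            warnings.warn(
                "burn-in variance still drifting by more than 5% over the "
                "final quarter of the run; consider a longer burn-in",
                UserWarning,
                stacklevel=2,
            )
    if len(x) == 0:
        return StandingArchitecture.empty()
    return StandingArchitecture(Se, orient, x)
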