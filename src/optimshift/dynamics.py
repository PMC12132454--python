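"""Per-generation stochastic evolution after the optimum shift.

Two engines share one core:

* the **hybrid engine** tracks each large-effect allele individually
  (binomial Wright-Fisher updates realizing the single-generation moments)
  while the small/intermediate-effect background of variance sigma^2 advances
  its mean deterministically along Lande's approximation;
* the **fully polygenic engine** tracks every allele explicitly, with no
  deterministic background.

The distance of the mean phenotype from the new optimum is never integrated
forward on its own: it is recomputed each generation from the bookkeeping
identity

    D(t) = Lambda - mean_bg(t) - sum_i orientation_i * 2 a_i * (x_i(t) - x_i(0-)),

with x_i(0-) the pre-shift frequency (x0 for standing alleles, 0 for new
mutations), which keeps phenotype and allele accounting exactly consistent.

All quantities are in internal delta units (see :mod:`optimshift.core_units`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_units import ParameterError, Scenario, TraitScale
from .msdb import StandingArchitecture

__all__ = [
    "Allele",
    "PopulationState",
    "Trajectory",
    "delta_x_moments",
    "step_hybrid",
    "run_hybrid",
    "run_polygenic",
]

FATE_SEGREGATING = "segregating"
FATE_FIXED = "fixed"
FATE_LOST = "lost"

ORIGIN_STANDING = "standing"
ORIGIN_NEW = "new"


@dataclass
class Allele:
    """One tracked variant (record view; engines use arrays internally)."""

    a: float                 # effect magnitude, delta units, > 0
    orientation: int         # +1 aligned with the shift, -1 opposing
    x: float                 # current frequency in [0, 1]
    origin: str              # "standing" | "new"
    birth_generation: int = 0
    fate: str = FATE_SEGREGATING
    fate_generation: int | None = None

    @property
    def Se(self) -> float:
        return self.a * self.a


def delta_x_moments(a, x, D, scale: TraitScale):
    """First two moments of the one-generation frequency change.

    E[dx] = (a D / VS - (a^2 / VS)(1/2 - x)) * x(1-x): the first term is
    directional selection toward the optimum (semi-dominant, sign follows the
    signed effect ``a``), the second is stabilizing selection against the
    minor allele (under-dominant, sign-free).  V[dx] = x(1-x)/2N is the
    standard drift term.  ``a`` may be signed (orientation * magnitude).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ParameterError("frequency x must lie in [0, 1]")
    a = np.asarray(a, dtype=float)
    VS = scale.vs_internal
    het = x * (1.0 - x)
    expected = (a * D / VS - (a * a / VS) * (0.5 - x)) * het
    variance = het / (2.0 * scale.N)
    if expected.ndim == 0:
        return float(expected), float(variance)
    return expected, variance


class _AlleleArrays:
    """Struct-of-arrays store for every allele ever born in one run."""

    def __init__(self, standing: StandingArchitecture):
        n = len(standing)
        self.a = np.sqrt(standing.Se).astype(float)
        self.sgn = standing.orientation.astype(np.int8)
        self.x = standing.x0.astype(float).copy()
        self.x_ref = standing.x0.astype(float).copy()  # pre-shift frequency
        self.x0 = standing.x0.astype(float).copy()
        self.x_max = standing.x0.astype(float).copy()
        self.origin = np.zeros(n, dtype=np.int8)       # 0 standing, 1 new
        self.birth = np.zeros(n, dtype=np.int64)
        self.fate = np.zeros(n, dtype=np.int8)         # 0 seg, 1 fixed, 2 lost
        self.fate_gen = np.full(n, -1, dtype=np.int64)

    def add_new(self, a: np.ndarray, sgn: np.ndarray, t: int, two_n: int) -> None:
        k = len(a)
        x_birth = np.full(k, 1.0 / two_n)
        self.a = np.concatenate([self.a, a])
        self.sgn = np.concatenate([self.sgn, sgn.astype(np.int8)])
        self.x = np.concatenate([self.x, x_birth])
        self.x_ref = np.concatenate([self.x_ref, np.zeros(k)])
        self.x0 = np.concatenate([self.x0, x_birth])
        self.x_max = np.concatenate([self.x_max, x_birth])
        self.origin = np.concatenate([self.origin, np.ones(k, dtype=np.int8)])
        self.birth = np.concatenate([self.birth, np.full(k, t, dtype=np.int64)])
        self.fate = np.concatenate([self.fate, np.zeros(k, dtype=np.int8)])
        self.fate_gen = np.concatenate([self.fate_gen, np.full(k, -1, dtype=np.int64)])

    @property
    def segregating(self) -> np.ndarray:
        return self.fate == 0

    def mean_shift_contribution(self) -> float:
        """sum orientation * 2a * (x - x_ref) over every allele."""
        return float(np.sum(self.sgn * 2.0 * self.a * (self.x - self.x_ref)))

    def va_large(self) -> float:
        return float(np.sum(2.0 * self.a**2 * self.x * (1.0 - self.x)))

    def to_dataframe(self) -> pd.DataFrame:
        fate_names = np.array([FATE_SEGREGATING, FATE_FIXED, FATE_LOST])
        origin_names = np.array([ORIGIN_STANDING, ORIGIN_NEW])
        return pd.DataFrame(
            {
                "allele_id": np.arange(len(self.a)),
                "Se": self.a**2,
                "a": self.a,
                "orientation": self.sgn.astype(int),
                "origin": origin_names[self.origin],
                "birth_generation": self.birth,
                "fate": fate_names[self.fate],
                "fate_generation": self.fate_gen,
                "x0": self.x0,
                "x_final": self.x,
                "x_max": self.x_max,
            }
        )


@dataclass
class PopulationState:
    """State of the population ``t`` generations after the shift."""

    t: int
    D: float
    mean_bg: float
    alleles: _AlleleArrays
    scenario: Scenario

    @property
    def VA_large(self) -> float:
        """2 sum a^2 x(1-x) over tracked alleles (delta^2 units)."""
        return self.alleles.va_large()

    @property
    def n_segregating(self) -> int:
        return int(np.count_nonzero(self.alleles.segregating))

    def recompute_distance(self) -> float:
        return self.scenario.Lambda - self.mean_bg - self.alleles.mean_shift_contribution()

    def check_bookkeeping(self, atol: float = 1e-9) -> None:
        resid = abs(self.D - self.recompute_distance())
        if resid > atol:
            raise RuntimeError(
                f"bookkeeping identity violated at t={self.t}: residual {resid:.3e}"
            )

    @classmethod
    def initial(cls, scenario: Scenario, standing: StandingArchitecture) -> "PopulationState":
        return cls(
            t=0,
            D=scenario.Lambda,
            mean_bg=0.0,
            alleles=_AlleleArrays(standing),
            scenario=scenario,
        )


@dataclass
class Trajectory:
    """Per-generation record of one run plus the terminal allele table."""

    series: pd.DataFrame          # t, D, VA_large, sigma2, n_segregating
    alleles: pd.DataFrame         # every allele ever born, with fates
    freqs: pd.DataFrame | None    # thinned per-allele frequencies (long form)
    scenario: Scenario
    seed_note: str = ""

    def write_tsv(self, series_path, alleles_path, freqs_path=None) -> None:
        self.series.to_csv(series_path, sep="\t", index=False)
        self.alleles.to_csv(alleles_path, sep="\t", index=False)
        if freqs_path is not None and self.freqs is not None:
            self.freqs.to_csv(freqs_path, sep="\t", index=False)


def _mutation_window(scenario: Scenario) -> float:
    """Generations until the background-only Lande distance falls to delta.

    New large-effect mutations are only injected while this window is open:
    once D_L < delta a large-effect mutant is opposed by selection from
    birth and cannot contribute.  See analytic.adaptation_window.
    """
    if scenario.Lambda <= 1.0:
        return 0.0
    if scenario.sigma2 <= 0:
        return math.inf
    return (scenario.VS / scenario.sigma2) * math.log(scenario.Lambda)


def step_hybrid(
    state: PopulationState,
    scenario: Scenario,
    rng: np.random.Generator,
    mutate: bool = True,
) -> PopulationState:
    """Advance the hybrid engine by one generation (in place; returns state).

    Order of operations: (i) binomial update of every segregating tracked
    allele around x + E[dx] at the current distance; (ii) deterministic
    background-mean step mean_bg += (1 - exp(-sigma2/VS)) * D, the discrete
    realization of Lande's approximation; (iii) Poisson(2NU) new mutations at
    frequency 1/2N with symmetric orientations (if ``mutate``); (iv) distance
    recomputed from the bookkeeping identity; (v) fates updated.
    """
    al = state.alleles
    N = scenario.N
    two_n = 2 * N
    VS = scenario.VS
    D = state.D
    t_next = state.t + 1

    seg = al.segregating
    if seg.any():
        a_signed = al.sgn[seg] * al.a[seg]
        x = al.x[seg]
        het = x * (1.0 - x)
        ex = x + (a_signed * D / VS - (a_signed**2 / VS) * (0.5 - x)) * het
        x_new = rng.binomial(two_n, np.clip(ex, 0.0, 1.0)) / two_n
        al.x[seg] = x_new
        al.x_max[seg] = np.maximum(al.x_max[seg], x_new)
        fixed = x_new >= 1.0
        lost = x_new <= 0.0
        if fixed.any() or lost.any():
            idx = np.flatnonzero(seg)
            al.fate[idx[fixed]] = 1
            al.fate[idx[lost]] = 2
            al.fate_gen[idx[fixed | lost]] = t_next

    if scenario.sigma2 > 0:
        state.mean_bg += -math.expm1(-scenario.sigma2 / VS) * D

    if mutate and scenario.twoNU > 0:
        k = rng.poisson(scenario.twoNU)
        if k:
            Se_new = scenario.effect_dist.sample_Se(rng, k)
            sgn_new = scenario.effect_dist.sample_orientation(rng, k)
            al.add_new(np.sqrt(Se_new), sgn_new, t_next, two_n)

    state.t = t_next
    state.D = state.recompute_distance()
    return state


def run_hybrid(
    scenario: Scenario,
    standing: StandingArchitecture | None,
    generations: int,
    rng: np.random.Generator,
    thin: int = 1,
    record_allele_freqs: bool = False,
    mutation_window: float | None = None,
    full_horizon: bool = False,
    stop_when_large_resolved: bool = False,
    d_stop: float = 1e-3,
) -> Trajectory:
    """Run the hybrid engine from the moment of the shift.

    Parameters
    ----------
    standing : StandingArchitecture or None
        Tracked alleles segregating at the shift (None for none).
    generations : int
        Hard cap on the number of generations.
    thin : int
        Record the series every ``thin`` generations (t=0 and the final
        generation are always recorded).
    mutation_window : float, optional
        Generations during which new tracked mutations are injected; default
        is the adaptation window T_end at which the background-only Lande
        distance reaches delta.  Pass ``math.inf`` for recurrent mutation
        throughout.
    full_horizon : bool
        Disable early stopping (run the full ``generations``).
    stop_when_large_resolved : bool
        Stop as soon as no tracked allele segregates and the mutation window
        has closed (used by fixation-fraction experiments where only allele
        fates matter).

    The run stops early once D < ``d_stop`` (delta units), no tracked allele
    segregates, and the mutation window has closed.  Deterministic given the
    rng state.
    """
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    if standing is None:
        standing = StandingArchitecture.empty()
    window = _mutation_window(scenario) if mutation_window is None else mutation_window
    if scenario.twoNU == 0:
        window = 0.0  # no mutational input: the window is irrelevant
    state = PopulationState.initial(scenario, standing)

    rec_t, rec_D, rec_va, rec_nseg = [], [], [], []
    freq_rows = [] if record_allele_freqs else None

    def record() -> None:
        rec_t.append(state.t)
        rec_D.append(state.D)
        rec_va.append(state.VA_large)
        rec_nseg.append(state.n_segregating)
        if freq_rows is not None:
            al = state.alleles
            seg = al.segregating
            for i in np.flatnonzero(seg | (al.fate_gen == state.t)):
                freq_rows.append((state.t, int(i), float(al.x[i])))

    record()
    for _ in range(generations):
        mutate = state.t < window
        step_hybrid(state, scenario, rng, mutate=mutate)
        if state.t % thin == 0 or state.t == generations:
            record()
        window_closed = state.t >= window
        no_large = state.n_segregating == 0
        if not full_horizon:
            if stop_when_large_resolved and no_large and window_closed:
                break
            if no_large and window_closed and abs(state.D) < d_stop:
                break
    if rec_t[-1] != state.t:
        record()

    series = pd.DataFrame(
        {
            "t": np.asarray(rec_t, dtype=np.int64),
            "D": rec_D,
            "VA_large": rec_va,
            "sigma2": scenario.sigma2,
            "n_segregating": np.asarray(rec_nseg, dtype=np.int64),
        }
    )
    freqs = (
        pd.DataFrame(freq_rows, columns=["t", "allele_id", "x"])
        if freq_rows is not None
        else None
    )
    return Trajectory(series=series, alleles=state.alleles.to_dataframe(),
                      freqs=freqs, scenario=scenario)


def run_polygenic(
    effect_dist,
    Lambda: float,
    N: int,
    generations: int,
    rng: np.random.Generator,
    twoNU: float,
    standing: StandingArchitecture | None = None,
    thin: int = 1,
    record_allele_freqs: bool = False,
    max_segregating: int = 2_000_000,
) -> Trajectory:
    """Fully polygenic engine: every allele of every effect size is tracked.

    There is no deterministic background (sigma2 = 0 in the underlying
    scenario); recurrent mutation continues throughout; D follows the
    bookkeeping identity over all loci.  ``standing`` defaults to a fresh
    MSDB draw via :func:`optimshift.msdb.sample_standing`.
    """
    from .msdb import sample_standing, variance_per_unit_input

    scenario = Scenario(
        Lambda=Lambda,
        sigma2=0.0,
        twoNU=twoNU,
        effect_dist=effect_dist,
        scale=TraitScale(N),
        allow_small=True,
    )
    va_msdb = twoNU * variance_per_unit_input(scenario)
    nodes, weights = effect_dist.quad_nodes()
    typical_se = float(np.sum(weights * nodes))
    if va_msdb < 10.0 * typical_se:
        warnings.warn(
            f"MSDB variance {va_msdb:.3g} is not >> the typical squared "
            f"effect {typical_se:.3g}; the run is not in the highly polygenic "
            "regime",
            UserWarning,
            stacklevel=2,
        )
    if standing is None:
        standing = sample_standing(scenario, rng)
    state = PopulationState.initial(scenario, standing)

    rec_t, rec_D, rec_va, rec_nseg = [], [], [], []
    freq_rows = [] if record_allele_freqs else None

    def record() -> None:
        rec_t.append(state.t)
        rec_D.append(state.D)
        rec_va.append(state.VA_large)
        rec_nseg.append(state.n_segregating)
        if freq_rows is not None:
            al = state.alleles
            for i in np.flatnonzero(al.segregating | (al.fate_gen == state.t)):
                freq_rows.append((state.t, int(i), float(al.x[i])))

    record()
    for _ in range(generations):
        step_hybrid(state, scenario, rng, mutate=True)
        if state.n_segregating > max_segregating:
            raise MemoryError(
                f"segregating allele count exceeded the cap of {max_segregating}"
            )
        if state.t % thin == 0 or state.t == generations:
            record()
    if rec_t[-1] != state.t:
        record()

    series = pd.DataFrame(
        {
            "t": np.asarray(rec_t, dtype=np.int64),
            "D": rec_D,
            "VA_large": rec_va,
            "sigma2": 0.0,
            "n_segregating": np.asarray(rec_nseg, dtype=np.int64),
        }
    )
    freqs = (
        pd.DataFrame(freq_rows, columns=["t", "allele_id", "x"])
        if freq_rows is not None
        else None
    )
    return Trajectory(series=series, alleles=state.alleles.to_dataframe(),
                      freqs=freqs, scenario=scenario)
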