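"""Closed-form and semi-analytic approximations for the post-shift response.

The layer provides:

* Lande's approximation for the mean-phenotype distance, D_L(t) =
  Lambda * exp(-VA t / VS);
* the sign-reversal distance a/2 below which a rare allele of effect a is
  opposed by selection;
* the establishment probability of a rare beneficial allele under the
  time-varying selection induced by the decaying background distance,
  computed from a discrete-generation Poisson branching process;
* a deterministic indicator for whether an established allele reaches
  frequency 1/2 ("crosses the Rubicon") while selection on it is still
  positive, obtained by integrating the expected-change dynamics jointly
  with the distance;
* the resulting fixation probability, approximated as
  establishment x reach-1/2, for standing and new alleles;
* expected numbers of large-effect fixations in the low-input
  (non-interfering) regime, and the regime classification of (a, Lambda).

All quantities are in internal delta units (see :mod:`optimshift.core_units`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_units import ParameterError, Scenario, TraitScale
from .msdb import sojourn_density

__all__ = [
    "lande_distance",
    "sign_reversal_distance",
    "mean_fitness_reduction",
    "adaptation_window",
    "establishment_probability",
    "reaches_half",
    "fixation_probability",
    "fixation_threshold",
    "establishment_probability_standing",
    "expected_fixations",
    "classify_regime",
    "RegimeLabel",
]

#: Fixation probabilities below this are treated as zero when locating regime
#: thresholds; they are far beyond Monte-Carlo resolution in any case.
PROB_EPS = 1e-6

#: Establishment frequency coefficient: x_est = max(x0, C_EST / (2N s0)),
#: the standard drift-selection boundary at which a beneficial allele's
#: ascent becomes quasi-deterministic.
C_EST = 1.0


def lande_distance(t, Lambda: float, VA: float, scale: TraitScale):
    """Distance from the optimum under Lande's approximation.

    D_L(t) = Lambda * exp(-VA t / VS): with constant genetic variance VA the
    mean phenotype approaches the new optimum exponentially at rate VA/VS.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    if VA < 0:
        raise ParameterError("VA must be >= 0")
    out = Lambda * np.exp(-VA * t / scale.vs_internal)
    return float(out) if out.ndim == 0 else out


def sign_reversal_distance(a: float) -> float:
    """Distance a/2 at which selection on a rare allele of effect a reverses.

    For x << 1/2 the expected change is proportional to a D - a^2/2: a rare
    aligned allele is favored iff the population is still further than half
    the allele's own effect from the optimum.
    """
    if a <= 0:
        raise ParameterError("a must be > 0")
    return a / 2.0


def mean_fitness_reduction(Lambda: float, scale: TraitScale, VA: float = 0.0) -> float:
    """Instantaneous mean-fitness reduction after a shift of size Lambda.

    Under the Gaussian fitness function, a population with phenotypic
    variance VA centered at distance Lambda from the optimum has mean fitness
    proportional to exp(-Lambda^2 / (2 (VS + VA))).  The reduction is
    reported relative to a population with the same variance centered at the
    optimum, so the variance-dependent prefactor cancels:

        reduction = 1 - exp(-Lambda^2 / (2 (VS + VA))).

    With VA = 0 this is 1 - exp(-Lambda^2 / 2 VS).
    """
    if Lambda < 0:
        raise ParameterError("Lambda must be >= 0")
    if VA < 0:
        raise ParameterError("VA must be >= 0")
    VS = scale.vs_internal
    return -math.expm1(-Lambda**2 / (2.0 * (VS + VA)))


def adaptation_window(Lambda: float, sigma2: float, scale: TraitScale) -> float:
    """Generations until the background-only Lande distance falls to delta.

    T_end solves Lambda * exp(-sigma2 t / VS) = delta (= 1 internally), i.e.
    T_end = (VS / sigma2) * ln(Lambda).  New mutations arising after T_end
    face a population already within drift distance of the optimum and are
    opposed by selection from birth; the window therefore bounds both the
    new-mutation integral of :func:`fixation_probability` and the hybrid
    engine's mutation injection.
    """
    if Lambda <= 1.0:
        return 0.0
    if sigma2 <= 0:
        raise ParameterError("sigma2 must be > 0 for a finite adaptation window")
    return (scale.vs_internal / sigma2) * math.log(Lambda)


# ---------------------------------------------------------------------------
# establishment: time-inhomogeneous branching approximation
# ---------------------------------------------------------------------------

def _selection_coefficient(a: float, t, scenario: Scenario):
    """Per-copy selective advantage of a rare aligned allele at time t.

    s(t) = (a/VS) (D_L(t) - a/2) with the background-only Lande distance
    D_L(t) = Lambda exp(-sigma2 t / VS): while the allele is rare its own
    contribution to D is negligible, so the decay of D is driven by the
    Fisherian background alone.
    """
    VS = scenario.VS
    D = scenario.Lambda * np.exp(-scenario.sigma2 * np.asarray(t, dtype=float) / VS)
    return (a / VS) * (D - a / 2.0)


def _reversal_time(a: float, scenario: Scenario) -> float:
    """Time at which s(t) crosses zero (inf if it never does)."""
    if scenario.Lambda <= a / 2.0:
        return 0.0
    if scenario.sigma2 <= 0:
        return math.inf
    return (scenario.VS / scenario.sigma2) * math.log(2.0 * scenario.Lambda / a)


def _survival_fixed_point(s: float, tol: float = 1e-14) -> float:
    """Single-copy survival p solving p = 1 - exp(-(1+s) p) (constant s > 0).

    Newton iteration on f(p) = 1 - e^{-(1+s)p} - p; plain fixed-point
    iteration stalls near criticality (small s) where the map's slope
    approaches 1.
    """
    if s <= 0:
        return 0.0
    p = min(1.0, 2.0 * s)
    for _ in range(100):
        e = math.exp(-(1.0 + s) * p)
        f = 1.0 - e - p
        fp = (1.0 + s) * e - 1.0
        step = f / fp
        p_next = p - step
        if not (0.0 < p_next <= 1.0):
            p_next = 0.5 * p
        if abs(p_next - p) < tol * max(p, 1e-30):
            return p_next
        p = p_next
    return p


def _establishment_curve(a: float, scenario: Scenario) -> np.ndarray:
    """Single-copy establishment probability p1(t0) for arrival times t0.

    Backward recursion of the discrete-generation branching process with
    Poisson(1 + s(t)) offspring: p(t) = 1 - exp(-(1 + s(t)) p(t+1)), run
    from the sign-reversal horizon T_rev (a lineage still alive when
    directional selection on it ends has typically grown to many copies
    and counts as established; this survival-to-reversal semantics also
    keeps the conditioned emergent-size law E[W | survive] = 1/p1
    consistent with the branching martingale E[n(t)] = e^{int s}) down to
    t = 0.  Entry [t0] is the survival probability of a single copy
    arising at generation t0; for arrivals close to T_rev "alive at
    reversal" overstates establishment — values there are upper bounds.
    In the constant-selection limit (sigma2 = 0) the recursion collapses
    to the classic fixed point p = 1 - e^{-(1+s)p}.
    """
    if scenario.Lambda <= a / 2.0:
        return np.zeros(1)
    if scenario.sigma2 <= 0:
        return np.array([_survival_fixed_point(_selection_coefficient(a, 0.0, scenario))])
    T = int(math.ceil(_reversal_time(a, scenario)))
    s = _selection_coefficient(a, np.arange(T + 1), scenario)
    p = np.zeros(T + 1)
    p[T] = 1.0
    for t in range(T - 1, -1, -1):
        p[t] = -math.expm1(-(1.0 + s[t]) * p[t + 1])
    return p


def _survival_from_copies(p1: float, copies) -> np.ndarray:
    """P(at least one of ``copies`` independent lineages survives).

    1 - (1 - p1)^copies: exact for integer copy numbers and equal to the
    small-p1 Poissonized form 1 - exp(-copies * p1) to O(copies * p1^2).
    """
    copies = np.asarray(copies, dtype=float)
    if p1 >= 1.0:
        return np.ones_like(copies)
    out = -np.expm1(copies * math.log1p(-p1))
    return out


def establishment_probability(
    a: float, x0: float, scenario: Scenario, t0: int = 0
) -> float:
    """Probability that an allele at frequency x0 escapes stochastic loss.

    The 2N x0 initial copies are treated as independent lineages of the
    branching approximation, so P = 1 - (1 - p1(t0))^(2N x0) with p1 the
    single-copy survival from :func:`_establishment_curve` (equal to
    1 - exp(-2N x0 p1) for small p1).  Returns 0 whenever Lambda <= a/2
    (the allele is opposed from the start).
    """
    if not (0 < x0 < 1):
        raise ParameterError("x0 must lie strictly in (0, 1)")
    if scenario.Lambda <= a / 2.0:
        return 0.0
    curve = _establishment_curve(a, scenario)
    idx = min(int(t0), len(curve) - 1) if scenario.sigma2 > 0 else 0
    p1 = curve[idx]
    return float(_survival_from_copies(p1, 2.0 * scenario.N * x0))


# ---------------------------------------------------------------------------
# deterministic reach-1/2 indicator
# ---------------------------------------------------------------------------

def reaches_half(
    a: float,
    x_start: float,
    scenario: Scenario,
    D0: float | None = None,
) -> tuple[bool, float | None]:
    """Does an established aligned allele reach frequency 1/2 in time?

    Integrates the deterministic system

        dx/dt = (a D / VS - (a^2 / VS)(1/2 - x)) x(1-x)
        dD/dt = -(sigma2 / VS) D - 2a dx/dt

    from (x_start, D0) (D0 defaults to Lambda) and reports whether x crosses
    1/2 while the expected change is still positive, plus the first-crossing
    time.  Past 1/2 stabilizing selection switches sides, so crossing is the
    decisive event of the fixation approximation.
    """
    ok, t_cross, _, _ = _integrate_reach(a, x_start, scenario, D0)
    return ok, t_cross


def _integrate_reach(
    a: float,
    x_start: float,
    scenario: Scenario,
    D0: float | None = None,
):
    """Deterministic (x, D) integration up to the 1/2 crossing.

    Returns (crossed, crossing_time, D_at_crossing, None).
    """
    if not (0 < x_start < 1):
        raise ParameterError("x_start must lie strictly in (0, 1)")
    if a <= 0:
        raise ParameterError("a must be > 0")
    VS = scenario.VS
    D0 = scenario.Lambda if D0 is None else D0
    if x_start >= 0.5:
        return True, 0.0, D0, None

    def growth(x, D):
        return a * D - a * a * (0.5 - x)

    if growth(x_start, D0) <= 0:
        return False, None, None, None

    def rhs(t, y):
        x, D = y
        dx = (growth(x, D) / VS) * x * (1.0 - x)
        dD = -(scenario.sigma2 / VS) * D - 2.0 * a * dx
        return (dx, dD)

    def ev_cross(t, y):
        return y[0] - 0.5

    ev_cross.terminal = True
    ev_cross.direction = 1.0

    def ev_reversal(t, y):
        return growth(y[0], y[1])

    ev_reversal.terminal = True
    ev_reversal.direction = -1.0

    # generous horizon: background decay plus the allele's own sweep time
    t_max = 200.0 * VS / max(scenario.sigma2, 1.0) \
        + 50.0 * VS / (a * a) * math.log(4.0 * scenario.N)
    sol = solve_ivp(
        rhs, (0.0, t_max), (x_start, D0),
        events=(ev_cross, ev_reversal), rtol=1e-8, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            f"reach-1/2 integration failed: {sol.message} "
            f"(a={a}, x_start={x_start}, Lambda={scenario.Lambda})"
        )
    if len(sol.t_events[0]):
        return True, float(sol.t_events[0][0]), float(sol.y_events[0][0][1]), None
    return False, None, None, None


def _establishment_frequency(a: float, s0: float, x0: float, N: int) -> float:
    """x_est = max(x0, C_EST / (2N s0)): seed for the deterministic phase."""
    return max(x0, C_EST / (2.0 * N * s0))


def _post_crossing_fixation(a: float, D_cross: float, scenario: Scenario) -> float:
    """Fixation probability from frequency 1/2 at distance D_cross.

    The diffusion fixation probability u(1/2) with the distance frozen at
    its crossing value: scale density G(y) = exp(Se y(1-y) - 2 a D y), so
    u = int_0^1/2 G / int_0^1 G.  Equals 1/2 at D = 0 — frequency 1/2 is
    then the unstable under-dominant equilibrium and drift decides — and
    approaches 1 once the crossing margin clears the drift scale, i.e.
    when 1/2 - y*(D) >> 1/sqrt(2 Se) with y* the unstable frequency.  This
    replaces the cruder "fixation certain past 1/2": marginal crossers
    (the band just above the critical starting frequency) are the ones it
    discounts.
    """
    Se = a * a
    y = np.linspace(0.0, 1.0, 1025)
    g = Se * y * (1.0 - y) - 2.0 * a * max(D_cross, 0.0) * y
    wgt = np.exp(g - g.max())
    half = len(y) // 2  # y[512] = 0.5 exactly
    num = np.trapezoid(wgt[: half + 1], y[: half + 1])
    den = np.trapezoid(wgt, y)
    return float(num / den)


def _reach_fix_factor(
    a: float, scenario: Scenario, D0: float, x_start: float
) -> float:
    """P(fix | established at x_start): deterministic crossing x u(1/2)."""
    ok, _, D_cross, _ = _integrate_reach(a, x_start, scenario, D0)
    if not ok:
        return 0.0
    return _post_crossing_fixation(a, D_cross, scenario)


_LAGUERRE_NODES, _LAGUERRE_WEIGHTS = np.polynomial.laguerre.laggauss(6)


def _single_copy_fix_factor(
    a: float,
    scenario: Scenario,
    D0: float,
    x_emerge: float,
    x_crit: float,
) -> float:
    """P(fix | survives the branching phase) for a single-copy lineage.

    Conditioned on surviving, a branching lineage emerges from the
    stochastic phase at frequency W * x_emerge with W ~ Exp(1) and
    x_emerge = 1/(2N p1) (so the unconditional mean frequency matches the
    branching expectation).  It crosses iff W x_emerge >= x_crit — factor
    exp(-x_crit / x_emerge) — and the excess above the threshold is again
    Exp(1) by memorylessness; the post-crossing fixation probability is
    averaged over that excess with Gauss-Laguerre quadrature.
    """
    w_thresh = x_crit / x_emerge
    p_cross = math.exp(-w_thresh)
    if p_cross <= 1e-300:
        return 0.0
    acc = 0.0
    for E, wq in zip(_LAGUERRE_NODES, _LAGUERRE_WEIGHTS):
        x_start = min((w_thresh + E) * x_emerge, 0.9999)
        acc += wq * _reach_fix_factor(a, scenario, D0, x_start)
    return p_cross * acc


def _critical_start(a: float, scenario: Scenario, D0: float) -> float:
    """Minimal starting frequency whose deterministic path reaches 1/2.

    Bisection in log frequency; returns inf when no start below 1/2 makes
    it.  The lower bound extends far below 1/2N because the conditioned
    lineage-size law probes sub-single-copy effective starting frequencies.
    The reach indicator is monotone in the starting frequency (starting
    higher at the same distance only helps).
    """
    hi_probe = 0.4999
    if not reaches_half(a, hi_probe, scenario, D0=D0)[0]:
        return math.inf
    lo = 1e-9
    if reaches_half(a, lo, scenario, D0=D0)[0]:
        return 0.0
    hi = hi_probe
    for _ in range(48):
        mid = math.sqrt(lo * hi)
        if reaches_half(a, mid, scenario, D0=D0)[0]:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# fixation probability and derived summaries
# ---------------------------------------------------------------------------

def fixation_probability(
    a: float,
    origin: str,
    scenario: Scenario,
    n_time_nodes: int = 64,
) -> float:
    """Fixation probability of an aligned allele of effect a.

    The approximation composes establishment with the reach-1/2 crossing
    and a post-crossing fixation factor.

    ``origin="standing"``: averaged over the normalized MSDB sojourn density
    of initial frequencies, int tau(x0) P_est(x0) P_reach(x0) dx0.

    ``origin="new"``: averaged over a uniform arrival time in the adaptation
    window [0, T_end], with the single-copy establishment evaluated under
    the time-shifted distance and the reach probability evaluated at D_L(t0).

    Fixation decomposes into surviving the stochastic low-copy phase,
    emerging above the critical deterministic starting frequency x_crit
    (bisection of :func:`reaches_half`), and fixing after the crossing
    (:func:`_post_crossing_fixation`).  Conditioned on survival, the
    n_surv ~ Binomial(2N x0, p1) successful founder lineages emerge from
    the stochastic phase at a combined frequency Gamma(n_surv,
    scale = 1/(2N p1)) — the standard conditioned-branching limit — which
    reduces to the Exp(1) law for a single copy and concentrates at x0 for
    many copies, recovering the sharp deterministic indicator.

    Opposing alleles (orientation -1) never fix; callers accounting for
    random orientation multiply by 1/2.
    """
    if origin not in ("standing", "new"):
        raise ParameterError(f"origin must be 'standing' or 'new', got {origin!r}")
    if scenario.Lambda <= a / 2.0:
        return 0.0
    N = scenario.N
    two_n = 2 * N

    if origin == "standing":
        p1 = _establishment_curve(a, scenario)[0]
        if p1 <= 0:
            return 0.0
        sd = sojourn_density(a * a, scenario.scale)
        x_crit = _critical_start(a, scenario, scenario.Lambda)
        if math.isinf(x_crit):
            return 0.0
        x_emerge = 1.0 / (two_n * p1)
        w = x_crit / x_emerge
        # u(1/2 | crossed) as a function of the starting frequency: the
        # transition from u ~ 1/2 (grazing crossers) to u ~ 1 happens in a
        # narrow band just above x_crit, so the interpolation grid is
        # log-spaced in the excess x - x_crit
        factor_half = _reach_fix_factor(a, scenario, scenario.Lambda, 0.4999)
        excess_lo = max(1e-4 * max(x_crit, x_emerge), 1e-9)
        excess_hi = 0.4999 - x_crit
        excess_nodes = np.geomspace(excess_lo, excess_hi, 16)
        u_nodes = np.array(
            [_reach_fix_factor(a, scenario, scenario.Lambda, x_crit + e)
             for e in excess_nodes]
        )

        def u_of(x):
            x = np.asarray(x, dtype=float)
            ex = np.clip(x - x_crit, excess_lo, excess_hi)
            out = np.interp(np.log(ex), np.log(excess_nodes), u_nodes)
            return np.where(x >= 0.5, factor_half, out)

        from scipy.special import gammaincc
        from scipy.stats import poisson

        # single-founder emergent excess above the crossing threshold is
        # Exp(1) by memorylessness; integrate u over it (Gauss-Laguerre)
        u_single_excess = float(sum(
            wq * u_of(x_emerge * (w + E))
            for E, wq in zip(_LAGUERRE_NODES, _LAGUERRE_WEIGHTS)))

        def fix_prob_copies(k: float) -> float:
            """P(fix) for an allele at frequency k/2N.

            The engine's first binomial update Poisson-thins the 2N x0 = k
            initial copies, so the number of establishing founder lineages
            is Poisson with mean lambda = -k ln(1 - p1), which makes
            P(n_surv >= 1) = 1 - (1 - p1)^k exactly (k need not be an
            integer).  The emergent frequency given j founders is
            Gamma(j, x_emerge); the j = 1 term integrates u over the full
            conditional law (marginal crossers matter there), higher j use
            the conditional mean (their crossing margins are comfortable).
            """
            lam_k = -k * math.log1p(-p1)
            j_hi = int(lam_k + 10 * math.sqrt(lam_k) + 10)
            j = np.arange(1, j_hi + 1)
            pmf = poisson.pmf(j, lam_k)
            cross = gammaincc(j, w)                 # P(Gamma(j) >= w)
            x_rep = x_emerge * (w + j)              # representative emergent freq
            u_vals = u_of(x_rep)
            u_vals[0] = u_single_excess
            return float(np.sum(pmf * cross * u_vals))

        # interpolate over copy number (smooth on log k) for the x0 integral
        k_lo, k_hi = 0.5, two_n - 1.0
        k_nodes = np.exp(np.linspace(math.log(k_lo), math.log(k_hi), 48))
        f_k = np.array([fix_prob_copies(k) for k in k_nodes])

        def integrand(x):
            k = np.clip(two_n * x, k_lo, k_hi)
            return np.interp(np.log(k), np.log(k_nodes), f_k)

        return float(sd.moment(integrand) / sd.total_time)

    # origin == "new"
    T_end = adaptation_window(scenario.Lambda, scenario.sigma2, scenario.scale)
    if T_end <= 0:
        return 0.0
    curve = _establishment_curve(a, scenario)
    t_nodes = np.linspace(0.0, T_end, n_time_nodes)
    vals = np.zeros(n_time_nodes)
    for i, t0 in enumerate(t_nodes):
        s_t = float(_selection_coefficient(a, t0, scenario))
        if s_t <= 0:
            continue
        idx = min(int(t0), len(curve) - 1)
        p_est = curve[idx]
        if p_est <= PROB_EPS:
            continue
        x_emerge = 1.0 / (two_n * p_est)
        if x_emerge >= 0.5:
            # emergence scale beyond the Rubicon: no meaningful
            # establishment is possible this late in the window
            continue
        D_t = scenario.Lambda * math.exp(-scenario.sigma2 * t0 / scenario.VS)
        x_crit = _critical_start(a, scenario, D_t)
        if math.isinf(x_crit):
            continue
        vals[i] = p_est * _single_copy_fix_factor(a, scenario, D_t, x_emerge, x_crit)
    return float(np.trapezoid(vals, t_nodes) / T_end)


def establishment_probability_standing(a: float, scenario: Scenario) -> float:
    """Establishment probability averaged over the MSDB initial frequency."""
    if scenario.Lambda <= a / 2.0:
        return 0.0
    p1 = _establishment_curve(a, scenario)[0]
    sd = sojourn_density(a * a, scenario.scale)
    N = scenario.N
    integral = sd.moment(lambda x: _survival_from_copies(p1, 2.0 * N * x))
    return float(integral / sd.total_time)


def expected_fixations(scenario: Scenario) -> tuple[float, float]:
    """Expected numbers of tracked-allele fixations (standing, new).

    Valid in the non-interfering low-input regime (2NU < 1; warns above):
    each potential fixation is treated independently, so both components are
    linear in 2NU.  Mutations are aligned with the shift with probability
    1/2 and only aligned alleles can fix, hence the factor 1/2.

    from_standing = 2NU * int dist(Se) T_soj(Se) * (1/2) P_fix(standing) dSe
    from_new      = 2NU * T_end * int dist(Se) * (1/2) P_fix(new) dSe
    """
    if scenario.twoNU == 0:
        return 0.0, 0.0
    if scenario.twoNU >= 1:
        warnings.warn(
            f"2NU={scenario.twoNU:.3g} >= 1: selective interference between "
            "large-effect alleles is ignored by this approximation; use the "
            "hybrid engine for the high-input regime",
            UserWarning,
            stacklevel=2,
        )
    nodes, weights = scenario.effect_dist.quad_nodes()
    from_standing = 0.0
    from_new = 0.0
    try:
        T_end = adaptation_window(scenario.Lambda, scenario.sigma2, scenario.scale)
    except ParameterError:
        T_end = 0.0
    for Se, w in zip(nodes, weights):
        a = math.sqrt(Se)
        sd = sojourn_density(Se, scenario.scale)
        from_standing += w * sd.total_time * 0.5 * fixation_probability(a, "standing", scenario)
        if T_end > 0:
            from_new += w * T_end * 0.5 * fixation_probability(a, "new", scenario)
    return scenario.twoNU * from_standing, scenario.twoNU * from_new


def fixation_threshold(
    a: float,
    scenario: Scenario,
    origin: str = "standing",
    prob_eps: float = PROB_EPS,
    n_time_nodes: int = 16,
    max_factor: float = 100.0,
) -> float:
    """Minimal shift size at which the fixation probability exceeds prob_eps.

    Bisection over Lambda starting from the establishment boundary a/2; the
    scenario's own Lambda is ignored.  Returns inf when no shift up to
    ``max_factor * sqrt(VS)`` produces a fixation probability above
    ``prob_eps`` (probabilities below it are treated as zero — they are far
    beyond Monte-Carlo resolution).
    """
    import dataclasses

    def pfix(lam: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            scen = dataclasses.replace(scenario, Lambda=float(lam))
        return fixation_probability(a, origin, scen, n_time_nodes=n_time_nodes)

    lo = a / 2.0
    hi = max(2.0 * a, 2.0 * math.sqrt(scenario.VS))
    while pfix(hi) <= prob_eps:
        hi *= 2.0
        if hi > max_factor * math.sqrt(scenario.VS):
            return math.inf
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if pfix(mid) > prob_eps:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class RegimeLabel:
    """Classification of (allele effect, shift size) into response regimes.

    Labels in order of increasing shift size:
    ``no_establishment`` (Lambda < a/2: opposed from the start),
    ``establish_no_fix`` (establishes but never reaches 1/2),
    ``standing_can_fix`` (high-frequency standing alleles can fix),
    ``most_established_fix`` (nearly every established allele fixes).
    """

    label: str
    thresholds: dict


def classify_regime(
    a: float,
    scenario: Scenario,
    ratio_cutoff: float = 0.9,
    prob_eps: float = PROB_EPS,
) -> RegimeLabel:
    """Classify the scenario's shift size for an allele of effect a.

    Thresholds are the Lambda values at which the label changes, located by
    bisection; fixation probabilities below ``prob_eps`` count as zero.
    """
    if a <= 0:
        raise ParameterError("a must be > 0")

    def with_lambda(lam: float) -> Scenario:
        import dataclasses
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return dataclasses.replace(scenario, Lambda=lam)

    def pfix(lam: float) -> float:
        return fixation_probability(a, "standing", with_lambda(lam))

    def ratio(lam: float) -> float:
        pe = establishment_probability_standing(a, with_lambda(lam))
        return pfix(lam) / pe if pe > 0 else 0.0

    lam_est = a / 2.0
    lam_hi = max(4.0 * a, 2.0 * scenario.Lambda, 2.0 * math.sqrt(scenario.VS))
    lam_fix = fixation_threshold(a, scenario, "standing", prob_eps=prob_eps)
    while math.isfinite(lam_fix) and ratio(lam_hi) <= ratio_cutoff \
            and lam_hi < 100.0 * math.sqrt(scenario.VS):
        lam_hi *= 2.0
    if math.isfinite(lam_fix) and ratio(lam_hi) > ratio_cutoff:
        lo, hi = lam_fix, lam_hi
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            if ratio(mid) > ratio_cutoff:
                hi = mid
            else:
                lo = mid
        lam_yellow = hi
    else:
        lam_yellow = math.inf

    thresholds = {
        "establish": lam_est,
        "standing_fix": lam_fix,
        "most_established_fix": lam_yellow,
    }
    lam = scenario.Lambda
    if lam < lam_est:
        label = "no_establishment"
    elif lam < lam_fix:
        label = "establish_no_fix"
    elif lam < lam_yellow:
        label = "standing_can_fix"
    else:
        label = "most_established_fix"
    return RegimeLabel(label=label, thresholds=thresholds)
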