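"""Independent exact Wright-Fisher oracles for small populations.

Brute-force transition-matrix computations on the full 2N+1 frequency
states, used only by the tests to validate the package's quadrature and
branching approximations.  Deliberately independent of the implementation:
everything here is built from binomial transition kernels and dense linear
algebra.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def transition_matrix(N: int, expected_dx) -> np.ndarray:
    """Full WF transition matrix with deterministic map x -> x + E[dx].

    ``expected_dx(x)`` gives the expected one-generation frequency change;
    row i is Binomial(2N, clip(x_i + E[dx](x_i))).
    """
    two_n = 2 * N
    x = np.arange(two_n + 1) / two_n
    p = np.clip(x + expected_dx(x), 0.0, 1.0)
    j = np.arange(two_n + 1)
    return binom.pmf(j[None, :], two_n, p[:, None])


def absorption_probability(N: int, expected_dx, start_copies: int = 1) -> float:
    """Exact probability of absorption at x = 1 from ``start_copies``."""
    P = transition_matrix(N, expected_dx)
    two_n = 2 * N
    interior = slice(1, two_n)
    Q = P[interior, interior]
    r = P[interior, two_n]  # one-step fixation
    u = np.linalg.solve(np.eye(two_n - 1) - Q, r)
    return float(u[start_copies - 1])


def expected_visits(N: int, expected_dx, start_copies: int = 1) -> np.ndarray:
    """Expected number of generations spent in each interior copy class.

    Returns an array over copy numbers 1..2N-1: the exact discrete analogue
    of the diffusion sojourn-time density for a mutant entering at
    ``start_copies``.
    """
    P = transition_matrix(N, expected_dx)
    two_n = 2 * N
    interior = slice(1, two_n)
    Q = P[interior, interior]
    e = np.zeros(two_n - 1)
    e[start_copies - 1] = 1.0
    # visits_j = sum_t P(X_t = j | X_0 = start) = [e^T (I - Q)^{-1}]_j
    v = np.linalg.solve((np.eye(two_n - 1) - Q).T, e)
    return v


def stabilizing_dx(Se: float, N: int):
    """E[dx] under the stabilizing term only (D = 0), internal units."""
    VS = 2.0 * N

    def f(x):
        return -(Se / VS) * (0.5 - x) * x * (1.0 - x)

    return f


def directional_dx(s: float):
    """E[dx] for plain semi-dominant selection with coefficient s."""

    def f(x):
        return s * x * (1.0 - x)

    return f


def eq1_dx(a: float, D: float, N: int):
    """E[dx] with both selection terms at a fixed distance D (aligned)."""
    VS = 2.0 * N

    def f(x):
        return (a * D / VS - (a * a / VS) * (0.5 - x)) * x * (1.0 - x)

    return f


def poisson_branching_survival(s: float) -> float:
    """Survival probability of a Poisson(1+s) branching process (oracle).

    Root of 1 - e^{-(1+s)p} - p on (0, 1], bracketed and solved by Brent's
    method (independent of the implementation's iteration scheme).
    """
    from scipy.optimize import brentq

    if s <= 0:
        return 0.0
    f = lambda p: 1.0 - np.exp(-(1.0 + s) * p) - p
    # f(eps) > 0 for small eps < root; f(1) < 0
    lo = 1e-12
    while f(lo) <= 0:
        lo *= 10
        if lo > 0.1:
            break
    return float(brentq(f, lo, 1.0, xtol=1e-15))
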