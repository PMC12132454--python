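"""Replicate orchestration and headline summaries.

Runs seeded ensembles of the hybrid engine and reduces them to the
quantities of interest: the long-term contribution of tracked large-effect
fixations to the shift, mutational-input sweeps, and two-dimensional
parameter-grid scans of the fixation probability with Gaussian smoothing.

Seeding: every replicate (and every grid cell) gets an independent stream
derived from the single master seed with ``numpy.random.SeedSequence(seed,
spawn_key=(index,))`` — a counter-based scheme, injective in the index, so
any individual replicate can be reproduced from (seed, index) alone.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .analytic import adaptation_window
from .core_units import ParameterError, Scenario
from .dynamics import Trajectory, run_hybrid
from .msdb import sample_standing, variance_per_unit_input

__all__ = [
    "ReplicateSummary",
    "run_replicates",
    "contribution_fraction",
    "ParameterGrid",
    "grid_scan",
    "smooth_grid",
]


def _replicate_rng(base_seed: int, index: int) -> np.random.Generator:
    """Independent stream number ``index`` derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(index,)))


def contribution_fraction(alleles: pd.DataFrame, Lambda: float) -> float:
    """Fraction of the shift accounted for by tracked-allele fixations.

    A fixation moves the mean phenotype by orientation * 2a * (1 - x_ref)
    with x_ref the pre-shift frequency (x0 for standing alleles, 0 for new
    mutations); the fraction is that mean change summed over fixed alleles,
    divided by Lambda.  Opposing fixations enter with negative sign.
    """
    if Lambda <= 0:
        raise ParameterError("Lambda must be > 0 for a contribution fraction")
    fixed = alleles[alleles["fate"] == "fixed"]
    if fixed.empty:
        return 0.0
    x_ref = np.where(fixed["origin"].to_numpy() == "standing",
                     fixed["x0"].to_numpy(), 0.0)
    shift = fixed["orientation"].to_numpy() * 2.0 * fixed["a"].to_numpy() * (1.0 - x_ref)
    return float(shift.sum() / Lambda)


@dataclass
class ReplicateSummary:
    """Per-replicate table plus aggregate statistics of a seeded ensemble."""

    table: pd.DataFrame       # replicate, n_fixed_large, n_fixed_opposing,
                              # contribution_fraction, time_to_D_below_delta
    scenario: Scenario
    base_seed: int

    @property
    def n_reps(self) -> int:
        return len(self.table)

    def aggregate(self) -> dict:
        out = {}
        for col in ("n_fixed_large", "contribution_fraction", "time_to_D_below_delta"):
            v = self.table[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            out[f"{col}_mean"] = float(np.mean(v)) if len(v) else math.nan
            out[f"{col}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
            out[f"{col}_se"] = (
                float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan
            )
        out["prob_any_fixation"] = float(np.mean(self.table["n_fixed_large"] > 0))
        return out


def _default_generations(scenario: Scenario) -> int:
    """Horizon long enough for the window plus allele resolution."""
    try:
        T_end = adaptation_window(scenario.Lambda, scenario.sigma2, scenario.scale)
    except ParameterError:
        T_end = 0.0
    if not math.isfinite(T_end):
        T_end = 0.0
    return int(6 * T_end) + 20 * scenario.N // 4 + 500


def run_replicates(
    scenario: Scenario,
    n_reps: int,
    base_seed: int,
    generations: int | None = None,
    thin: int = 1,
) -> ReplicateSummary:
    """Run ``n_reps`` independent MSDB-draw + hybrid-engine replicates.

    Each replicate samples a fresh standing architecture at MSDB, runs the
    hybrid engine to resolution, and records the number of tracked fixations,
    the contribution fraction, and the first generation at which |D| drops
    below delta.  Fully reproducible from ``base_seed``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    gens = _default_generations(scenario) if generations is None else generations
    rows = []
    for rep in range(n_reps):
        rng = _replicate_rng(base_seed, rep)
        standing = sample_standing(scenario, rng)
        traj = run_hybrid(scenario, standing, gens, rng, thin=thin)
        al = traj.alleles
        fixed = al[al["fate"] == "fixed"]
        d_series = traj.series
        below = d_series[np.abs(d_series["D"].to_numpy()) < 1.0]
        rows.append(
            {
                "replicate": rep,
                "n_fixed_large": int(len(fixed)),
                "n_fixed_opposing": int((fixed["orientation"] < 0).sum()),
                "contribution_fraction": contribution_fraction(al, scenario.Lambda)
                if scenario.Lambda > 0
                else 0.0,
                "time_to_D_below_delta": float(below["t"].iloc[0])
                if len(below)
                else math.nan,
                "n_alleles_born": int(len(al)),
            }
        )
    return ReplicateSummary(table=pd.DataFrame(rows), scenario=scenario,
                            base_seed=base_seed)


def smooth_grid(values: np.ndarray, bandwidth: float) -> np.ndarray:
    """Separable Gaussian smoothing with reflecting boundaries.

    ``bandwidth`` is the kernel standard deviation in grid cells; 0 returns
    the input unchanged.  Reflection keeps every kernel weight inside the
    domain, so the total mass of the grid is preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    if bandwidth < 0:
        raise ParameterError("bandwidth must be >= 0")
    if bandwidth == 0:
        return values.copy()
    return gaussian_filter(values, sigma=bandwidth, mode="reflect")


_AXIS_NAMES = ("twoNU", "Lambda", "sigma2", "VA0", "p_large")


@dataclass
class ParameterGrid:
    """Two-axis scan specification over trait genetics and ecology.

    ``axes`` maps axis names (two of: twoNU, Lambda, sigma2, VA0, p_large)
    to value arrays.  When the axes are (VA0, p_large), each cell is
    converted to (sigma2, twoNU) via sigma2 = (1-p) VA0 and
    2NU = p VA0 / V1, where V1 is the MSDB tracked-allele variance per unit
    mutational input from quadrature; a cell is flagged invalid when the
    requested large-effect variance is unreachable.
    """

    axes: dict
    base: Scenario
    statistic: str = "fix_prob"   # or "contribution"
    n_reps: int = 100
    bandwidth: float = 1.0
    # filled by grid_scan:
    raw: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    se: np.ndarray | None = None
    invalid: np.ndarray | None = None

    def __post_init__(self):
        if len(self.axes) != 2:
            raise ParameterError("exactly two axes required")
        for name in self.axes:
            if name not in _AXIS_NAMES:
                raise ParameterError(f"unknown axis {name!r}; choose from {_AXIS_NAMES}")
        if self.statistic not in ("fix_prob", "contribution"):
            raise ParameterError("statistic must be 'fix_prob' or 'contribution'")
        if ("VA0" in self.axes) != ("p_large" in self.axes):
            raise ParameterError("VA0 and p_large axes must be used together")

    @property
    def shape(self) -> tuple[int, int]:
        (n1, n2) = (len(v) for v in self.axes.values())
        return (n1, n2)

    def cell_scenario(self, i: int, j: int) -> Scenario | None:
        """Scenario for cell (i, j), or None when infeasible."""
        names = list(self.axes)
        vals = {names[0]: self.axes[names[0]][i], names[1]: self.axes[names[1]][j]}
        updates = {}
        if "VA0" in vals:
            va0, p = float(vals["VA0"]), float(vals["p_large"])
            if not (0 <= p <= 1):
                raise ParameterError("p_large must lie in [0, 1]")
            updates["sigma2"] = (1.0 - p) * va0
            if p == 0:
                updates["twoNU"] = 0.0
            else:
                v1 = variance_per_unit_input(self.base)
                if v1 <= 0:
                    return None
                updates["twoNU"] = p * va0 / v1
        for key in ("twoNU", "Lambda", "sigma2"):
            if key in vals:
                updates[key] = float(vals[key])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return dataclasses.replace(self.base, **updates)

    def to_dataframe(self) -> pd.DataFrame:
        if self.raw is None:
            raise RuntimeError("grid has not been filled; run grid_scan first")
        names = list(self.axes)
        rows = []
        for i, v1 in enumerate(self.axes[names[0]]):
            for j, v2 in enumerate(self.axes[names[1]]):
                rows.append(
                    {
                        names[0]: v1,
                        names[1]: v2,
                        "raw": self.raw[i, j],
                        "smoothed": self.smoothed[i, j],
                        "se": self.se[i, j],
                        "n_reps": self.n_reps,
                        "invalid": bool(self.invalid[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def grid_scan(grid: ParameterGrid, base_seed: int) -> ParameterGrid:
    """Fill a parameter grid with Monte-Carlo cell values.

    Each cell holds the probability that at least one tracked allele fixes
    (``statistic="fix_prob"``) or the mean contribution fraction
    (``statistic="contribution"``), estimated from ``grid.n_reps`` seeded
    replicates; deterministic given ``base_seed``.
    """
    n1, n2 = grid.shape
    raw = np.zeros((n1, n2))
    se = np.zeros((n1, n2))
    invalid = np.zeros((n1, n2), dtype=bool)
    for i in range(n1):
        for j in range(n2):
            scen = grid.cell_scenario(i, j)
            if scen is None:
                invalid[i, j] = True
                raw[i, j] = math.nan
                se[i, j] = math.nan
                continue
            cell_seed = np.random.SeedSequence(base_seed, spawn_key=(i, j))
            summary = run_replicates(
                scen, grid.n_reps,
                base_seed=int(cell_seed.generate_state(1)[0] % 2**31),
            )
            agg = summary.aggregate()
            if grid.statistic == "fix_prob":
                p = agg["prob_any_fixation"]
                raw[i, j] = p
                se[i, j] = math.sqrt(p * (1 - p) / grid.n_reps)
            else:
                raw[i, j] = agg["contribution_fraction_mean"]
                se[i, j] = agg["contribution_fraction_se"]
    filled = dataclasses.replace(grid)
    filled.raw = raw
    filled.invalid = invalid
    filled.se = se
    smoothed = raw.copy()
    finite = np.isfinite(raw)
    if grid.bandwidth > 0 and finite.all():
        smoothed = smooth_grid(raw, grid.bandwidth)
    elif grid.bandwidth > 0:
        # smooth only over the valid region, leaving invalid cells NaN
        filler = np.where(finite, raw, 0.0)
        weight = smooth_grid(finite.astype(float), grid.bandwidth)
        smoothed = np.where(
            finite, smooth_grid(filler, grid.bandwidth) / np.maximum(weight, 1e-12),
            math.nan,
        )
    filled.smoothed = smoothed
    return filled
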