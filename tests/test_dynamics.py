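"""Post-shift engines: moments, bookkeeping, determinism, exact oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from optimshift import (
    PointMassEffects,
    Scenario,
    StandingArchitecture,
    TraitScale,
    delta_x_moments,
    run_hybrid,
    run_polygenic,
    sample_standing,
    step_hybrid,
)
from optimshift.core_units import ParameterError
from optimshift.dynamics import PopulationState
from optimshift.msdb import variance_per_unit_input

from wf_oracle import absorption_probability, eq1_dx


def single_allele(Se, x0, orientation=1):
    return StandingArchitecture(
        np.array([Se]), np.array([orientation], dtype=np.int8), np.array([x0]))


class TestDeltaXMoments:
    def test_neutral_allele(self, scale_5000):
        e, v = delta_x_moments(0.0, 0.3, 50.0, scale_5000)
        assert e == 0.0
        assert v == pytest.approx(0.3 * 0.7 / 10_000)

    def test_worked_value(self, scale_5000):
        """Direct evaluation at a^2=200, x=1/400, D=50."""
        e, _ = delta_x_moments(math.sqrt(200), 0.0025, 50.0, scale_5000)
        assert e == pytest.approx(1.515e-4, rel=1e-3)

    def test_selection_reverses_at_half_effect(self, scale_5000):
        """For a rare allele the sign of E[dx] flips exactly at D = a/2."""
        a = 3.7
        x = 1e-6
        e, _ = delta_x_moments(a, x, a / 2.0, scale_5000)
        # residual drive at finite x is a^2 x / VS, vanishing with x
        assert abs(e) <= a * a * x / scale_5000.vs_internal * x * 1.01
        e_above, _ = delta_x_moments(a, 1e-6, a / 2.0 + 0.1, scale_5000)
        e_below, _ = delta_x_moments(a, 1e-6, a / 2.0 - 0.1, scale_5000)
        assert e_above > 0 > e_below

    def test_rejects_out_of_range_frequency(self, scale_5000):
        with pytest.raises(ParameterError):
            delta_x_moments(1.0, 1.2, 0.0, scale_5000)


class TestHybridEngine:
    def test_background_only_is_exact_lande(self, scale_5000, rng):
        """2NU=0, no alleles: D follows Lambda e^{-sigma2 t / VS} exactly."""
        sc = Scenario(Lambda=80.0, sigma2=400.0, twoNU=0.0,
                      effect_dist=PointMassEffects(200.0), scale=scale_5000)
        traj = run_hybrid(sc, None, 100, rng, full_horizon=True)
        t = traj.series["t"].to_numpy()
        expected = 80.0 * np.exp(-0.04 * t)
        assert np.max(np.abs(traj.series["D"].to_numpy() - expected)) < 1e-10

    def test_fixed_allele_is_absorbing(self, scale_1000, rng):
        sc = Scenario(Lambda=10.0, sigma2=40.0, twoNU=0.0,
                      effect_dist=PointMassEffects(200.0), scale=scale_1000)
        state = PopulationState.initial(sc, single_allele(200.0, 0.5))
        state.alleles.x[0] = 1.0
        state.alleles.fate[0] = 1
        state.D = state.recompute_distance()
        for _ in range(20):
            step_hybrid(state, sc, rng)
        assert state.alleles.x[0] == 1.0
        # a fixation from x0 moves the mean by 2a(1 - x0)
        assert state.alleles.mean_shift_contribution() == pytest.approx(
            2.0 * math.sqrt(200.0) * 0.5)

    def test_bookkeeping_identity_every_generation(self, scale_1000, rng):
        sc = Scenario(Lambda=30.0, sigma2=40.0, twoNU=5.0,
                      effect_dist=PointMassEffects(100.0), scale=scale_1000)
        state = PopulationState.initial(sc, single_allele(200.0, 0.05))
        for _ in range(300):
            step_hybrid(state, sc, rng)
            state.check_bookkeeping(atol=1e-9)

    def test_same_seed_identical_trajectory(self, scale_1000):
        sc = Scenario(Lambda=30.0, sigma2=40.0, twoNU=5.0,
                      effect_dist=PointMassEffects(100.0), scale=scale_1000)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(1234)
            standing = sample_standing(sc, rng)
            runs.append(run_hybrid(sc, standing, 500, rng, thin=1))
        pd.testing.assert_frame_equal(runs[0].series, runs[1].series)
        pd.testing.assert_frame_equal(runs[0].alleles, runs[1].alleles)

    def test_neutral_drift_variance(self, scale_1000, rng):
        """One-generation variance of a neutral allele matches x(1-x)/2N."""
        sc = Scenario(Lambda=0.0, sigma2=0.0, twoNU=0.0,
                      effect_dist=PointMassEffects(0.0), scale=scale_1000,
                      allow_small=True)
        x0, n = 0.3, 10_000
        deltas = np.empty(n)
        for i in range(n):
            state = PopulationState.initial(sc, single_allele(0.0, x0))
            step_hybrid(state, sc, rng)
            deltas[i] = state.alleles.x[0] - x0
        expected = x0 * (1 - x0) / (2 * scale_1000.N)
        assert deltas.var() == pytest.approx(expected, rel=0.05)

    def test_fixed_d_absorption_matches_wf_matrix(self, rng):
        """Binomial updates at frozen D reproduce exact absorption odds."""
        N, a, D = 50, 4.0, 6.0
        scale = TraitScale(N)
        exact = absorption_probability(N, eq1_dx(a, D, N), start_copies=1)
        two_n = 2 * N
        reps = 10_000
        x = np.full(reps, 1.0 / two_n)
        VS = 2.0 * N
        active = np.ones(reps, dtype=bool)
        for _ in range(4000):
            if not active.any():
                break
            xa = x[active]
            ex = xa + (a * D / VS - (a * a / VS) * (0.5 - xa)) * xa * (1 - xa)
            x[active] = rng.binomial(two_n, np.clip(ex, 0, 1)) / two_n
            active &= (x > 0) & (x < 1)
        fixed = np.mean(x >= 1.0)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(fixed - exact) < 3 * se

    def test_early_acceleration_late_slowdown(self, scale_1000):
        """High mutational input: replicate-mean D first undershoots, then
        overshoots, Lande's curve with the total initial variance."""
        with pytest.warns(UserWarning):
            sc = Scenario(Lambda=80.0, sigma2=40.0, twoNU=10.0,
                          effect_dist=PointMassEffects(200.0), scale=scale_1000)
        va0 = sc.sigma2 + sc.twoNU * variance_per_unit_input(sc)
        rng = np.random.default_rng(42)
        T = 300
        acc = np.zeros(T + 1)
        n_reps = 30
        for _ in range(n_reps):
            standing = sample_standing(sc, rng)
            traj = run_hybrid(sc, standing, T, rng, full_horizon=True)
            acc += traj.series["D"].to_numpy()[: T + 1]
        mean_d = acc / n_reps
        t = np.arange(T + 1)
        lande_total = 80.0 * np.exp(-va0 * t / sc.VS)
        assert mean_d[20] < lande_total[20]      # variance boost
        assert mean_d[150] > lande_total[150]    # interference slowdown


class TestPolygenicEngine:
    def test_distance_fluctuates_at_delta_scale_without_shift(self):
        rng = np.random.default_rng(3)
        traj = run_polygenic(PointMassEffects(2.0), Lambda=0.0, N=500,
                             generations=2500, rng=rng, twoNU=50.0)
        d = traj.series["D"].to_numpy()
        assert np.mean(np.abs(d)) < 3.0  # of order delta (= 1)

    def test_tracks_lande_while_distance_large(self):
        """Replicate-mean D follows Lande at the MSDB variance within 10%.

        VA/VS ~ 0.04 per generation, small enough that the continuous
        exponential is a fair description of the discrete dynamics over
        the comparison window.
        """
        rng = np.random.default_rng(4)
        T, n_reps = 150, 25
        acc = np.zeros(T + 1)
        for _ in range(n_reps):
            traj = run_polygenic(PointMassEffects(1.0), Lambda=40.0, N=1000,
                                 generations=T, rng=rng, twoNU=50.0)
            acc += traj.series["D"].to_numpy()[: T + 1]
        mean_d = acc / n_reps
        sc = Scenario(Lambda=40.0, sigma2=0.0, twoNU=50.0,
                      effect_dist=PointMassEffects(1.0),
                      scale=TraitScale(1000), allow_small=True)
        va = 50.0 * variance_per_unit_input(sc)
        t = np.arange(T + 1)
        lande = 40.0 * np.exp(-va * t / 2000.0)
        mask = mean_d > 5.0
        rel = np.abs(mean_d[mask] - lande[mask]) / lande[mask]
        assert rel.max() < 0.10

    def test_aligned_alleles_fix_preferentially(self):
        """Standing small-effect alleles aligned with the shift fix more."""
        rng = np.random.default_rng(5)
        fixed_aligned = n_aligned = fixed_opposing = n_opposing = 0
        for _ in range(8):
            traj = run_polygenic(PointMassEffects(2.0), Lambda=30.0, N=500,
                                 generations=3000, rng=rng, twoNU=30.0)
            al = traj.alleles
            standing = al[al["origin"] == "standing"]
            fixed = (standing["fate"] == "fixed").to_numpy()
            aligned = (standing["orientation"] > 0).to_numpy()
            fixed_aligned += int((fixed & aligned).sum())
            n_aligned += int(aligned.sum())
            fixed_opposing += int((fixed & ~aligned).sum())
            n_opposing += int((~aligned).sum())
        pa = fixed_aligned / n_aligned
        po = fixed_opposing / n_opposing
        pooled = (fixed_aligned + fixed_opposing) / (n_aligned + n_opposing)
        z = (pa - po) / math.sqrt(
            pooled * (1 - pooled) * (1 / n_aligned + 1 / n_opposing))
        assert z > 2.33  # one-sided 1%

    def test_memory_guard(self):
        rng = np.random.default_rng(6)
        with pytest.raises(MemoryError):
            run_polygenic(PointMassEffects(0.5), Lambda=0.0, N=200,
                          generations=2000, rng=rng, twoNU=100.0,
                          max_segregating=50)
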