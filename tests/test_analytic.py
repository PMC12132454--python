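"""Analytic layer: Lande decay, establishment, reach-1/2, regimes."""

import dataclasses
import math
import warnings

import numpy as np
import pytest

from optimshift import (
    PointMassEffects,
    Scenario,
    TraitScale,
    adaptation_window,
    classify_regime,
    establishment_probability,
    establishment_probability_standing,
    expected_fixations,
    fixation_probability,
    fixation_threshold,
    lande_distance,
    mean_fitness_reduction,
    reaches_half,
    sign_reversal_distance,
)
from optimshift.analytic import _survival_fixed_point
from optimshift.core_units import ParameterError

from wf_oracle import (
    absorption_probability,
    directional_dx,
    eq1_dx,
    poisson_branching_survival,
)


def scenario(Lambda, sigma2=40.0, N=1000, Se=200.0, twoNU=0.0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return Scenario(Lambda=Lambda, sigma2=sigma2, twoNU=twoNU,
                        effect_dist=PointMassEffects(Se), scale=TraitScale(N))


class TestLandeDistance:
    def test_initial_condition(self, scale_5000):
        assert lande_distance(0.0, 80.0, 400.0, scale_5000) == 80.0

    def test_no_variance_no_adaptation(self, scale_5000):
        t = np.array([0.0, 10.0, 1e4])
        assert np.all(lande_distance(t, 80.0, 0.0, scale_5000) == 80.0)

    def test_e_folding(self, scale_5000):
        # VA/VS = 0.04, so t=25 is one e-fold
        assert lande_distance(25.0, 80.0, 400.0, scale_5000) == pytest.approx(
            80.0 * math.exp(-1.0))

    def test_rejects_negative_inputs(self, scale_5000):
        with pytest.raises(ParameterError):
            lande_distance(-1.0, 80.0, 400.0, scale_5000)
        with pytest.raises(ParameterError):
            lande_distance(1.0, 80.0, -1.0, scale_5000)


class TestSignReversal:
    def test_half_effect(self):
        assert sign_reversal_distance(math.sqrt(200.0)) == pytest.approx(
            7.0710678, rel=1e-6)

    def test_consistent_with_moments(self, scale_5000):
        from optimshift import delta_x_moments

        a = math.sqrt(200.0)
        x = 1e-6
        e, _ = delta_x_moments(a, x, sign_reversal_distance(a), scale_5000)
        # at finite x the residual drive is a^2 x / VS, vanishing with x
        assert abs(e) <= a * a * x / scale_5000.vs_internal * x * (1 - x) * 1.01


class TestMeanFitnessReduction:
    def test_no_shift_no_reduction(self, scale_5000):
        assert mean_fitness_reduction(0.0, scale_5000) == 0.0

    def test_reference_shift(self, scale_5000):
        """Shift of 0.8 sqrt(VS) costs ~27% of mean fitness."""
        lam = 0.8 * math.sqrt(scale_5000.vs_internal)
        assert mean_fitness_reduction(lam, scale_5000) == pytest.approx(
            1.0 - math.exp(-0.32), abs=1e-12)

    def test_sqrt_two_vs_shift(self, scale_5000):
        lam = math.sqrt(2.0 * scale_5000.vs_internal)
        assert mean_fitness_reduction(lam, scale_5000) == pytest.approx(
            1.0 - math.exp(-1.0))

    def test_phenotypic_variance_softens_selection(self, scale_5000):
        lam = 50.0
        assert mean_fitness_reduction(lam, scale_5000, VA=400.0) < \
            mean_fitness_reduction(lam, scale_5000, VA=0.0)


class TestAdaptationWindow:
    def test_shift_at_delta_scale_gives_zero(self, scale_5000):
        assert adaptation_window(1.0, 40.0, scale_5000) == 0.0

    def test_closed_form(self, scale_5000):
        # (VS / sigma2) ln(Lambda) = 250 ln(100)
        assert adaptation_window(100.0, 40.0, scale_5000) == pytest.approx(
            250.0 * math.log(100.0))

    def test_doubling_variance_halves_window(self, scale_5000):
        w1 = adaptation_window(50.0, 40.0, scale_5000)
        w2 = adaptation_window(50.0, 80.0, scale_5000)
        assert w1 == pytest.approx(2.0 * w2)


class TestEstablishment:
    def test_blue_region_zero(self):
        a = math.sqrt(200.0)
        sc = scenario(Lambda=0.49 * a)
        assert establishment_probability(a, 0.01, sc) == 0.0

    def test_constant_s_classic_limit(self):
        """sigma2=0, single copy: P solves the Poisson-branching fixed point,
        ~ 1 - e^{-2s} ~ 2s for small s."""
        N = 5000
        a, lam = 1.0, 3.0  # s = (a/VS)(lam - a/2) = 2.5e-4
        sc = Scenario(Lambda=lam, sigma2=0.0, twoNU=0.0,
                      effect_dist=PointMassEffects(1.0),
                      scale=TraitScale(N), allow_small=True)
        s = (a / sc.VS) * (lam - a / 2.0)
        p = establishment_probability(a, 1.0 / (2 * N), sc)
        assert p == pytest.approx(-math.expm1(-2.0 * s), rel=0.01)
        assert p == pytest.approx(poisson_branching_survival(s), rel=1e-6)

    def test_constant_s_matches_wf_matrix(self):
        """Branching survival vs exact WF absorption at N=50, within 5%."""
        for s in (0.05, 0.1, 0.2):
            exact = absorption_probability(50, directional_dx(s))
            assert _survival_fixed_point(s) == pytest.approx(exact, rel=0.05)

    def test_full_moments_frozen_d_matches_wf_matrix(self):
        """Establishment under both selection terms at fixed D, N=50."""
        N, a, lam = 50, 4.0, 6.0
        sc = Scenario(Lambda=lam, sigma2=0.0, twoNU=0.0,
                      effect_dist=PointMassEffects(16.0),
                      scale=TraitScale(N), allow_small=True)
        for copies in (1, 5):
            exact = absorption_probability(N, eq1_dx(a, lam, N), copies)
            approx = establishment_probability(a, copies / (2 * N), sc)
            assert approx == pytest.approx(exact, rel=0.05)

    def test_decreases_with_arrival_time(self):
        """Later arrivals face a smaller distance: establishment declines.

        Probed over the first two thirds of the directional window; close
        to the reversal horizon the survival-to-reversal construction only
        bounds establishment from above (see _establishment_curve).
        """
        a = math.sqrt(200.0)
        sc = scenario(Lambda=50.0)
        probs = [establishment_probability(a, 1 / 2000, sc, t0=t)
                 for t in (0, 20, 40, 60)]
        assert all(p1 >= p2 for p1, p2 in zip(probs, probs[1:]))
        assert probs[0] > probs[-1]


class TestReachesHalf:
    def test_starting_at_half_trivially_true(self):
        ok, t = reaches_half(math.sqrt(200.0), 0.5, scenario(Lambda=50.0))
        assert ok and t == 0.0

    def test_barely_above_blue_region_fails(self):
        """Just past a/2 the allele establishes but never crosses 1/2."""
        a = math.sqrt(200.0)
        sc = scenario(Lambda=0.51 * a)
        ok, t = reaches_half(a, 0.01, sc)
        assert not ok and t is None

    def test_more_background_variance_never_helps(self):
        """Raising sigma2 can flip reach true->false, never false->true."""
        a = math.sqrt(200.0)
        for lam in (20.0, 30.0, 40.0):
            for x0 in (0.005, 0.02, 0.1):
                reached = [
                    reaches_half(a, x0, scenario(Lambda=lam, sigma2=s2))[0]
                    for s2 in (10.0, 40.0, 80.0, 160.0)
                ]
                # once False, stays False as sigma2 grows
                assert all(b or not a_ for a_, b in zip(reached[1:], reached))


class TestFixationProbability:
    def test_blue_region_zero_for_both_origins(self):
        a = math.sqrt(200.0)
        sc = scenario(Lambda=0.45 * a)
        assert fixation_probability(a, "standing", sc) == 0.0
        assert fixation_probability(a, "new", sc) == 0.0

    def test_bounded_by_establishment(self):
        a = math.sqrt(200.0)
        for lam in (30.0, 40.0, 60.0):
            sc = scenario(Lambda=lam)
            assert 0.0 <= fixation_probability(a, "standing", sc) <= \
                establishment_probability_standing(a, sc) + 1e-12

    def test_monotone_in_shift_size(self):
        a = math.sqrt(200.0)
        probs = [fixation_probability(a, "standing", scenario(Lambda=lam))
                 for lam in (10.0, 25.0, 32.0, 40.0, 55.0)]
        assert all(p1 <= p2 + 1e-9 for p1, p2 in zip(probs, probs[1:]))

    def test_new_allele_threshold_exceeds_standing(self):
        """A new mutation starts from one copy: it needs a larger shift."""
        a = math.sqrt(200.0)
        sc = scenario(Lambda=30.0)
        th_standing = fixation_threshold(a, sc, "standing")
        th_new = fixation_threshold(a, sc, "new")
        assert th_new > th_standing > a / 2.0


class TestExpectedFixations:
    def test_no_input_no_fixations(self):
        sc = scenario(Lambda=40.0, twoNU=0.0)
        assert expected_fixations(sc) == (0.0, 0.0)

    def test_linear_in_mutational_input(self):
        sc1 = scenario(Lambda=40.0, twoNU=0.02)
        sc2 = scenario(Lambda=40.0, twoNU=0.01)
        s1, n1 = expected_fixations(sc1)
        s2, n2 = expected_fixations(sc2)
        assert s1 == pytest.approx(2.0 * s2, rel=1e-9)
        assert n1 == pytest.approx(2.0 * n2, rel=1e-9)

    def test_large_shift_favors_new_mutations(self):
        """Deep in the red region most fixations arise from new alleles."""
        sc = scenario(Lambda=80.0, twoNU=0.01, N=1000)
        from_standing, from_new = expected_fixations(sc)
        assert from_new > from_standing > 0.0

    def test_high_input_warns(self):
        sc = scenario(Lambda=40.0, twoNU=2.0)
        with pytest.warns(UserWarning, match="interference"):
            expected_fixations(sc)


class TestRegimeClassification:
    def test_blue_label_below_half_effect(self):
        a = math.sqrt(200.0)
        regime = classify_regime(a, scenario(Lambda=0.49 * a))
        assert regime.label == "no_establishment"
        assert regime.thresholds["establish"] == pytest.approx(a / 2.0)

    def test_purple_label_between_thresholds(self):
        a = math.sqrt(200.0)
        regime = classify_regime(a, scenario(Lambda=10.0))
        assert regime.label == "establish_no_fix"

    def test_red_label_above_fixation_threshold(self):
        a = math.sqrt(200.0)
        regime = classify_regime(a, scenario(Lambda=40.0))
        assert regime.label in ("standing_can_fix", "most_established_fix")
        ths = regime.thresholds
        assert a / 2.0 < ths["standing_fix"] <= ths["most_established_fix"]

    def test_fixation_onset_moves_right_with_background_variance(self):
        a = math.sqrt(200.0)
        th40 = fixation_threshold(a, scenario(Lambda=30.0, sigma2=40.0))
        th80 = fixation_threshold(a, scenario(Lambda=30.0, sigma2=80.0))
        assert th80 > th40
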