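"""Genotype-frequency recursion: gamete pools, fixed points, equilibria,
sweeps and invasion thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolbsex.dynamics import (
    GenotypeState,
    NoFemalesError,
    NoMalesError,
    STANDARD_XY_XX,
    TransmissionRates,
    female_gametes,
    invasion_threshold,
    iterate_to_equilibrium,
    leading_eigenvalue,
    male_gametes,
    next_generation,
    persistence_threshold,
    perturbed_start,
    summarize_state,
    sweep_alpha,
    trajectory,
)

NO_TRANSMISSION = TransmissionRates(0, 0, 0)


class TestGametePools:
    @pytest.mark.parametrize(
        "state, p1, p3",
        [
            (GenotypeState(g1=0.5, g2=0.5), 0.5, 0.5),
            (GenotypeState(g3=0.5, g2=0.5), 1.0, 0.0),
            # hand arithmetic on the pool formula
            (
                GenotypeState(g1=0.15, g3=0.28, g2=0.57),
                (0.075 + 0.28) / 0.43,
                0.075 / 0.43,
            ),
        ],
    )
    def test_sperm_pool(self, state, p1, p3):
        pools = male_gametes(state)
        assert pools.p1 == pytest.approx(p1)
        assert pools.p3 == pytest.approx(p3)
        assert pools.p1 + pools.p3 == pytest.approx(1.0, abs=1e-12)

    def test_no_males_is_an_error(self):
        with pytest.raises(NoMalesError):
            male_gametes(GenotypeState(g2=1.0))

    @pytest.mark.parametrize(
        "state, rates, expected",
        [
            # only uninfected XX mothers: all eggs uninfected X
            (GenotypeState(g1=0.5, g2=0.5), NO_TRANSMISSION, (1, 0, 0, 0)),
            # fully transmitting XX.Wo+ mothers: all eggs infected X
            (GenotypeState(g1=0.5, g4=0.5), TransmissionRates(1, 0, 0), (0, 0, 1, 0)),
            # XY.Wo+ mothers at t_XY=0.8: (1-t)/2 and t/2 splits
            (
                GenotypeState(g1=0.5, g6=0.5),
                TransmissionRates(0, 0.8, 0),
                (0.1, 0.1, 0.4, 0.4),
            ),
        ],
    )
    def test_egg_pool(self, state, rates, expected):
        pools = female_gametes(state, rates)
        got = (pools.p2, pools.p4, pools.p6, pools.p8)
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    def test_no_females_is_an_error(self):
        with pytest.raises(NoFemalesError):
            female_gametes(GenotypeState(g1=1.0), NO_TRANSMISSION)


class TestNextGeneration:
    def test_standard_population_is_a_fixed_point(self):
        for rates in (NO_TRANSMISSION, TransmissionRates(0.7, 0.3, 0.9)):
            nxt = next_generation(STANDARD_XY_XX, rates)
            assert nxt.as_array() == pytest.approx(STANDARD_XY_XX.as_array(), abs=1e-12)

    def test_full_blocked_transmission_fixed_point(self):
        # YY males, infected XY and YY females in 1/2:1/4:1/4 proportions
        state = GenotypeState(g3=0.5, g6=0.25, g8=0.25)
        nxt = next_generation(state, TransmissionRates(1, 1, 0))
        assert nxt.as_array() == pytest.approx(state.as_array(), abs=1e-12)

    def test_no_transmission_means_no_infected_offspring(self):
        state = GenotypeState(g1=0.3, g2=0.2, g3=0.1, g4=0.2, g6=0.1, g8=0.1)
        nxt = next_generation(state, NO_TRANSMISSION)
        assert nxt.g4 == nxt.g6 == nxt.g8 == 0.0

    @given(
        g=st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
        t=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_positivity(self, g, t):
        arr = np.asarray(g) / sum(g)
        state = GenotypeState.from_array(arr)
        nxt = next_generation(state, TransmissionRates(*t))
        out = nxt.as_array()
        assert np.all(out >= -1e-15)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)


class TestEquilibrium:
    def test_subthreshold_blocked_run_loses_distorter_at_25_75(self):
        res = iterate_to_equilibrium(
            perturbed_start(0.01), TransmissionRates.from_alpha(0.4, "blocked")
        )
        assert res.converged and res.distorter_lost
        assert res.distorter_freq == 0.0
        assert sorted([res.x_freq, res.y_freq]) == pytest.approx([0.25, 0.75], abs=1e-9)

    def test_full_blocked_transmission_reaches_known_interior_point(self):
        res = iterate_to_equilibrium(
            perturbed_start(0.01), TransmissionRates.from_alpha(1.0, "blocked")
        )
        assert res.distorter_freq == pytest.approx(0.5, abs=1e-9)
        assert res.x_freq == pytest.approx(0.125, abs=1e-9)
        assert res.female_freq == pytest.approx(0.5, abs=1e-9)
        assert res.state.as_array() == pytest.approx(
            np.array([0, 0, 0.5, 0, 0.25, 0.25]), abs=1e-9
        )

    def test_uninfected_population_converges_immediately(self):
        res = iterate_to_equilibrium(STANDARD_XY_XX, NO_TRANSMISSION, max_gen=5)
        assert res.converged and res.generations == 1

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            iterate_to_equilibrium(STANDARD_XY_XX, NO_TRANSMISSION, tol=0)
        with pytest.raises(ValueError):
            iterate_to_equilibrium(STANDARD_XY_XX, NO_TRANSMISSION, max_gen=0)


class TestSummaries:
    def test_standard_population_copy_counts_and_doses(self):
        x, y, d, f, dose = summarize_state(STANDARD_XY_XX)
        assert (x, y, d, f) == pytest.approx((0.75, 0.25, 0.0, 0.5))
        # one Y dose to three X doses to four autosome doses per mating pair
        assert dose.y_dose == pytest.approx(1.0)
        assert dose.x_dose == pytest.approx(3.0)
        assert dose.autosome_dose == 4.0
        assert dose.y_to_a == pytest.approx(0.25)
        assert dose.y_to_x == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "state, x_freq",
        [
            (GenotypeState(g3=0.5, g8=0.5), 0.0),
            (GenotypeState(g3=0.5, g6=0.25, g8=0.25), 0.125),
        ],
    )
    def test_copy_counting(self, state, x_freq):
        x, y, *_ = summarize_state(state)
        assert x == pytest.approx(x_freq, abs=1e-12)
        assert x + y == pytest.approx(1.0, abs=1e-12)


class TestSweepAndTrajectory:
    def test_blocked_sweep_bounds(self):
        grid = np.arange(0, 1.0001, 0.05)
        table = sweep_alpha("blocked", grid)
        assert len(table) == len(grid)
        assert table["x_freq"].min() == pytest.approx(0.125, abs=1e-6)
        assert table["distorter_freq"].max() == pytest.approx(0.5, abs=1e-6)
        # balanced sex ratio at equilibrium everywhere on the blocked sweep
        assert np.allclose(table["female_freq"], 0.5, atol=1e-6)

    def test_uniform_high_alpha_drives_x_loss(self):
        res = iterate_to_equilibrium(
            perturbed_start(0.01),
            TransmissionRates.from_alpha(0.9, "uniform"),
            max_gen=20_000,
        )
        assert res.x_freq < 1e-3

    def test_uniform_full_transmission_is_singular(self):
        # at exactly alpha=1 every egg is infected: males (and with them the
        # uninfected classes) vanish and the population tends to all-infected
        # females, X/Y frozen at 1/2 among the survivors
        res = iterate_to_equilibrium(
            perturbed_start(0.01), TransmissionRates.from_alpha(1.0, "uniform"),
            max_gen=5000,
        )
        assert res.female_freq > 0.999
        assert res.x_freq == pytest.approx(0.5, abs=1e-6)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sweep_alpha("blocked", [0.5, 1.2])

    def test_trajectory_shape_and_flat_series(self):
        t = trajectory(STANDARD_XY_XX, NO_TRANSMISSION, 10)
        assert len(t) == 11
        assert t["female_freq"].nunique() == 1
        assert t["distorter_freq"].eq(0).all()

    def test_blocked_trajectory_restores_balanced_sex_ratio(self):
        t = trajectory(perturbed_start(0.01), TransmissionRates(0.9, 0.9, 0.0), 400)
        assert t["female_freq"].iloc[-1] == pytest.approx(0.5, abs=1e-6)

    def test_uniform_trajectory_biases_sex_ratio_toward_females(self):
        t = trajectory(perturbed_start(0.01), TransmissionRates(0.9, 0.9, 0.9), 400)
        assert t["female_freq"].iloc[-1] > 0.5


class TestInvasionThreshold:
    def test_uniform_threshold_is_one_half(self):
        alpha, eig = invasion_threshold("uniform", tol=1e-10)
        assert alpha == pytest.approx(0.5, abs=1e-8)
        # leading eigenvalue of the uniform linearization is 2*alpha
        assert eig(0.25) == pytest.approx(0.5, abs=1e-12)

    def test_blocked_threshold_is_two_minus_sqrt_two(self):
        alpha, _ = invasion_threshold("blocked", tol=1e-10)
        assert alpha == pytest.approx(2 - math.sqrt(2), abs=1e-8)

    def test_zero_rate_cannot_invade(self):
        assert leading_eigenvalue(0.0, "uniform") == pytest.approx(0.0, abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            invasion_threshold("diagonal")

    @pytest.mark.parametrize("mode", ["blocked", "uniform"])
    def test_threshold_separates_loss_from_persistence(self, mode):
        thr, _ = invasion_threshold(mode, tol=1e-9)
        lo = TransmissionRates.from_alpha(thr - 0.02, mode)
        hi = TransmissionRates.from_alpha(min(thr + 0.02, 1.0), mode)
        start = perturbed_start(1e-4)
        assert iterate_to_equilibrium(start, lo, max_gen=200_000).distorter_lost
        assert not iterate_to_equilibrium(start, hi, max_gen=200_000).distorter_lost

    def test_no_hysteresis_in_blocked_mode(self):
        # persistence from a 1%-infected start matches the linear threshold
        pers = persistence_threshold("blocked", eps=0.01, grid_tol=0.005)
        assert pers == pytest.approx(2 - math.sqrt(2), abs=0.01)
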