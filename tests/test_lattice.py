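"""Lattice model: rates, division bookkeeping, Gillespie dynamics."""

import numpy as np
import pytest
from scipy import stats

from consortia.lattice import (
    BLUE,
    H,
    ORANGE,
    V,
    DivisionEvent,
    LMParams,
    LatticeState,
    apply_division,
    effective_rotation_probability,
    ensemble_fractions,
    gillespie_step,
    growth_rates,
    horizontal_growth_propensity,
    make_lattice,
    simulate_lm,
)


def grid_state(strain, orient, time=0.0):
    return LatticeState(
        np.array(strain, dtype=np.int8), np.array(orient, dtype=np.int8), time
    )


class TestGrowthRates:
    def test_flat_landscape_at_zero_kappa(self):
        r = growth_rates(3, 7, V, LMParams(M=5, N=10, lam=2.0, kappa=0.0))
        assert r == pytest.approx((2.0, 2.0, 2.0, 2.0))

    def test_top_row_grows_upward_at_base_rate(self):
        r = growth_rates(5, 1, V, LMParams(M=5, N=10, lam=1.0, kappa=0.7))
        assert r.v_plus == pytest.approx(1.0)

    def test_interior_row_rates(self):
        r = growth_rates(2, 1, V, LMParams(M=5, N=5, lam=1.0, kappa=0.5))
        assert r.v_plus == pytest.approx(np.exp(-1.5), rel=1e-12)
        assert r.v_minus == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_out_of_lattice_rejected(self):
        with pytest.raises(ValueError):
            growth_rates(0, 1, V, LMParams(M=5, N=5))
        with pytest.raises(ValueError):
            growth_rates(1, 6, H, LMParams(M=5, N=5))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LMParams(lam=-1.0)
        with pytest.raises(ValueError):
            LMParams(kappa=-0.1)
        with pytest.raises(ValueError):
            LMParams(p_rot=(0.0, 1.5))


class TestRotationProbability:
    def test_uniform_neighborhood_returns_intrinsic(self):
        state = grid_state(np.full((5, 5), ORANGE), np.zeros((5, 5)))
        p = effective_rotation_probability(state, (2, 2), LMParams(M=5, N=5, p_rot=(0.1, 0.5)))
        assert p == pytest.approx(0.5)

    def test_interior_mean_over_nine(self):
        strain = np.full((3, 3), BLUE)
        strain[1, 1] = ORANGE
        state = grid_state(strain, np.zeros((3, 3)))
        p = effective_rotation_probability(state, (1, 1), LMParams(M=3, N=3, p_rot=(0.1, 0.5)))
        assert p == pytest.approx((0.5 + 8 * 0.1) / 9)

    def test_corner_averages_existing_cells_only(self):
        state = grid_state(np.full((4, 4), BLUE), np.zeros((4, 4)))
        p = effective_rotation_probability(state, (0, 0), LMParams(M=4, N=4, p_rot=(0.3, 0.9)))
        assert p == pytest.approx(0.3)  # mean of 4 identical values


class TestApplyDivision:
    def test_row_shift_drops_boundary_cell(self):
        # 1x3 row [a, b, c]; horizontal b divides rightward without rotation
        state = grid_state([[0, 1, 0]], [[H, H, H]])
        apply_division(state, DivisionEvent((0, 1), "right", H, 0.1))
        assert state.strain.tolist() == [[0, 1, 1]]  # c removed
        assert state.time == pytest.approx(0.1)

    def test_boundary_mother_loses_second_daughter(self):
        state = grid_state([[0, 1, 0]], [[H, H, H]])
        apply_division(state, DivisionEvent((0, 2), "right", H, 0.1))
        assert state.strain.tolist() == [[0, 1, 0]]  # unchanged

    def test_column_shift_with_rotation(self):
        state = grid_state([[0], [1], [0]], [[V], [V], [V]])
        apply_division(state, DivisionEvent((1, 0), "up", H, 0.1))
        assert state.strain[:, 0].tolist() == [0, 1, 1]
        assert state.orient[:, 0].tolist() == [V, V, H]  # new top cell rotated

    def test_direction_must_match_orientation(self):
        state = grid_state([[0, 0]], [[V, V]])
        with pytest.raises(ValueError):
            apply_division(state, DivisionEvent((0, 0), "right", H, 0.1))

    def test_occupancy_conserved_over_many_events(self, rng):
        params = LMParams(M=6, N=9, lam=1.0, kappa=0.1, p_rot=(0.3, 0.3))
        state = make_lattice(params, "random-mixed", rng)
        for _ in range(300):
            event, _ = gillespie_step(state, params, rng)
            apply_division(state, event)
            assert state.strain.shape == (6, 9)
            assert set(np.unique(state.orient)) <= {V, H}


class TestGillespieStep:
    def test_total_rate_and_mean_waiting_time(self, rng):
        params = LMParams(M=4, N=5, lam=1.5, kappa=0.0)
        state = make_lattice(params, "random-mixed", rng)
        dts = [gillespie_step(state, params, rng)[1] for _ in range(4000)]
        # R = 2 * lam * M * N regardless of orientations at kappa = 0
        expected = 1.0 / (2 * 1.5 * 4 * 5)
        assert np.mean(dts) == pytest.approx(expected, rel=0.05)

    def test_no_rotation_channel_when_probability_zero(self, rng):
        params = LMParams(M=4, N=4, p_rot=(0.0, 0.0))
        state = make_lattice(params, "random-mixed", rng)
        for _ in range(100):
            event, _ = gillespie_step(state, params, rng)
            i, j = event.site
            assert event.daughter_orientation == state.orient[i, j]

    def test_deterministic_given_rng_state(self):
        params = LMParams(M=4, N=4, p_rot=(0.2, 0.4))
        state = make_lattice(params, "random-mixed", np.random.default_rng(7))
        e1, dt1 = gillespie_step(state, params, np.random.default_rng(99))
        e2, dt2 = gillespie_step(state, params, np.random.default_rng(99))
        assert e1 == e2 and dt1 == dt2


class TestFirstEventDistributionOracle:
    def test_matches_exhaustive_enumeration(self):
        """On a 2x2 lattice at kappa = 0 every cell exposes two unit-rate
        directions, so the first event is uniform over (site, direction) and
        the rotation branch has probability equal to the four-cell mean
        rotation probability; the sampled distribution must match."""
        params = LMParams(M=2, N=2, lam=1.0, kappa=0.0, p_rot=(0.2, 0.5))
        rng = np.random.default_rng(42)
        base = make_lattice(params, "random-mixed", rng, orientation="random")
        p_eff = float(
            np.mean(np.where(base.strain == ORANGE, 0.5, 0.2))
        )
        counts = {}
        n_draws = 10_000
        for _ in range(n_draws):
            event, _ = gillespie_step(base, params, rng)
            i, j = event.site
            rotated = event.daughter_orientation != base.orient[i, j]
            key = (i, j, event.direction, rotated)
            counts[key] = counts.get(key, 0) + 1
        expected = {}
        for i in range(2):
            for j in range(2):
                dirs = ("up", "down") if base.orient[i, j] == V else ("right", "left")
                for d in dirs:
                    for rotated, pr in ((True, p_eff), (False, 1 - p_eff)):
                        expected[(i, j, d, rotated)] = n_draws * (1 / 8) * pr
        keys = sorted(expected)
        obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
        exp = np.array([expected[k] for k in keys])
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        crit = stats.chi2.ppf(0.999, df=len(keys) - 1)
        assert chi2 < crit


class TestSimulate:
    def test_all_vertical_without_rotation_stays_vertical(self):
        params = LMParams(M=6, N=10, lam=5.0, p_rot=(0.0, 0.0))
        df = simulate_lm(params, "single", t_end=1.0, sample_interval=0.2,
                         seed=3, orientation="all-V", engine="reference")
        assert np.all(df["f_H"] == 0.0)

    def test_single_strain_is_absorbing(self):
        params = LMParams(M=5, N=8, lam=5.0, p_rot=(0.5, 0.5))
        df = simulate_lm(params, "single", t_end=2.0, sample_interval=0.5, seed=4)
        assert np.all(df["f_orange"] == 0.0)

    def test_compiled_engine_reproducible(self):
        params = LMParams(M=6, N=10, lam=5.0, p_rot=(0.3, 0.3))
        a = simulate_lm(params, "random-mixed", t_end=1.0, sample_interval=0.1, seed=5)
        b = simulate_lm(params, "random-mixed", t_end=1.0, sample_interval=0.1, seed=5)
        assert np.array_equal(a["f_H"].to_numpy(), b["f_H"].to_numpy())

    def test_engines_statistically_consistent(self):
        """Compiled and reference event loops implement the same process:
        the mean horizontal fraction after relaxation from all-V agrees."""
        params = LMParams(M=5, N=8, lam=8.0, kappa=0.1, p_rot=(0.4, 0.4))
        means = {}
        for engine in ("compiled", "reference"):
            finals = [
                simulate_lm(params, "single", t_end=1.0, sample_interval=0.5,
                            seed=100 + r, orientation="all-V", engine=engine)
                ["f_H"].iloc[-1]
                for r in range(30)
            ]
            means[engine] = np.mean(finals)
        assert means["compiled"] == pytest.approx(means["reference"], abs=0.05)

    def test_end_before_induction_rejected(self):
        params = LMParams(p_rot_post=(0.0, 0.5), induction_time=2.0)
        with pytest.raises(ValueError):
            simulate_lm(params, t_end=1.0)

    def test_label_swap_symmetry(self):
        """Swapping strain labels and mirroring the seeding yields mirrored
        mean fraction trajectories (two-sample tolerance)."""
        kw = dict(M=8, N=24, lam=8.0, kappa=0.05, induction_time=0.5)
        pa = LMParams(p_rot=(0.0, 0.0), p_rot_post=(0.0, 0.4), **kw)
        pb = LMParams(p_rot=(0.0, 0.0), p_rot_post=(0.4, 0.0), **kw)
        ea = ensemble_fractions(pa, "random-mixed", 30, t_end=3.0,
                                sample_interval=0.5, seed=6)
        eb = ensemble_fractions(pb, "random-mixed", 30, t_end=3.0,
                                sample_interval=0.5, seed=6)
        np.testing.assert_allclose(
            ea["mean"].to_numpy(), 1.0 - eb["mean"].to_numpy(), atol=0.12
        )


class TestHorizontalPropensity:
    def test_no_horizontal_cells_gives_zero(self):
        params = LMParams(M=3, N=4)
        state = grid_state(np.zeros((3, 4)), np.zeros((3, 4)))
        assert horizontal_growth_propensity(state, BLUE, params) == 0.0

    def test_single_horizontal_cell_flat_landscape(self):
        params = LMParams(M=3, N=4, lam=2.0, kappa=0.0)
        orient = np.zeros((3, 4))
        orient[1, 2] = H
        state = grid_state(np.zeros((3, 4)), orient)
        # sigma counts all 12 blue cells; the one H cell contributes 2*lam
        assert horizontal_growth_propensity(state, BLUE, params) == pytest.approx(
            2 * 2.0 / 12
        )

    def test_lone_horizontal_cell_of_its_strain(self):
        params = LMParams(M=3, N=4, lam=2.0, kappa=0.0)
        strain = np.zeros((3, 4))
        orient = np.zeros((3, 4))
        strain[1, 2] = ORANGE
        orient[1, 2] = H
        state = grid_state(strain, orient)
        # sigma_orange = 1, so the propensity is h+ + h- = 2*lam
        assert horizontal_growth_propensity(state, ORANGE, params) == pytest.approx(4.0)

    def test_absent_strain_signaled(self):
        params = LMParams(M=2, N=2)
        state = grid_state(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            horizontal_growth_propensity(state, ORANGE, params)
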