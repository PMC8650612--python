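"""Simulator unit and property tests: placement, stepping, oxygen, rendering."""

import numpy as np
import pandas as pd
import pytest

import coronakit as ck
from coronakit.colony_sim import (
    OxygenField,
    _radial_density,
    make_colony,
    max_stable_dt,
    render_frame,
    simulate,
    step_agents,
    step_oxygen,
)
from coronakit.params import STATE_CORONA, STATE_ELONGATED, STATE_ROUNDED


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

class TestMakeColony:
    def test_degenerate_disc_puts_all_agents_at_center(self):
        p = ck.ColonyParams(n_cells=5, drop_radius=0.0, ring_start_radius=0.0, seed=1)
        tab = make_colony(p)
        assert len(tab) == 5
        assert np.allclose(tab[["x_um", "y_um"]].to_numpy(), 0.0)

    def test_determinism_same_seed_identical_tables(self, tiny_params):
        a = make_colony(tiny_params)
        b = make_colony(tiny_params)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ck.ColonyParams(n_cells=0)
        with pytest.raises(ValueError):
            ck.ColonyParams(drop_radius=-5.0)

    def test_center_density_exceeds_rim_density_across_seeds(self):
        """Monte-Carlo check of the center-decreasing placement law: the
        empirical areal density in [0, 300) μm beats [900, 1200) μm in at
        least 95 of 100 seeds."""
        area_in = np.pi * 300.0**2
        area_out = np.pi * (1200.0**2 - 900.0**2)
        wins = 0
        for seed in range(100):
            p = ck.ColonyParams(n_cells=5000, drop_radius=1200.0, seed=seed)
            tab = make_colony(p)
            r = np.hypot(tab.x_um, tab.y_um)
            dens_in = np.sum(r < 300) / area_in
            dens_out = np.sum((r >= 900) & (r < 1200)) / area_out
            wins += dens_in >= dens_out
        assert wins >= 95

    def test_all_agents_inside_drop(self, tiny_params):
        tab = make_colony(tiny_params)
        r = np.hypot(tab.x_um, tab.y_um)
        assert np.all(r <= tiny_params.drop_radius + 1e-9)


# ---------------------------------------------------------------------------
# Agent stepping
# ---------------------------------------------------------------------------

def _one_agent(state, x=500.0, y=0.0):
    return pd.DataFrame({"id": [0], "t_min": [100.0], "x_um": [x], "y_um": [y],
                         "state": np.array([state], dtype=np.int8), "alive": [True]})


class TestStepAgents:
    def test_rounded_agents_do_not_move(self, tiny_params):
        out = step_agents(_one_agent(STATE_ROUNDED), None, tiny_params, dt=1.0)
        assert out.x_um.iloc[0] == 500.0 and out.y_um.iloc[0] == 0.0

    def test_capped_kappa_moves_exactly_radially(self):
        p = ck.ColonyParams(n_cells=1, ring_kappa=1e9, seed=3)
        assert p.ring_kappa == ck.params.KAPPA_CAP
        out = step_agents(_one_agent(STATE_CORONA), None, p, dt=1.0)
        dx = out.x_um.iloc[0] - 500.0
        dy = out.y_um.iloc[0] - 0.0
        assert abs(np.arctan2(dy, dx)) < 1e-3  # outward = +x here

    def test_displacement_bound_every_step(self, tiny_params):
        sim = simulate(tiny_params.replace(duration_h=0.5, frame_interval=1.0))
        ag = sim.agents
        speeds = {STATE_ROUNDED: 0.0, STATE_ELONGATED: tiny_params.base_speed,
                  STATE_CORONA: tiny_params.corona_speed(30.0)}
        max_speed = max(speeds.values())
        for (t0, t1) in zip(sim.frame_times[:-1], sim.frame_times[1:]):
            a = ag[ag.t_min == t0].set_index("id")
            b = ag[ag.t_min == t1].set_index("id")
            common = a.index.intersection(b.index)
            d = np.hypot(b.loc[common].x_um - a.loc[common].x_um,
                         b.loc[common].y_um - a.loc[common].y_um)
            assert np.all(d <= max_speed * (t1 - t0) + 1e-9)

    def test_elongated_walk_is_unbiased_with_correct_speed(self):
        """Law of large numbers on the default (κ=0) elongated step model:
        over 10⁴ steps the mean vector displacement vanishes and the mean
        per-step speed equals base_speed within 2%."""
        p = ck.ColonyParams(n_cells=200, drop_radius=500.0, core_radius=0.0,
                            ring_start_radius=0.0, base_speed=3.9, seed=7)
        rng = np.random.default_rng(99)
        n, steps = 200, 10_000
        x = np.zeros(n)
        y = np.zeros(n)
        total_step = 0.0
        from coronakit.colony_sim import _move
        state = np.full(n, STATE_ELONGATED, dtype=np.int8)
        for _ in range(steps // 100):
            # batch 100 steps at a time for speed; step model is i.i.d.
            for _ in range(100):
                x2, y2 = _move(x, y, state, p, 0.0, 1.0, rng)
                total_step += np.hypot(x2 - x, y2 - y).mean()
                x, y = x2, y2
        mean_disp = np.hypot(x.mean(), y.mean())
        assert total_step / steps == pytest.approx(3.9, rel=0.02)
        # after N unbiased steps the COM displacement is ~ step·√N/√n_agents
        assert mean_disp < 5 * 3.9 * np.sqrt(steps) / np.sqrt(n)

    def test_division_off_conserves_agent_count(self, tiny_params):
        sim = simulate(tiny_params.replace(duration_h=0.5))
        counts = sim.agents.groupby("t_min").size()
        assert counts.nunique() == 1

    def test_division_creates_fresh_ids(self):
        p = ck.ColonyParams(n_cells=50, drop_radius=100.0, ring_start_radius=100.0,
                            division_rate=6.0, duration_h=1.0, seed=2)
        sim = simulate(p)
        last = sim.agents[sim.agents.t_min == sim.frame_times[-1]]
        assert len(last) > 50
        assert last.id.is_unique


# ---------------------------------------------------------------------------
# Oxygen dynamics
# ---------------------------------------------------------------------------

class TestOxygen:
    def grid(self, n=40, dr=15.0):
        return np.arange(n) * dr

    def test_uniform_oxygen_without_consumption_is_steady(self):
        r = self.grid()
        f = OxygenField(r, np.ones(len(r)))
        out = step_oxygen(f, np.zeros(len(r)), dt=0.01, diffusion=1000.0, consumption=0.0)
        assert np.allclose(out.concentration, 1.0)

    def test_zero_diffusion_decay_matches_closed_form(self):
        """Without diffusion, dC/dt = −aρ·C/(C+Km): one explicit step moves
        each interior node by exactly that amount."""
        r = self.grid()
        c0 = np.full(len(r), 0.8)
        rho = np.full(len(r), 0.5)
        a, km, dt = 0.2, 0.05, 0.1
        out = step_oxygen(OxygenField(r, c0), rho, dt, diffusion=0.0,
                          consumption=a, km=km)
        expected = 0.8 - dt * a * 0.5 * 0.8 / (0.8 + km)
        assert np.allclose(out.concentration[:-1], expected)
        assert out.concentration[-1] == 1.0  # boundary stays oxygenated

    def test_stability_bound_violation_names_max_dt(self):
        r = self.grid()
        f = OxygenField(r, np.ones(len(r)))
        dt_max = max_stable_dt(15.0, 3000.0)
        with pytest.raises(ValueError, match=f"{dt_max:g}"):
            step_oxygen(f, np.zeros(len(r)), dt=10 * dt_max, diffusion=3000.0,
                        consumption=0.0)

    def test_steady_state_matches_fine_grid_oracle(self):
        """Long integration on the production grid converges to the same
        steady state as a brute-force integration on a 4× finer grid
        (independent oracle for the radial reaction–diffusion scheme)."""
        D, k, km = 2000.0, 0.1, 0.05

        def steady(dr, n_nodes, minutes=400):
            r = np.arange(n_nodes) * dr
            rho = np.where(r < 400.0, 0.3, 0.0)
            f = OxygenField(r, np.ones(n_nodes))
            dt = 0.9 * max_stable_dt(dr, D)
            for _ in range(int(minutes / dt)):
                f = step_oxygen(f, rho, dt, D, k, km)
            return r, f.concentration

        r1, c1 = steady(15.0, 41)
        r2, c2 = steady(15.0 / 4, 161)
        assert np.max(np.abs(c1 - np.interp(r1, r2, c2))) < 0.02

    def test_min_concentration_non_increasing_for_static_density(self):
        r = self.grid()
        rho = np.exp(-r / 200.0) * 0.3
        f = OxygenField(r, np.ones(len(r)))
        mins = []
        for _ in range(200):
            f = step_oxygen(f, rho, 0.02, diffusion=2000.0, consumption=0.2)
            mins.append(f.concentration.min())
        assert np.all(np.diff(mins) <= 1e-12)

    def test_density_cap_limits_relative_density(self):
        r = self.grid()
        rho = _radial_density(np.zeros(500), np.zeros(500), r, rho_ref=1e-6, cap=0.3)
        assert rho.max() <= 0.3


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

class TestRender:
    def test_no_agents_no_noise_gives_constant_background(self, tiny_params):
        p = tiny_params.replace(noise_sd=0.0)
        empty = pd.DataFrame(columns=["id", "t_min", "x_um", "y_um", "state", "alive"])
        frame = render_frame(empty, p)
        assert frame.min() == frame.max() == int(p.render_background)

    def test_intensity_argmax_at_agent_position(self, tiny_params):
        p = tiny_params.replace(noise_sd=0.0)
        x, y = 99.0, -150.0
        frame = render_frame(_one_agent(STATE_ROUNDED, x, y), p)
        i, j = np.unravel_index(np.argmax(frame), frame.shape)
        ps, half = p.pixel_size, p.half_width
        assert abs((j + 0.5) * ps - half - x) <= ps
        assert abs((i + 0.5) * ps - half - y) <= ps

    def test_mean_intensity_monotone_in_agent_count(self, tiny_params):
        """Rendering k = 1..50 disjoint agents strictly increases the frame
        mean (additive bumps, no saturation at these intensities)."""
        p = tiny_params.replace(noise_sd=0.0, render_amplitude=60.0)
        rng = np.random.default_rng(0)
        pos = rng.uniform(-600, 600, size=(50, 2))
        means = []
        for k in range(1, 51):
            ag = pd.DataFrame({"id": np.arange(k), "t_min": 0.0,
                               "x_um": pos[:k, 0], "y_um": pos[:k, 1],
                               "state": np.int8(STATE_ROUNDED), "alive": True})
            means.append(render_frame(ag, p).astype(float).mean())
        assert np.all(np.diff(means) > 0)


# ---------------------------------------------------------------------------
# Full simulation contracts
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_bit_identical_given_equal_params(self, tiny_params):
        p = tiny_params.replace(duration_h=0.2)
        a, b = simulate(p), simulate(p)
        pd.testing.assert_frame_equal(a.agents, b.agents)
        assert np.array_equal(a.render(5), b.render(5))

    def test_kinematic_ring_truth_piecewise_linear(self):
        p = ck.ColonyParams(ring_formation_time=60.0, ring_speed_initial=2.2,
                            ring_speed_late=0.67, speed_crossover_time=600.0,
                            ring_start_radius=1050.0)
        assert p.ring_radius(np.array([200.0]))[0] == pytest.approx(1050.0 + 2.2 * 140)
        assert np.isnan(p.ring_radius(np.array([30.0]))[0])
        # continuity at the crossover and exact slopes
        t = np.arange(60.0, 1440.0, 1.0)
        r = p.ring_radius(t)
        slopes = np.diff(r)
        assert np.allclose(slopes[t[:-1] < 599], 2.2)
        assert np.allclose(slopes[t[:-1] >= 600], 0.67)

    def test_unconfined_mode_has_no_ring_truth(self):
        p = ck.ColonyParams(mode="unconfined", n_cells=100, duration_h=0.1,
                            core_radius=0.0)
        sim = simulate(p)
        assert np.all(~np.isfinite(sim.ring_truth.r_um))

    def test_short_kinematic_run_warns_ring_never_forms(self, tiny_params):
        with pytest.warns(UserWarning, match="never forms"):
            simulate(tiny_params.replace(duration_h=0.1))

    def test_mechanistic_hypoxic_core_is_stationary(self):
        """With consumption high enough to push the core below the rounding
        threshold, core agents show essentially no net displacement."""
        p = ck.ColonyParams(mode="mechanistic", n_cells=600, drop_radius=600.0,
                            core_radius=0.0, ring_start_radius=500.0,
                            oxygen_diffusion=1000.0, oxygen_consumption=0.5,
                            duration_h=1.5, seed=4, image_size=512, pixel_size=3.0)
        sim = simulate(p)
        first = sim.agents[sim.agents.t_min == 0].set_index("id")
        last = sim.agents[sim.agents.t_min == sim.frame_times[-1]].set_index("id")
        r0 = np.hypot(first.x_um, first.y_um)
        core_ids = first.index[r0 < 150]
        disp = np.hypot(last.loc[core_ids].x_um - first.loc[core_ids].x_um,
                        last.loc[core_ids].y_um - first.loc[core_ids].y_um)
        # rounded well before the end: mean net displacement a small fraction
        # of what free motility (3.9 μm/min × 90 min) would produce
        assert disp.mean() < 0.1 * p.base_speed * p.duration_min
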