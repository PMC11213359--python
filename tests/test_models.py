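"""Simulator correctness against independent numerical oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import flowmiss as fm
from flowmiss.errors import ConfigurationError, SimulationError
from flowmiss.models import (
    conversion_trajectories,
    simulate_fhn,
    simulate_sir_ssa,
    sir_ode_states,
    sir_ssa_states,
)


class TestPriors:
    def test_gaussian_sample_mean_converges(self, rng):
        prior = fm.PriorSpec((fm.Gaussian(0, 1), fm.Gaussian(0, 1)))
        draws = fm.sample_prior(prior, 10**5, rng)
        assert np.all(np.abs(draws.mean(axis=0)) < 4 / np.sqrt(10**5))

    def test_uniform_support(self, rng):
        prior = fm.PriorSpec((fm.Uniform(0.0, 0.8),))
        draws = fm.sample_prior(prior, 10**4, rng)
        assert draws.min() >= 0.0 and draws.max() <= 0.8

    def test_seeded_reproducibility(self):
        prior = fm.default_prior("conversion_reaction")
        a = fm.sample_prior(prior, 50, np.random.default_rng(7))
        b = fm.sample_prior(prior, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "bad", [lambda: fm.Gaussian(0, 0.0), lambda: fm.Uniform(1.0, 1.0), lambda: fm.PriorSpec(())]
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            bad()

    def test_uniform_logpdf_outside_support(self):
        u = fm.Uniform(0.0, 1.0)
        assert u.logpdf(1.5) == -np.inf and np.isfinite(u.logpdf(0.5))


class TestConversionReaction:
    def test_initial_condition_and_symmetry(self):
        spec = fm.default_model("conversion_reaction", time_grid=np.array([0.0, 100.0]))
        x = fm.simulate(np.log([0.4, 0.4]), spec)
        assert x.values[0, 0] == 0.0
        # k1 = k2: equilibrium at B = 1/2
        assert abs(x.values[1, 0] - 0.5) < 1e-10

    def test_matches_numeric_ode_solution(self):
        """Exact solution agrees with an independent adaptive ODE integration."""
        spec = fm.default_model("conversion_reaction", n_x=11)
        theta = np.array([-0.98, -0.66])
        k1, k2 = np.exp(theta)
        sol = solve_ivp(
            lambda t, y: [-k1 * y[0] + k2 * y[1], k1 * y[0] - k2 * y[1]],
            (0, 10),
            [1.0, 0.0],
            t_eval=spec.time_grid,
            rtol=1e-10,
            atol=1e-12,
        )
        ours = fm.simulate(theta, spec).values[:, 0]
        assert np.max(np.abs(ours - sol.y[1])) < 1e-6

    def test_trajectory_bounded_in_unit_interval(self, rng):
        spec = fm.default_model("conversion_reaction")
        theta = fm.sample_prior(fm.default_prior("conversion_reaction"), 100, rng)
        trajs = conversion_trajectories(theta, spec)
        assert trajs.min() >= 0.0 and trajs.max() <= 1.0

    def test_nonfinite_theta_rejected(self):
        spec = fm.default_model("conversion_reaction")
        with pytest.raises(SimulationError):
            fm.simulate(np.array([np.nan, 0.0]), spec)


class TestSinusoid:
    def test_exact_values(self):
        spec = fm.default_model("sinusoid", time_grid=np.array([0.0, 0.5]))
        x = fm.simulate(np.array([0.5, 0.0]), spec)
        assert abs(x.values[1, 0] - 1.0) < 1e-12  # sin(pi/2) = 1
        x = fm.simulate(np.array([0.7, 0.3]), spec)
        assert abs(x.values[0, 0] - 0.3) < 1e-12  # sin(0) = 0

    def test_periodicity(self):
        a = 0.5
        spec = fm.default_model("sinusoid")  # grid step 0.25, period 1/a = 2
        x = fm.simulate(np.array([a, 0.1]), spec).values[:, 0]
        shift = int(round((1 / a) / (spec.time_grid[1] - spec.time_grid[0])))
        np.testing.assert_allclose(x[shift:], x[:-shift], atol=1e-9)


def _rk4(rhs, y0, t_grid, h):
    """Fixed-step classical Runge-Kutta oracle."""
    t, y = 0.0, np.asarray(y0, dtype=float)
    out, k = [], 0
    t_grid = np.asarray(t_grid)
    while k < len(t_grid):
        if t >= t_grid[k] - 1e-12:
            out.append(y.copy())
            k += 1
            continue
        step = min(h, t_grid[k] - t)
        k1 = rhs(t, y)
        k2 = rhs(t + step / 2, y + step / 2 * k1)
        k3 = rhs(t + step / 2, y + step / 2 * k2)
        k4 = rhs(t + step, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += step
    return np.array(out)


class TestFHN:
    theta = np.array([0.7, 0.8, 3.0])

    def test_deterministic_repeat(self):
        spec = fm.default_model("fhn")
        a = simulate_fhn(self.theta, spec).values
        b = simulate_fhn(self.theta, spec).values
        np.testing.assert_array_equal(a, b)

    def test_against_fixed_step_rk4(self):
        spec = fm.default_model("fhn", n_x=6)
        alpha, beta, gamma = self.theta

        def rhs(t, y):
            v, r = y
            return np.array([gamma * (v - v**3 / 3 + r), -(v - alpha + beta * r) / gamma])

        oracle = _rk4(rhs, [-1.0, 1.0], spec.time_grid, h=1e-4)
        ours = simulate_fhn(self.theta, spec).values[:, 0]
        assert np.max(np.abs(ours - oracle[:, 0])) < 1e-4

    def test_tolerance_convergence(self):
        # a much looser solve agrees to well below observation noise scale
        spec = fm.default_model("fhn")
        tight = simulate_fhn(self.theta, spec).values
        loose = solve_ivp(
            lambda t, y: [3.0 * (y[0] - y[0] ** 3 / 3 + y[1]), -(y[0] - 0.7 + 0.8 * y[1]) / 3.0],
            (0, 15),
            [-1.0, 1.0],
            t_eval=spec.time_grid,
            method="LSODA",
            rtol=1e-6,
            atol=1e-6,
        )
        assert np.max(np.abs(tight[:, 0] - loose.y[0])) < 1e-4


class TestSIR:
    def test_ode_conservation(self):
        spec = fm.default_model("sir_ode")
        states = sir_ode_states(np.array([-0.8, -1.4]), spec)
        n_pop = spec.constants["N_pop"]
        assert np.max(np.abs(states.sum(axis=1) - n_pop)) < 1e-6 * n_pop

    def test_zero_transmission_is_pure_decay(self):
        spec = fm.default_model("sir_ode", constants={"I0": 100})
        states = sir_ode_states(np.array([-30.0, -1.4]), spec)
        infected = states[:, 1]
        assert np.all(np.diff(infected) <= 1e-9)

    def test_ode_against_fixed_step_rk4(self):
        spec = fm.default_model("sir_ode", n_x=7)
        beta, gamma, n_pop = 10**-0.8, 10**-1.4, 1000.0

        def rhs(t, y):
            inf = beta * y[0] * y[1] / n_pop
            return np.array([-inf, inf - gamma * y[1], gamma * y[1]])

        oracle = _rk4(rhs, [999.0, 1.0, 0.0], spec.time_grid, h=1e-3)
        ours = sir_ode_states(np.array([-0.8, -1.4]), spec)
        rel = np.max(np.abs(ours - oracle) / np.maximum(np.abs(oracle), 1.0))
        assert rel < 1e-4

    def test_ssa_conservation_and_integer_counts(self, rng):
        spec = fm.default_model("sir_ssa")
        states = sir_ssa_states(np.array([-0.8, -1.4]), spec, rng)
        assert states.dtype.kind == "i" and states.min() >= 0
        assert np.all(states.sum(axis=1) == spec.constants["N_pop"])

    def test_ssa_seeded_determinism(self):
        spec = fm.default_model("sir_ssa")
        a = simulate_sir_ssa(np.array([-0.8, -1.4]), spec, np.random.default_rng(5)).values
        b = simulate_sir_ssa(np.array([-0.8, -1.4]), spec, np.random.default_rng(5)).values
        np.testing.assert_array_equal(a, b)

    def test_ssa_ensemble_mean_matches_ode(self, rng):
        """Large-population limit: Gillespie ensemble mean approaches the ODE."""
        # mean-field agreement needs small relative fluctuations in the initial
        # state; with I0 of only a few individuals the ensemble mean genuinely
        # departs from the ODE near the epidemic peak (timing jitter).
        n_pop, n_rep, i0 = 10**4, 2000, 1000
        spec = fm.default_model("sir_ssa", n_x=9, constants={"N_pop": n_pop, "I0": i0})
        spec_ode = fm.default_model("sir_ode", n_x=9, constants={"N_pop": n_pop, "I0": i0})
        theta = np.array([-1.0, -1.2])
        infected = np.stack([sir_ssa_states(theta, spec, rng)[:, 1] for _ in range(n_rep)])
        ode_inf = sir_ode_states(theta, spec_ode)[:, 1]
        se = infected.std(axis=0, ddof=1) / np.sqrt(n_rep)
        z = np.abs(infected.mean(axis=0) - ode_inf) / np.maximum(se, 1e-9)
        # the ODE is the large-N limit, not the exact mean; allow 3 SE pointwise
        assert np.all(z < 3.0), f"max z = {z.max():.2f}"


class TestNoiseAndBatch:
    def test_zero_noise_is_identity(self, rng):
        spec = fm.default_model("sinusoid")
        x = fm.simulate(np.array([0.3, 0.1]), spec)
        assert fm.add_noise(x, 0.0, rng) is x

    def test_noise_moments(self, rng):
        x = fm.CompleteData(np.zeros((10**5, 1)), np.arange(10**5))
        noisy = fm.add_noise(x, 0.05, rng)
        diff = noisy.values - x.values
        assert abs(diff.std() - 0.05) < 0.02 * 0.05
        assert abs(diff.mean()) < 4 * 0.05 / np.sqrt(10**5)

    def test_batch_shapes_and_reproducibility(self):
        model = fm.default_model("conversion_reaction")
        prior = fm.default_prior("conversion_reaction")
        t1, v1 = fm.simulate_batch(model, prior, 64, np.random.default_rng(3))
        t2, v2 = fm.simulate_batch(model, prior, 64, np.random.default_rng(3))
        assert t1.shape == (64, 2) and v1.shape == (64, 3, 1)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(v1, v2)

    def test_batch_marginals_match_prior(self, rng):
        """Composition check: theta columns are distributed as the prior."""
        from scipy import stats

        model = fm.default_model("sinusoid")
        prior = fm.default_prior("sinusoid")
        theta, _ = fm.simulate_batch(model, prior, 10**4, rng)
        p_a = stats.kstest(theta[:, 0], stats.uniform(0.1, 0.9).cdf).pvalue
        p_b = stats.kstest(theta[:, 1], stats.uniform(-1.0, 2.0).cdf).pvalue
        assert p_a > 0.01 and p_b > 0.01
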