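"""Priors and benchmark simulators.

Five mechanistic test models generate complete time series ``x ~ pi(x | theta)``:

* ``conversion_reaction`` — chemical conversion A <-> B with log-scale rate
  parameters; the observable is the concentration of B.  The two-state linear
  ODE has the exact solution ``B(t) = k1/(k1+k2) * (1 - exp(-(k1+k2) t))``
  for the initial condition (A, B) = (1, 0), which is what we evaluate.
* ``sinusoid`` — ``sin(2 pi a t) + b`` with frequency a and offset b.
* ``fhn`` — the FitzHugh-Nagumo excitable-system ODE (three parameters),
  integrated numerically; the voltage variable is observed.
* ``sir_ode`` — deterministic SIR compartment model with log10-scale
  transmission and recovery rates; the scaled infected fraction I/N is observed.
* ``sir_ssa`` — the same SIR dynamics as a continuous-time Markov jump
  process, simulated exactly with the Gillespie stochastic simulation
  algorithm and read off at the observation grid.

Gaussian measurement noise is added on top of every simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, SimulationError

__all__ = [
    "Gaussian",
    "Uniform",
    "PriorSpec",
    "ModelSpec",
    "CompleteData",
    "sample_prior",
    "simulate",
    "simulate_conversion_reaction",
    "simulate_sinusoid",
    "simulate_fhn",
    "simulate_sir_ode",
    "simulate_sir_ssa",
    "add_noise",
    "simulate_batch",
    "default_prior",
    "default_model",
    "conversion_trajectories",
    "sinusoid_trajectories",
]


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Gaussian:
    mean: float
    sd: float

    def __post_init__(self):
        if not (self.sd > 0):
            raise ConfigurationError(f"gaussian sd must be positive, got {self.sd}")

    def sample(self, n, rng):
        return rng.normal(self.mean, self.sd, size=n)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return -0.5 * np.log(2 * np.pi * self.sd**2) - 0.5 * ((x - self.mean) / self.sd) ** 2

    @property
    def std(self):
        return self.sd


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo < self.hi):
            raise ConfigurationError(f"uniform requires lo < hi, got [{self.lo}, {self.hi}]")

    def sample(self, n, rng):
        return rng.uniform(self.lo, self.hi, size=n)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lo) & (x <= self.hi)
        return np.where(inside, -np.log(self.hi - self.lo), -np.inf)

    @property
    def mean(self):
        return 0.5 * (self.lo + self.hi)

    @property
    def std(self):
        return (self.hi - self.lo) / np.sqrt(12.0)


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter prior pi(theta)."""

    components: tuple
    names: tuple = ()

    def __post_init__(self):
        if len(self.components) == 0:
            raise ConfigurationError("prior needs at least one component")
        if self.names and len(self.names) != len(self.components):
            raise ConfigurationError("names/components length mismatch")

    @property
    def n_theta(self) -> int:
        return len(self.components)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.column_stack([c.sample(n, rng) for c in self.components])

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return sum(c.logpdf(theta[:, i]) for i, c in enumerate(self.components))

    @property
    def mean(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def std(self) -> np.ndarray:
        return np.array([c.std for c in self.components])


def sample_prior(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. parameter vectors; rows are samples."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return prior.sample(n, rng)


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

MODEL_NAMES = ("conversion_reaction", "sinusoid", "fhn", "sir_ode", "sir_ssa")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    time_grid: np.ndarray
    noise_sd: float = 0.05
    d_obs: int = 1
    constants: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ConfigurationError(f"unknown model {self.name!r}")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("time_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "time_grid", grid)
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_x(self) -> int:
        return self.time_grid.size


@dataclass(frozen=True)
class CompleteData:
    """A complete (no missing entries) simulated trajectory."""

    values: np.ndarray  # (n_x, d_obs)
    time_grid: np.ndarray

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] == 1 and np.asarray(self.time_grid).size > 1:
            v = v.T
        object.__setattr__(self, "values", v)


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------


def _conversion_rates(theta: np.ndarray, spec: ModelSpec):
    theta = np.asarray(theta, dtype=float)
    if "log_k2" in spec.constants:
        k1 = np.exp(theta[..., 0])
        k2 = np.exp(float(spec.constants["log_k2"])) * np.ones_like(k1)
    else:
        k1 = np.exp(theta[..., 0])
        k2 = np.exp(theta[..., 1])
    return k1, k2


def conversion_trajectories(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Vectorized exact B(t) for a batch of parameters; (n, n_x)."""
    k1, k2 = _conversion_rates(np.atleast_2d(theta), spec)
    s = (k1 + k2)[:, None]
    return (k1 / (k1 + k2))[:, None] * (1.0 - np.exp(-s * spec.time_grid[None, :]))


def simulate_conversion_reaction(theta, spec: ModelSpec, rng=None) -> CompleteData:
    """Concentration of species B for rate parameters theta = (ln k1, ln k2)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise SimulationError(f"non-finite parameters {theta}")
    return CompleteData(conversion_trajectories(theta[None, :], spec)[0][:, None], spec.time_grid)


def sinusoid_trajectories(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    theta = np.atleast_2d(theta)
    a, b = theta[:, 0][:, None], theta[:, 1][:, None]
    return np.sin(2 * np.pi * a * spec.time_grid[None, :]) + b


def simulate_sinusoid(theta, spec: ModelSpec, rng=None) -> CompleteData:
    """sin(2 pi a t) + b at the grid points, theta = (a, b)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise SimulationError(f"non-finite parameters {theta}")
    return CompleteData(sinusoid_trajectories(theta[None, :], spec)[0][:, None], spec.time_grid)


def _fhn_rhs(t, y, alpha, beta, gamma):
    v, r = y
    return [gamma * (v - v**3 / 3.0 + r), -(v - alpha + beta * r) / gamma]


def simulate_fhn(theta, spec: ModelSpec, rng=None) -> CompleteData:
    """FitzHugh-Nagumo voltage trajectory, theta = (alpha, beta, gamma).

    dV/dt = gamma (V - V^3/3 + R),  dR/dt = -(V - alpha + beta R) / gamma.
    """
    theta = np.asarray(theta, dtype=float)
    alpha, beta, gamma = theta[:3]
    y0 = spec.constants.get("x0", (-1.0, 1.0))
    t = spec.time_grid
    sol = solve_ivp(
        _fhn_rhs,
        (min(0.0, t[0]), t[-1]),
        y0,
        t_eval=t,
        args=(alpha, beta, gamma),
        method="LSODA",
        rtol=1e-8,
        atol=1e-8,
    )
    if not sol.success:
        raise SimulationError(f"FHN integration failed for theta={theta}: {sol.message}")
    return CompleteData(sol.y[0][:, None], t)


def _sir_rhs(t, y, beta, gamma, n_pop):
    s, i, r = y
    inf = beta * s * i / n_pop
    return [-inf, inf - gamma * i, gamma * i]


def sir_ode_states(theta, spec: ModelSpec) -> np.ndarray:
    """All three compartments (n_x, 3) of the deterministic SIR model."""
    theta = np.asarray(theta, dtype=float)
    beta, gamma = 10.0 ** theta[0], 10.0 ** theta[1]
    n_pop = float(spec.constants.get("N_pop", 1000))
    i0 = float(spec.constants.get("I0", 1.0))
    t = spec.time_grid
    sol = solve_ivp(
        _sir_rhs,
        (min(0.0, t[0]), t[-1]),
        [n_pop - i0, i0, 0.0],
        t_eval=t,
        args=(beta, gamma, n_pop),
        method="LSODA",
        rtol=1e-8,
        atol=1e-8,
    )
    if not sol.success:
        raise SimulationError(f"SIR integration failed for theta={theta}: {sol.message}")
    return sol.y.T


def simulate_sir_ode(theta, spec: ModelSpec, rng=None) -> CompleteData:
    """Scaled infected fraction I(t)/N_pop; theta = (log10 beta, log10 gamma)."""
    states = sir_ode_states(theta, spec)
    n_pop = float(spec.constants.get("N_pop", 1000))
    return CompleteData(states[:, 1][:, None] / n_pop, spec.time_grid)


@njit(cache=False)
def _gillespie_sir(s0, i0, beta, gamma, n_pop, t_grid, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_t = t_grid.shape[0]
    out = np.empty((n_t, 3), dtype=np.int64)
    s, i, r = s0, i0, n_pop - s0 - i0
    t = 0.0
    k = 0
    while k < n_t:
        a1 = beta * s * i / n_pop
        a2 = gamma * i
        a0 = a1 + a2
        if a0 <= 0.0:  # absorbing state, record remaining grid points
            while k < n_t:
                out[k, 0] = s
                out[k, 1] = i
                out[k, 2] = r
                k += 1
            break
        t_next = t + np.random.exponential(1.0 / a0)
        while k < n_t and t_grid[k] < t_next:
            out[k, 0] = s
            out[k, 1] = i
            out[k, 2] = r
            k += 1
        if np.random.random() * a0 < a1:
            s -= 1
            i += 1
        else:
            i -= 1
            r += 1
        t = t_next
    return out


def sir_ssa_states(theta, spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Integer compartment counts (n_x, 3) from one exact Gillespie realization.

    Reactions: infection S + I -> 2I with propensity beta*S*I/N, and recovery
    I -> R with propensity gamma*I.  The state is read off by piecewise-constant
    interpolation at the grid times.
    """
    theta = np.asarray(theta, dtype=float)
    beta, gamma = 10.0 ** theta[0], 10.0 ** theta[1]
    n_pop = int(spec.constants.get("N_pop", 1000))
    if n_pop <= 0:
        raise ConfigurationError("N_pop must be a positive integer")
    i0 = int(spec.constants.get("I0", 1))
    seed = int(rng.integers(0, 2**31 - 1))
    grid = np.asarray(spec.time_grid, dtype=np.float64)
    return _gillespie_sir(n_pop - i0, i0, beta, gamma, float(n_pop), grid, seed)


def simulate_sir_ssa(theta, spec: ModelSpec, rng: np.random.Generator) -> CompleteData:
    """Scaled infected count I(t)/N_pop from one stochastic realization."""
    states = sir_ssa_states(theta, spec, rng)
    n_pop = float(spec.constants.get("N_pop", 1000))
    return CompleteData(states[:, 1][:, None] / n_pop, spec.time_grid)


_SIMULATORS = {
    "conversion_reaction": simulate_conversion_reaction,
    "sinusoid": simulate_sinusoid,
    "fhn": simulate_fhn,
    "sir_ode": simulate_sir_ode,
    "sir_ssa": simulate_sir_ssa,
}


_n_simulator_calls = 0


def simulation_call_count() -> int:
    """Total simulator invocations so far (amortization accounting)."""
    return _n_simulator_calls


def _count_calls(n: int = 1) -> None:
    global _n_simulator_calls
    _n_simulator_calls += n


def simulate(theta, spec: ModelSpec, rng=None) -> CompleteData:
    """Run the simulator named in ``spec`` (noise-free trajectory)."""
    _count_calls()
    return _SIMULATORS[spec.name](theta, spec, rng)


def add_noise(x: CompleteData, noise_sd: float, rng: np.random.Generator) -> CompleteData:
    """Independent additive gaussian measurement noise on every entry."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if noise_sd == 0:
        return x
    return CompleteData(x.values + rng.normal(0.0, noise_sd, size=x.values.shape), x.time_grid)


def simulate_batch(
    model: ModelSpec, prior: PriorSpec, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """M i.i.d. pairs (theta, noisy trajectory); values stacked (M, n_x, d_obs).

    Closed-form models (conversion reaction, sinusoid) are vectorized over the
    batch; the ODE/SSA models loop per sample.
    """
    if m < 1:
        raise ConfigurationError("batch size must be >= 1")
    theta = sample_prior(prior, m, rng)
    _count_calls(m)
    if model.name == "conversion_reaction":
        clean = conversion_trajectories(theta, model)[:, :, None]
    elif model.name == "sinusoid":
        clean = sinusoid_trajectories(theta, model)[:, :, None]
    else:
        rows = []
        for i in range(m):
            try:
                rows.append(_SIMULATORS[model.name](theta[i], model, rng).values)
            except SimulationError as err:
                raise SimulationError(f"simulation failed at batch index {i}: {err}") from err
        clean = np.stack(rows)
    noisy = clean + rng.normal(0.0, model.noise_sd, size=clean.shape) if model.noise_sd > 0 else clean
    return theta, noisy


# --------------------------------------------------------------------------
# default study configurations
# --------------------------------------------------------------------------


def default_prior(name: str, param_dependent: bool = False) -> PriorSpec:
    """The prior used by each benchmark problem."""
    if name == "conversion_reaction":
        comps = [Gaussian(-0.75, 0.25)] if param_dependent else [Gaussian(-0.75, 0.25), Gaussian(-0.75, 0.25)]
        names = ["log_k1"] if param_dependent else ["log_k1", "log_k2"]
        if param_dependent:
            comps.append(Uniform(0.0, 0.8))
            names.append("p_miss")
        return PriorSpec(tuple(comps), tuple(names))
    if name == "sinusoid":
        return PriorSpec((Uniform(0.1, 1.0), Uniform(-1.0, 1.0)), ("a", "b"))
    if name == "fhn":
        return PriorSpec((Uniform(0.2, 1.2), Uniform(0.2, 1.2), Uniform(1.0, 4.0)), ("alpha", "beta", "gamma"))
    if name in ("sir_ode", "sir_ssa"):
        return PriorSpec((Gaussian(-0.8, 0.3), Gaussian(-1.4, 0.3)), ("log10_beta", "log10_gamma"))
    raise ConfigurationError(f"unknown model {name!r}")


def default_model(name: str, n_x: int | None = None, **overrides) -> ModelSpec:
    """Benchmark ModelSpec with the study's default grid/noise/constants."""
    if name == "conversion_reaction":
        grid = np.array([0.0, 5.0, 10.0]) if n_x in (None, 3) else np.linspace(0.0, 10.0, n_x)
        base = dict(time_grid=grid, noise_sd=0.05)
    elif name == "sinusoid":
        base = dict(time_grid=np.linspace(0.0, 10.0, n_x or 41), noise_sd=0.05)
    elif name == "fhn":
        base = dict(time_grid=np.linspace(0.0, 15.0, n_x or 21), noise_sd=0.05, constants={"x0": (-1.0, 1.0)})
    elif name in ("sir_ode", "sir_ssa"):
        base = dict(
            time_grid=np.linspace(0.0, 60.0, n_x or 21),
            noise_sd=0.05,
            constants={"N_pop": 1000, "I0": 1},
        )
    else:
        raise ConfigurationError(f"unknown model {name!r}")
    if "constants" in overrides and "constants" in base:
        base["constants"] = {**base["constants"], **overrides.pop("constants")}
    base.update(overrides)
    return ModelSpec(name=name, **base)
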