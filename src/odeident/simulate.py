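"""Numerical integration, forward sensitivities and synthetic data.

Sensitivities are propagated with the forward sensitivity equations,

    dS/dt = (df/dx) S + df/dtheta,    S(0) = dx0/dtheta,

integrated jointly with the states (theta = unknown parameters followed by
unknown initial conditions, so S(0) is a zero matrix with an identity block
in the unknown-IC rows).  Output sensitivities follow by the chain rule,
S_y = (dg/dx) S + dg/dtheta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .model import ModelValidationError, OdeModel

__all__ = [
    "ConstantInput",
    "PiecewiseLinearInput",
    "Trajectory",
    "SensitivityBundle",
    "IntegrationError",
    "simulate",
    "sensitivities",
    "generate_synthetic_data",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to reach the end of the grid."""

    def __init__(self, message: str, last_time: float | None = None):
        self.last_time = last_time
        super().__init__(message)


@dataclass(frozen=True)
class ConstantInput:
    value: float

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value) \
            if np.ndim(t) else float(self.value)


@dataclass(frozen=True)
class PiecewiseLinearInput:
    times: tuple
    values: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("node times must be strictly increasing, >= 2 nodes")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values",
                           tuple(float(v) for v in self.values))

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


@dataclass
class Trajectory:
    """State and output trajectories on a time grid."""

    time_grid: np.ndarray
    state_names: list[str]
    output_names: list[str]
    state_values: np.ndarray  # (n_t, n_states)
    output_values: np.ndarray  # (n_t, n_outputs)

    def output(self, name: str) -> np.ndarray:
        return self.output_values[:, self.output_names.index(name)]

    def state(self, name: str) -> np.ndarray:
        return self.state_values[:, self.state_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time_grid})
        for i, n in enumerate(self.output_names):
            df[n] = self.output_values[:, i]
        return df


@dataclass
class SensitivityBundle:
    trajectory: Trajectory
    theta_names: list[str]
    state_sens: np.ndarray  # (n_t, n_states, n_theta)
    output_sens: np.ndarray  # (n_t, n_outputs, n_theta)

    def output_sensitivity(self, output: str, theta: str) -> np.ndarray:
        i = self.trajectory.output_names.index(output)
        j = self.theta_names.index(theta)
        return self.output_sens[:, i, j]


class _CompiledModel:
    """Lambdified RHS, output map and their Jacobians for one model."""

    def __init__(self, model: OdeModel):
        model.validate()
        self.model = model
        self.state_names = model.state_names
        self.output_names = list(model.outputs)
        self.theta_param_names = [p.name for p in model.unknown_parameters]
        self.theta_ic_states = [s.name for s in model.unknown_ic_states]
        self.theta_names = self.theta_param_names + [
            f"{s}(0)" for s in self.theta_ic_states
        ]
        subs = {sp.Symbol(n, real=True): sp.Float(v)
                for n, v in model.constants.items()}
        subs.update({sp.Symbol(p.name, real=True): sp.Float(p.value)
                     for p in model.known_parameters})
        x = [sp.Symbol(s, real=True) for s in self.state_names]
        p = [sp.Symbol(n, real=True) for n in self.theta_param_names]
        u = [sp.Symbol(n, real=True) for n in model.inputs]
        f = sp.Matrix([model.odes[s].xreplace(subs) for s in self.state_names])
        g = sp.Matrix([model.outputs[o].xreplace(subs)
                       for o in self.output_names])
        args = (x, p, u)
        self.n_states = len(x)
        self.n_outputs = len(g)
        self.n_params = len(p)
        self.n_theta = len(self.theta_names)
        self.f = sp.lambdify(args, f, modules="numpy")
        self.jac_x = sp.lambdify(args, f.jacobian(x), modules="numpy")
        self.jac_p = sp.lambdify(args, f.jacobian(p) if p else sp.zeros(len(x), 0),
                                 modules="numpy")
        self.g = sp.lambdify(args, g, modules="numpy")
        self.g_x = sp.lambdify(args, g.jacobian(x), modules="numpy")
        self.g_p = sp.lambdify(args, g.jacobian(p) if p else sp.zeros(len(g), 0),
                               modules="numpy")

    def split_theta(self, theta) -> tuple[np.ndarray, dict[str, float]]:
        vec = _theta_vector(theta, self.theta_names)
        p = vec[: self.n_params]
        ic = dict(zip(self.theta_ic_states, vec[self.n_params:]))
        return p, ic

    def initial_state(self, theta) -> np.ndarray:
        _, ic_unknown = self.split_theta(theta)
        x0 = np.empty(self.n_states)
        for i, s in enumerate(self.model.states):
            x0[i] = float(s.ic_value) if s.ic_known else ic_unknown[s.name]
        return x0


_COMPILE_CACHE: dict[int, _CompiledModel] = {}


def _compiled(model: OdeModel) -> _CompiledModel:
    key = id(model)
    cm = _COMPILE_CACHE.get(key)
    if cm is None or cm.model is not model:
        cm = _CompiledModel(model)
        _COMPILE_CACHE[key] = cm
    return cm


def _theta_vector(theta, names: list[str]) -> np.ndarray:
    if isinstance(theta, dict):
        missing = [n for n in names if n not in theta]
        # accept bare state names for unknown-IC entries, e.g. "x1" for "x1(0)"
        resolved = dict(theta)
        for n in list(missing):
            if n.endswith("(0)") and n[:-3] in theta:
                resolved[n] = theta[n[:-3]]
                missing.remove(n)
        if missing:
            raise ValueError(f"theta is missing entries for {missing}")
        return np.array([float(resolved[n]) for n in names])
    vec = np.asarray(theta, dtype=float)
    if vec.shape != (len(names),):
        raise ValueError(
            f"theta must have {len(names)} entries ({names}); got shape {vec.shape}"
        )
    return vec


def _input_values(model: OdeModel, input_signal, t) -> list[float]:
    if not model.inputs:
        return []
    if input_signal is None:
        raise ModelValidationError(
            f"model {model.name!r} has inputs {list(model.inputs)}; "
            "an input signal is required"
        )
    if isinstance(input_signal, dict):
        return [float(input_signal[n](t)) for n in model.inputs]
    return [float(input_signal(t))]


def simulate(model: OdeModel, theta, time_grid, input_signal=None,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model on ``time_grid`` for unknown-quantity values ``theta``.

    ``theta`` is a dict keyed by unknown names (unknown ICs as ``"x(0)"`` or
    the bare state name) or an array in canonical order.  A stiff-capable
    integrator with the analytic state Jacobian is used throughout.
    """
    cm = _compiled(model)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing with >= 2 points")
    p, _ = cm.split_theta(theta)
    x0 = cm.initial_state(theta)

    def rhs(tt, x):
        u = _input_values(model, input_signal, tt)
        return np.asarray(cm.f(x, p, u), dtype=float).ravel()

    def jac(tt, x):
        u = _input_values(model, input_signal, tt)
        return np.asarray(cm.jac_x(x, p, u), dtype=float)

    sol = solve_ivp(rhs, (t[0], t[-1]), x0, t_eval=t, method=method,
                    rtol=rtol, atol=atol, jac=jac)
    if not sol.success or sol.y.shape[1] != t.size:
        last = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationError(
            f"integration of {model.name!r} failed: {sol.message}", last)
    xs = sol.y.T
    if not np.all(np.isfinite(xs)):
        raise IntegrationError(f"integration of {model.name!r} returned "
                               "non-finite states")
    ys = np.empty((t.size, cm.n_outputs))
    for i, tt in enumerate(t):
        u = _input_values(model, input_signal, tt)
        ys[i] = np.asarray(cm.g(xs[i], p, u), dtype=float).ravel()
    return Trajectory(t, cm.state_names, cm.output_names, xs, ys)


def sensitivities(model: OdeModel, theta, time_grid, input_signal=None,
                  rtol: float = 1e-8, atol: float = 1e-10,
                  method: str = "LSODA") -> SensitivityBundle:
    """States, outputs and their sensitivities to the unknown quantities."""
    cm = _compiled(model)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing with >= 2 points")
    p, _ = cm.split_theta(theta)
    n_s, n_th, n_p = cm.n_states, cm.n_theta, cm.n_params
    x0 = cm.initial_state(theta)
    S0 = np.zeros((n_s, n_th))
    for j, sname in enumerate(cm.theta_ic_states):
        S0[cm.state_names.index(sname), n_p + j] = 1.0

    def rhs(tt, z):
        u = _input_values(model, input_signal, tt)
        x = z[:n_s]
        S = z[n_s:].reshape(n_s, n_th)
        fx = np.asarray(cm.f(x, p, u), dtype=float).ravel()
        Jx = np.asarray(cm.jac_x(x, p, u), dtype=float)
        dS = Jx @ S
        if n_p:
            dS[:, :n_p] += np.asarray(cm.jac_p(x, p, u), dtype=float)
        return np.concatenate([fx, dS.ravel()])

    z0 = np.concatenate([x0, S0.ravel()])
    sol = solve_ivp(rhs, (t[0], t[-1]), z0, t_eval=t, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success or sol.y.shape[1] != t.size:
        last = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationError(
            f"sensitivity integration of {model.name!r} failed: {sol.message}",
            last)
    Z = sol.y.T
    xs = Z[:, :n_s]
    Ss = Z[:, n_s:].reshape(t.size, n_s, n_th)
    ys = np.empty((t.size, cm.n_outputs))
    Sy = np.empty((t.size, cm.n_outputs, n_th))
    for i, tt in enumerate(t):
        u = _input_values(model, input_signal, tt)
        ys[i] = np.asarray(cm.g(xs[i], p, u), dtype=float).ravel()
        Gx = np.asarray(cm.g_x(xs[i], p, u), dtype=float)
        Sy[i] = Gx @ Ss[i]
        if n_p:
            Sy[i][:, :n_p] += np.asarray(cm.g_p(xs[i], p, u), dtype=float)
    traj = Trajectory(t, cm.state_names, cm.output_names, xs, ys)
    return SensitivityBundle(traj, list(cm.theta_names), Ss, Sy)


def generate_synthetic_data(model: OdeModel, theta_true, time_grid,
                            input_signal=None, sigma=0.05,
                            noise: str = "additive", seed: int = 0,
                            outputs: list[str] | None = None,
                            rtol: float = 1e-8,
                            atol: float = 1e-10) -> pd.DataFrame:
    """Noisy observation table: ``time`` plus one column per measured output.

    ``sigma`` is a scalar or per-output dict; ``noise`` is ``'additive'``
    (constant SD) or ``'relative'`` (SD proportional to |y|).  ``sigma=0``
    returns the noise-free outputs; identical seeds give identical tables.
    """
    if noise not in ("additive", "relative"):
        raise ValueError("noise must be 'additive' or 'relative'")
    traj = simulate(model, theta_true, time_grid, input_signal,
                    rtol=rtol, atol=atol)
    names = outputs if outputs is not None else traj.output_names
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"time": traj.time_grid})
    for n in names:
        y = traj.output(n)
        s = float(sigma[n]) if isinstance(sigma, dict) else float(sigma)
        if s < 0:
            raise ValueError("sigma must be non-negative")
        sd = s * np.abs(y) if noise == "relative" else s
        df[n] = y + rng.normal(0.0, 1.0, size=y.shape) * sd
    return df
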