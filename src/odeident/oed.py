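"""D-optimal experiment design over input signals.

The design problem: given nominal parameter values, fixed sampling times and
a Gaussian noise spec, choose the input signal (a constant level or a
piecewise-linear profile on equally spaced nodes) that maximizes
log det(FIM), i.e. minimizes the volume of the asymptotic confidence
ellipsoid of the parameter estimates.  The objective is non-convex in the
node values, so a multistart bounded local search is used; because constant
signals are a subspace of piecewise-linear ones, the piecewise search is
additionally warm-started from a coarse constant-level scan, which makes
the design-space nesting property hold up to optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import OdeModel
from .practical import Design, FimReport, compute_fim
from .simulate import ConstantInput, IntegrationError, PiecewiseLinearInput

__all__ = [
    "DesignSpace",
    "DesignResult",
    "DesignInfeasibleError",
    "optimize_design",
    "compare_designs",
]


class DesignInfeasibleError(RuntimeError):
    """Raised when every candidate design yields a singular FIM."""


@dataclass
class DesignSpace:
    """Search space of the input-design problem.

    Defaults document the package's reference configuration for the
    chemostat example: horizon [0, 50] h, 20 uniform sampling times, 5
    equally spaced piecewise-linear nodes, feed concentration in [0, 100],
    sigma = 0.05 per output.
    """

    theta_nominal: dict
    input_kind: str = "piecewise_linear"  # or "constant"
    n_nodes: int = 5
    input_bounds: tuple[float, float] = (0.0, 100.0)
    horizon: tuple[float, float] = (0.0, 50.0)
    sampling_times: np.ndarray | None = None  # default: 20 uniform in horizon
    n_times: int = 20
    sigma: dict[str, float] | float = 0.05
    outputs: list[str] | None = None

    def __post_init__(self):
        if self.input_kind not in ("constant", "piecewise_linear"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        lo, hi = self.input_bounds
        if lo > hi:
            raise ValueError("input_bounds must satisfy u_min <= u_max")
        if self.input_kind == "piecewise_linear" and self.n_nodes < 2:
            raise ValueError("piecewise_linear needs at least 2 nodes")
        t0, tf = self.horizon
        if tf <= t0:
            raise ValueError("horizon must satisfy tf > t0")
        if self.sampling_times is None:
            self.sampling_times = np.linspace(t0, tf, self.n_times)
        else:
            self.sampling_times = np.asarray(self.sampling_times, dtype=float)
            if (self.sampling_times.min() < t0 - 1e-12
                    or self.sampling_times.max() > tf + 1e-12):
                raise ValueError("sampling_times must lie within the horizon")

    @property
    def n_vars(self) -> int:
        return 1 if self.input_kind == "constant" else self.n_nodes

    def node_times(self) -> np.ndarray:
        t0, tf = self.horizon
        return np.linspace(t0, tf, self.n_nodes)

    def signal(self, u: np.ndarray):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if self.input_kind == "constant":
            return ConstantInput(float(u[0]))
        return PiecewiseLinearInput(tuple(self.node_times()), tuple(u))

    def design(self, u: np.ndarray) -> Design:
        return Design(times=self.sampling_times, sigma=self.sigma,
                      input_signal=self.signal(u), outputs=self.outputs)


@dataclass
class DesignResult:
    space: DesignSpace
    optimal_input: np.ndarray  # node values, or length-1 array for constant
    fim_report: FimReport
    objective_trace: list[float]  # per-start best log_det
    n_starts: int
    seed: int
    name: str = "design"

    @property
    def log_det(self) -> float:
        return self.fim_report.log_det

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_kind": self.space.input_kind,
            "node_times": self.space.node_times().tolist()
            if self.space.input_kind == "piecewise_linear" else None,
            "optimal_input": np.atleast_1d(self.optimal_input).tolist(),
            "log_det": float(self.log_det),
            "fim": self.fim_report.to_dict(),
            "objective_trace": [float(v) for v in self.objective_trace],
            "n_starts": int(self.n_starts),
            "seed": int(self.seed),
        }


def optimize_design(model: OdeModel, space: DesignSpace, n_starts: int = 10,
                    seed: int = 3, maxfev: int | None = None,
                    n_polish: int = 2, name: str | None = None) -> DesignResult:
    """Maximize log det(FIM) over the design space, deterministically.

    Candidate generation combines ``n_starts`` random inits, a coarse
    constant-level scan (the nesting warm start: constant signals are a
    subspace of piecewise-linear ones) and, for piecewise spaces, bang-bang
    node patterns — the shapes D-optimal inputs typically take; all 2^d
    patterns are enumerated when d <= 6, a seeded sample otherwise.  The
    ``n_polish`` best candidates are refined by a bounded local search.
    The returned design is the best input evaluated *anywhere* during the
    search, so its log_det dominates every evaluated candidate by
    construction.
    """
    lo, hi = space.input_bounds
    d = space.n_vars
    rng = np.random.default_rng(seed)

    best: dict = {"u": None, "ld": -np.inf}

    def objective(u):
        u = np.clip(np.asarray(u, dtype=float), lo, hi)
        try:
            rep = compute_fim(model, space.theta_nominal, space.design(u))
        except IntegrationError:
            return np.inf
        ld = rep.log_det
        if np.isfinite(ld) and ld > best["ld"]:
            best["ld"] = ld
            best["u"] = u.copy()
        return -ld if np.isfinite(ld) else 1e12

    candidates: list[np.ndarray] = []
    if hi > lo:
        candidates += [lo + (hi - lo) * rng.random(d) for _ in range(n_starts)]
        # constant-level scan (skips u_min, which is often the zero input)
        candidates += [np.full(d, lev) for lev in np.linspace(lo, hi, 9)[1:]]
        if d > 1:
            if d <= 6:
                patterns = np.array(
                    [[(m >> i) & 1 for i in range(d)] for m in range(2 ** d)]
                )
            else:
                patterns = rng.integers(0, 2, size=(2 * n_starts, d))
            candidates += [lo + (hi - lo) * pat.astype(float)
                           for pat in patterns]
    else:
        candidates = [np.full(d, lo)]

    trace: list[float] = []
    scored = []
    for u in candidates:
        val = objective(u)
        trace.append(-val if np.isfinite(val) else -np.inf)
        scored.append((val, u))

    bounds = [(lo, hi)] * d
    options = {"maxfev": maxfev if maxfev else 40 * d}
    scored.sort(key=lambda t: t[0])
    if hi > lo:
        for val, x0 in scored[:max(n_polish, 0)]:
            if not np.isfinite(val):
                continue
            res = minimize(objective, x0, method="Powell", bounds=bounds,
                           options=options)
            trace.append(-float(res.fun) if np.isfinite(res.fun) else -np.inf)

    if best["u"] is None:
        raise DesignInfeasibleError(
            "every candidate design yielded a singular FIM"
        )
    u_opt = best["u"]
    rep = compute_fim(model, space.theta_nominal, space.design(u_opt))
    return DesignResult(space, np.atleast_1d(u_opt), rep, trace,
                        n_starts, seed,
                        name=name or space.input_kind)


def compare_designs(designs) -> dict:
    """Tabulate det(FIM) and per-quantity SDs, with pairwise ratios.

    Accepts :class:`DesignResult` objects or plain dicts
    ``{"name", "det", "sds": {...}}`` (e.g. values transcribed from a
    reference table).  Ratios are second/first for every ordered pair.
    """
    rows = []
    for i, dsg in enumerate(designs):
        if isinstance(dsg, DesignResult):
            rows.append({
                "name": dsg.name or f"design{i}",
                "det": dsg.fim_report.det,
                "sds": dict(dsg.fim_report.sds or {}),
            })
        else:
            rows.append({
                "name": dsg.get("name", f"design{i}"),
                "det": float(dsg["det"]),
                "sds": {k: float(v) for k, v in dsg.get("sds", {}).items()},
            })
    table = pd.DataFrame([
        {"name": r["name"], "det": r["det"],
         **{f"sd_{k}": v for k, v in r["sds"].items()}}
        for r in rows
    ])
    ratios = []
    for i, a in enumerate(rows):
        for j, b in enumerate(rows):
            if i == j:
                continue
            entry = {
                "from": a["name"], "to": b["name"],
                "det_ratio": b["det"] / a["det"] if a["det"] else np.inf,
            }
            for k in a["sds"]:
                if k in b["sds"] and a["sds"][k]:
                    entry[f"sd_ratio_{k}"] = b["sds"][k] / a["sds"][k]
            ratios.append(entry)
    return {"table": table, "ratios": pd.DataFrame(ratios)}
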