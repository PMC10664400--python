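"""Practical identifiability: FIM, multistart least squares, profile likelihood.

Under independent Gaussian observation noise with per-output SD sigma, the
Fisher information matrix of a design with sampling times t_k is

    FIM = sum_k S_y(t_k)^T W S_y(t_k),    W = diag(1/sigma^2),

where S_y is the output-sensitivity matrix at t_k.  Its inverse lower-bounds
the estimator covariance (Cramér–Rao), so sqrt(diag(FIM^-1)) are asymptotic
parameter SDs.  The estimation objective is the matching weighted residual
sum of squares, so those SDs are in parameter units and the chi-square
profile-likelihood threshold applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import OdeModel
from .simulate import IntegrationError, sensitivities, simulate

__all__ = [
    "Design",
    "FimReport",
    "FitResult",
    "LikelihoodProfile",
    "EstimationError",
    "compute_fim",
    "fit_least_squares",
    "profile_likelihood",
    "cluster_termini",
]

# relative eigenvalue threshold below which the FIM is declared singular
_SINGULAR_RTOL = 1e-10


class EstimationError(RuntimeError):
    """Raised when every optimization start fails."""


@dataclass
class Design:
    """Sampling times, input signal and noise spec of one experiment."""

    times: np.ndarray
    sigma: dict[str, float] | float
    input_signal: object = None
    outputs: list[str] | None = None  # None: all model outputs

    def sigma_for(self, output: str) -> float:
        s = self.sigma[output] if isinstance(self.sigma, dict) else self.sigma
        s = float(s)
        if s <= 0:
            raise ValueError(f"sigma for output {output!r} must be positive")
        return s

    def describe(self) -> dict:
        return {
            "times": [float(t) for t in np.asarray(self.times)],
            "sigma": (
                {k: float(v) for k, v in self.sigma.items()}
                if isinstance(self.sigma, dict) else float(self.sigma)
            ),
            "outputs": list(self.outputs) if self.outputs else None,
            "input_signal": repr(self.input_signal),
        }


@dataclass
class FimReport:
    theta_names: list[str]
    fim: np.ndarray
    singular: bool
    rank: int
    log_det: float  # -inf when singular
    sds: dict[str, float] | None
    correlations: np.ndarray | None
    condition_number: float
    null_directions: list[np.ndarray]
    design: dict

    @property
    def det(self) -> float:
        return float(np.exp(self.log_det)) if np.isfinite(self.log_det) else 0.0

    def to_dict(self) -> dict:
        return {
            "theta_names": list(self.theta_names),
            "fim": self.fim.tolist(),
            "singular": bool(self.singular),
            "rank": int(self.rank),
            "log_det": float(self.log_det),
            "sds": (
                {k: float(v) for k, v in self.sds.items()}
                if self.sds is not None else None
            ),
            "correlations": (
                self.correlations.tolist()
                if self.correlations is not None else None
            ),
            "condition_number": float(self.condition_number),
            "null_directions": [v.tolist() for v in self.null_directions],
            "design": self.design,
        }


def fim_from_output_sens(output_sens: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """FIM = sum over times of S_y^T diag(w) S_y (w = 1/sigma^2 per output)."""
    n_th = output_sens.shape[2]
    fim = np.zeros((n_th, n_th))
    for k in range(output_sens.shape[0]):
        Sk = output_sens[k]
        fim += Sk.T @ (weights[:, None] * Sk)
    return 0.5 * (fim + fim.T)


def _fim_report(fim: np.ndarray, theta_names: list[str], design: dict) -> FimReport:
    eig, vec = np.linalg.eigh(fim)
    top = eig[-1] if eig.size else 0.0
    tol = max(top, 0.0) * _SINGULAR_RTOL
    rank = int(np.sum(eig > tol))
    singular = rank < len(theta_names)
    null_dirs = [vec[:, i] for i in range(len(eig)) if eig[i] <= tol]
    if singular:
        log_det, sds, corr, cond = -np.inf, None, None, np.inf
    else:
        sign, log_det = np.linalg.slogdet(fim)
        if sign <= 0:
            log_det = -np.inf
        cov = np.linalg.inv(fim)
        d = np.sqrt(np.diag(cov))
        sds = dict(zip(theta_names, d))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        cond = float(eig[-1] / eig[0])
    return FimReport(list(theta_names), fim, singular, rank, float(log_det),
                     sds, corr, cond, null_dirs, design)


def compute_fim(model: OdeModel, theta_nominal, design: Design,
                rtol: float = 1e-8, atol: float = 1e-10) -> FimReport:
    """Fisher information of ``design`` at the nominal unknown quantities.

    A singular FIM is a flagged result (``singular=True``, SDs undefined,
    null directions reported), not an exception.
    """
    bundle = sensitivities(model, theta_nominal, np.asarray(design.times, float),
                           design.input_signal, rtol=rtol, atol=atol)
    out_names = design.outputs or bundle.trajectory.output_names
    idx = [bundle.trajectory.output_names.index(o) for o in out_names]
    S = bundle.output_sens[:, idx, :]
    w = np.array([1.0 / design.sigma_for(o) ** 2 for o in out_names])
    fim = fim_from_output_sens(S, w)
    return _fim_report(fim, bundle.theta_names, design.describe())


# ---------------------------------------------------------------------------
# weighted least squares


def _data_arrays(model: OdeModel, data: pd.DataFrame):
    if "time" not in data.columns:
        raise ValueError("data table must have a 'time' column")
    outs = [c for c in data.columns if c != "time"]
    unknown_outs = [c for c in outs if c not in model.outputs]
    if unknown_outs:
        raise ValueError(f"data columns {unknown_outs} are not model outputs")
    times = data["time"].to_numpy(dtype=float)
    obs = data[outs].to_numpy(dtype=float)
    return times, outs, obs


def _residual_fn(model: OdeModel, data: pd.DataFrame, sigma, input_signal,
                 theta_names: list[str], rtol: float, atol: float):
    times, outs, obs = _data_arrays(model, data)
    sig = np.array([
        float(sigma[o]) if isinstance(sigma, dict) else float(sigma)
        for o in outs
    ])
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive for every measured output")

    def resid(vec):
        try:
            traj = simulate(model, vec, times, input_signal,
                            rtol=rtol, atol=atol)
        except IntegrationError:
            return np.full(obs.size, 1e6)
        pred = np.column_stack([traj.output(o) for o in outs])
        return ((pred - obs) / sig).ravel()

    return resid, times, outs, sig


@dataclass
class FitResult:
    theta_names: list[str]
    theta_hat: dict[str, float]
    rss: float
    n_starts: int
    converged_fraction: float
    termini: list[tuple[np.ndarray, float]] = field(repr=False)
    fim_at_hat: FimReport | None = None

    def to_dict(self) -> dict:
        return {
            "theta_hat": {k: float(v) for k, v in self.theta_hat.items()},
            "rss": float(self.rss),
            "n_starts": int(self.n_starts),
            "converged_fraction": float(self.converged_fraction),
            "fim_at_hat": self.fim_at_hat.to_dict() if self.fim_at_hat else None,
        }


def fit_least_squares(model: OdeModel, data: pd.DataFrame,
                      theta_bounds: dict[str, tuple[float, float]],
                      sigma=1.0, n_starts: int = 20, seed: int = 0,
                      input_signal=None, compute_fim_at_hat: bool = True,
                      rtol: float = 1e-8, atol: float = 1e-10) -> FitResult:
    """Multistart weighted least squares over the unknown quantities.

    Starts are Latin-hypercube samples in log-space within ``theta_bounds``
    (keyed by unknown names; bare state names accepted for unknown ICs),
    each refined by a bounded trust-region local solver.  Deterministic
    given ``seed``.
    """
    from .simulate import _compiled  # canonical theta ordering

    cm = _compiled(model)
    names = list(cm.theta_names)
    lo = np.empty(len(names))
    hi = np.empty(len(names))
    for i, n in enumerate(names):
        key = n if n in theta_bounds else n[:-3] if n.endswith("(0)") else n
        if key not in theta_bounds:
            raise ValueError(f"theta_bounds missing entry for {n!r}")
        lo[i], hi[i] = theta_bounds[key]
    if np.any(lo <= 0) or np.any(hi <= lo):
        raise ValueError("bounds must be positive with hi > lo")

    resid, times, outs, sig = _residual_fn(model, data, sigma, input_signal,
                                           names, rtol, atol)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n_starts)
    starts = 10 ** (np.log10(lo) + unit * (np.log10(hi) - np.log10(lo)))

    termini: list[tuple[np.ndarray, float]] = []
    n_ok = 0
    for x0 in starts:
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success or res.status > 0:
            n_ok += 1
        termini.append((res.x.copy(), float(np.sum(res.fun ** 2))))
    if not termini:
        raise EstimationError(
            f"all {n_starts} starts failed for model {model.name!r}"
        )
    termini.sort(key=lambda t: t[1])
    best_x, best_rss = termini[0]
    theta_hat = dict(zip(names, best_x))

    fim_rep = None
    if compute_fim_at_hat:
        design = Design(times=times, sigma=(
            sigma if isinstance(sigma, dict)
            else {o: float(sigma) for o in outs}
        ), input_signal=input_signal, outputs=outs)
        fim_rep = compute_fim(model, best_x, design, rtol=rtol, atol=atol)

    return FitResult(names, theta_hat, best_rss, n_starts,
                     n_ok / max(n_starts, 1), termini, fim_rep)


def cluster_termini(termini: list[tuple[np.ndarray, float]],
                    rtol: float = 1e-3,
                    rss_window: float | None = None) -> list[dict]:
    """Merge optimization termini within ``rtol`` relative distance.

    Returns one representative per cluster (best RSS first).  With
    ``rss_window`` set, only termini with RSS within that window of the best
    are clustered — used to count distinct equal-quality solutions.
    """
    if not termini:
        return []
    ordered = sorted(termini, key=lambda t: t[1])
    best_rss = ordered[0][1]
    if rss_window is not None:
        ordered = [t for t in ordered if t[1] <= best_rss + rss_window]
    clusters: list[dict] = []
    for x, rss in ordered:
        for c in clusters:
            ref = c["theta"]
            if np.all(np.abs(x - ref) <= rtol * np.maximum(np.abs(ref), 1e-12)):
                c["size"] += 1
                break
        else:
            clusters.append({"theta": x.copy(), "rss": rss, "size": 1})
    return clusters


@dataclass
class LikelihoodProfile:
    quantity: str
    grid: np.ndarray
    profiled_objective: np.ndarray
    theta_hat_value: float
    min_objective: float
    threshold: float
    ci: tuple[float, float] | None
    unbounded_low: bool
    unbounded_high: bool
    flat: bool
    failed_points: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "grid": self.grid.tolist(),
            "profiled_objective": self.profiled_objective.tolist(),
            "threshold": float(self.threshold),
            "ci": list(self.ci) if self.ci else None,
            "unbounded_low": self.unbounded_low,
            "unbounded_high": self.unbounded_high,
            "flat": self.flat,
            "failed_points": list(self.failed_points),
        }


def profile_likelihood(model: OdeModel, data: pd.DataFrame, quantity: str,
                       grid, sigma=1.0,
                       theta_bounds: dict[str, tuple[float, float]] | None = None,
                       fit: FitResult | None = None, threshold: float = 3.84,
                       seed: int = 0, n_starts: int = 8, input_signal=None,
                       rtol: float = 1e-8, atol: float = 1e-10
                       ) -> LikelihoodProfile:
    """Profile the weighted-RSS objective over one unknown quantity.

    For each grid value the quantity is fixed and all other unknowns are
    re-optimized (warm-started from the neighbouring grid point).  The CI is
    the grid interval where the profile stays within ``threshold`` of its
    minimum (default 3.84: chi-square, 1 df, 95%); a profile whose total
    variation is below ``threshold/100`` is flagged flat.  Failed grid
    points are flagged and skipped, the profile continues.
    """
    from .simulate import _compiled

    cm = _compiled(model)
    names = list(cm.theta_names)
    if quantity not in names:
        if f"{quantity}(0)" in names:
            quantity = f"{quantity}(0)"
        else:
            raise ValueError(f"{quantity!r} is not an unknown quantity of "
                             f"{model.name!r} ({names})")
    qi = names.index(quantity)
    grid = np.asarray(grid, dtype=float)

    if fit is None:
        if theta_bounds is None:
            raise ValueError("theta_bounds required when no fit is supplied")
        fit = fit_least_squares(model, data, theta_bounds, sigma=sigma,
                                n_starts=n_starts, seed=seed,
                                input_signal=input_signal,
                                compute_fim_at_hat=False,
                                rtol=rtol, atol=atol)
    hat = np.array([fit.theta_hat[n] for n in names])
    resid, *_ = _residual_fn(model, data, sigma, input_signal, names,
                             rtol, atol)
    others = [i for i in range(len(names)) if i != qi]

    if theta_bounds is not None:
        lo = np.array([theta_bounds.get(n, theta_bounds.get(n[:-3] if n.endswith("(0)") else n))[0] for n in names])
        hi = np.array([theta_bounds.get(n, theta_bounds.get(n[:-3] if n.endswith("(0)") else n))[1] for n in names])
    else:
        lo = np.maximum(hat * 1e-3, 1e-12)
        hi = hat * 1e3

    def objective_at(qval, warm):
        full = np.empty(len(names))
        full[qi] = qval
        if not others:
            full_res = resid(full)
            return float(np.sum(full_res ** 2)), warm
        def sub_res(sub):
            full[others] = sub
            return resid(full)
        res = least_squares(sub_res, np.clip(warm, lo[others], hi[others]),
                            bounds=(lo[others], hi[others]), method="trf",
                            xtol=1e-10, ftol=1e-10)
        return float(np.sum(res.fun ** 2)), res.x

    prof = np.full(grid.size, np.nan)
    failed: list[int] = []
    start_idx = int(np.argmin(np.abs(grid - hat[qi])))
    for direction in (range(start_idx, grid.size), range(start_idx - 1, -1, -1)):
        warm = hat[others].copy()
        for i in direction:
            try:
                prof[i], warm = objective_at(grid[i], warm)
            except Exception:
                failed.append(i)
    ok = np.isfinite(prof)
    if not np.any(ok):
        raise EstimationError(f"profile of {quantity!r} failed at every grid point")
    mn = float(np.nanmin(prof))
    inside = ok & (prof <= mn + threshold)
    idx = np.where(inside)[0]
    ci = (float(grid[idx[0]]), float(grid[idx[-1]])) if idx.size else None
    flat = bool(np.nanmax(prof) - mn < threshold * 1e-2)
    return LikelihoodProfile(
        quantity=quantity, grid=grid, profiled_objective=prof,
        theta_hat_value=float(hat[qi]), min_objective=mn, threshold=threshold,
        ci=ci,
        unbounded_low=bool(idx.size and idx[0] == 0),
        unbounded_high=bool(idx.size and idx[-1] == grid.size - 1),
        flat=flat, failed_points=sorted(failed),
    )
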