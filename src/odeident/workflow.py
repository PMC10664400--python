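"""Upstream analysis workflow: structural first, then practical / design.

Structural identifiability is checked before any data-dependent step; when
a quantity is structurally non-identifiable, practical SD reporting is
short-circuited with an explicit warning (structural non-identifiability
implies practical non-identifiability — no finite design can repair it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .model import ModelValidationError, ObservationSetup, OdeModel
from .oed import DesignSpace, optimize_design
from .practical import Design, compute_fim, fit_least_squares
from .structural import count_output_equivalent_params, test_local_identifiability

__all__ = ["AnalysisReport", "WorkflowError", "run_workflow"]

STAGES = ("structural", "practical", "oed")


class WorkflowError(ValueError):
    """Invalid workflow configuration."""


@dataclass
class AnalysisReport:
    model_name: str
    config: dict
    structural: dict | None = None
    practical: dict | None = None
    design: dict | None = None
    warnings: list[str] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    tool_version: str = __version__
    exit_code: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "config": self.config,
            "structural": self.structural,
            "practical": self.practical,
            "design": self.design,
            "warnings": list(self.warnings),
            "seeds": dict(self.seeds),
            "tool_version": self.tool_version,
            "exit_code": self.exit_code,
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


def _jsonable_config(config: dict) -> dict:
    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple, np.ndarray)):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return float(v)
        if isinstance(v, pd.DataFrame):
            return f"<data table, {len(v)} rows>"
        return v
    return conv(config)


def run_workflow(model: OdeModel, config: dict) -> AnalysisReport:
    """Run the selected stages in order structural -> (oed | practical).

    ``config`` keys: ``stages`` (non-empty subset of structural, practical,
    oed), ``seed``, ``force`` (report practical SDs even under structural
    non-identifiability), plus per-stage option dicts ``structural``,
    ``practical`` (requires ``data`` and ``theta_bounds``), and ``oed``.
    """
    stages = list(config.get("stages", ()))
    if not stages:
        raise WorkflowError("config must select at least one stage")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise WorkflowError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    seed = int(config.get("seed", 17))
    force = bool(config.get("force", False))
    report = AnalysisReport(model.name, _jsonable_config(config))
    report.seeds["workflow"] = seed

    structurally_bad = False
    if "structural" in stages:
        opts = dict(config.get("structural", {}))
        setup = opts.get("setup")
        if setup is None:
            measured = tuple(opts.get("measure", tuple(model.outputs)))
            setup = ObservationSetup(
                measured,
                dict(opts.get("ic_overrides", {})),
                opts.get("input_class", "generic_smooth"),
            )
        res = test_local_identifiability(
            model, setup,
            max_order=opts.get("max_order"),
            n_points=int(opts.get("n_points", 3)),
            seed=seed,
        )
        report.structural = res.to_dict()
        report.seeds["structural"] = seed
        structurally_bad = not res.all_identifiable
        count_requested = opts.get("count_solutions", "auto")
        small = res.n_unknowns <= 4 and len(model.states) <= 3
        if count_requested is True or (count_requested == "auto" and small):
            try:
                sc = count_output_equivalent_params(model, setup, seed=seed)
                report.structural["solution_count"] = sc.to_dict()
            except (ModelValidationError, ValueError) as exc:
                report.warnings.append(f"solution counting skipped: {exc}")

    if "oed" in stages:
        opts = dict(config.get("oed", {}))
        space = opts.get("space")
        if space is None:
            nominal = opts.get("theta_nominal",
                               model.metadata.get("nominal_theta"))
            if nominal is None:
                raise WorkflowError("oed stage needs theta_nominal")
            space = DesignSpace(theta_nominal=dict(nominal),
                                **{k: v for k, v in opts.items()
                                   if k in ("input_kind", "n_nodes",
                                            "input_bounds", "horizon",
                                            "n_times", "sigma", "outputs")})
        dres = optimize_design(model, space,
                               n_starts=int(opts.get("n_starts", 10)),
                               seed=seed)
        report.design = dres.to_dict()
        report.seeds["oed"] = seed

    if "practical" in stages:
        opts = dict(config.get("practical", {}))
        suppress = structurally_bad and not force
        if structurally_bad:
            report.warnings.append(
                "structurally non-identifiable; practical SDs suppressed"
                if suppress else
                "structurally non-identifiable; practical SDs reported "
                "under --force and are not trustworthy"
            )
        practical: dict = {}
        data = opts.get("data")
        if data is not None and not suppress:
            fit = fit_least_squares(
                model, data, opts["theta_bounds"],
                sigma=opts.get("sigma", 1.0),
                n_starts=int(opts.get("n_starts", 20)),
                seed=seed, input_signal=opts.get("input_signal"),
            )
            practical["fit"] = fit.to_dict()
        elif opts.get("theta_nominal") is not None and not suppress:
            design = opts.get("design")
            if design is None:
                raise WorkflowError("practical FIM stage needs a design")
            rep = compute_fim(model, opts["theta_nominal"], design)
            practical["fim"] = rep.to_dict()
        practical["suppressed"] = suppress
        report.practical = practical
        report.seeds["practical"] = seed
        if suppress and (data is not None or opts.get("theta_nominal")):
            report.exit_code = 4

    return report
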