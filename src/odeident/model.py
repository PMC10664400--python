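"""Symbolic ODE model container, JSON (de)serialization and validation.

A model is the standard state-space system

    dx/dt = f(x, u, p),    y = g(x, u, p),    x(0) = x0,

with states ``x``, inputs ``u``, parameters ``p`` and outputs ``y``.  Each
state's initial condition and each parameter is declared either *known*
(with a numeric value) or *unknown*; the unknown quantities — unknown
parameters followed by unknown initial conditions — form the vector that
every identifiability computation in this package refers to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import sympy as sp

from .expr import parse_expression, serialize_expression

__all__ = [
    "StateSpec",
    "ParamSpec",
    "OdeModel",
    "ObservationSetup",
    "ModelValidationError",
    "parse_model",
    "substitute_known",
    "ic_name",
]


class ModelValidationError(ValueError):
    """Raised when a model definition violates the schema or its invariants."""


@dataclass(frozen=True)
class StateSpec:
    """One state variable: name, whether its IC is known, and its value."""

    name: str
    ic_known: bool = True
    ic_value: float | None = None
    positive: bool = True


@dataclass(frozen=True)
class ParamSpec:
    """One parameter: unknown (to be identified) or known with a value."""

    name: str
    known: bool = False
    value: float | None = None
    positive: bool = True


def ic_name(state: str) -> str:
    """Name used for the unknown initial condition of ``state`` in reports."""
    return f"{state}(0)"


@dataclass
class OdeModel:
    name: str
    states: tuple[StateSpec, ...]
    parameters: tuple[ParamSpec, ...]
    inputs: tuple[str, ...] = ()
    constants: dict[str, float] = field(default_factory=dict)
    odes: dict[str, sp.Expr] = field(default_factory=dict)
    outputs: dict[str, sp.Expr] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- symbol tables -------------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def symbol(self, name: str) -> sp.Symbol:
        return sp.Symbol(name, real=True)

    @property
    def symbols(self) -> dict[str, sp.Symbol]:
        """All declared symbols (states, parameters, inputs, constants)."""
        names = (
            self.state_names
            + self.param_names
            + list(self.inputs)
            + list(self.constants)
        )
        return {n: self.symbol(n) for n in names}

    # -- unknown-quantity vector ---------------------------------------
    @property
    def unknown_parameters(self) -> list[ParamSpec]:
        return [p for p in self.parameters if not p.known]

    @property
    def known_parameters(self) -> list[ParamSpec]:
        return [p for p in self.parameters if p.known]

    @property
    def unknown_ic_states(self) -> list[StateSpec]:
        return [s for s in self.states if not s.ic_known]

    def unknown_names(self) -> list[str]:
        """Unknown parameters, then unknown ICs (augmented-column order)."""
        return [p.name for p in self.unknown_parameters] + [
            ic_name(s.name) for s in self.unknown_ic_states
        ]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        names = (
            self.state_names
            + self.param_names
            + list(self.inputs)
            + list(self.constants)
        )
        seen = set()
        for n in names:
            if n in seen:
                raise ModelValidationError(f"duplicate name {n!r} in model {self.name!r}")
            seen.add(n)
        if set(self.odes) != set(self.state_names):
            raise ModelValidationError(
                f"model {self.name!r}: odes must have exactly one entry per state "
                f"(states={sorted(self.state_names)}, odes={sorted(self.odes)})"
            )
        if not self.outputs:
            raise ModelValidationError(f"model {self.name!r}: output map is empty")
        declared = set(names)
        for label, expr in list(self.odes.items()) + list(self.outputs.items()):
            for sym in expr.free_symbols:
                if sym.name not in declared:
                    raise ModelValidationError(
                        f"model {self.name!r}: expression for {label!r} uses "
                        f"undeclared symbol {sym.name!r}"
                    )
        for s in self.states:
            if s.ic_known and s.ic_value is None:
                raise ModelValidationError(
                    f"state {s.name!r}: known IC requires a value"
                )
        for p in self.parameters:
            if p.known and p.value is None:
                raise ModelValidationError(
                    f"parameter {p.name!r}: known status requires a value"
                )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": [
                {
                    "name": s.name,
                    "ic": (
                        {"known": True, "value": float(s.ic_value)}
                        if s.ic_known
                        else {"known": False}
                    ),
                    "positive": s.positive,
                }
                for s in self.states
            ],
            "parameters": [
                {
                    "name": p.name,
                    "known": p.known,
                    **({"value": float(p.value)} if p.known else {}),
                    "positive": p.positive,
                }
                for p in self.parameters
            ],
            "inputs": list(self.inputs),
            "constants": {k: float(v) for k, v in self.constants.items()},
            "odes": {k: serialize_expression(v) for k, v in self.odes.items()},
            "outputs": {k: serialize_expression(v) for k, v in self.outputs.items()},
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "OdeModel":
        try:
            states = tuple(
                StateSpec(
                    name=s["name"],
                    ic_known=bool(s["ic"]["known"]),
                    ic_value=s["ic"].get("value"),
                    positive=bool(s.get("positive", True)),
                )
                for s in d["states"]
            )
            parameters = tuple(
                ParamSpec(
                    name=p["name"],
                    known=bool(p["known"]),
                    value=p.get("value"),
                    positive=bool(p.get("positive", True)),
                )
                for p in d["parameters"]
            )
        except (KeyError, TypeError) as exc:
            raise ModelValidationError(f"malformed model definition: {exc}") from None
        model = cls(
            name=d.get("name", "model"),
            states=states,
            parameters=parameters,
            inputs=tuple(d.get("inputs", ())),
            constants=dict(d.get("constants", {})),
            metadata=dict(d.get("metadata", {})),
        )
        symbols = model.symbols
        model.odes = {
            k: parse_expression(v, symbols) for k, v in d.get("odes", {}).items()
        }
        model.outputs = {
            k: parse_expression(v, symbols) for k, v in d.get("outputs", {}).items()
        }
        model.validate()
        return model


def parse_model(text: str) -> OdeModel:
    """Parse a JSON model definition into a validated :class:`OdeModel`."""
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"invalid JSON: {exc}") from None
    return OdeModel.from_dict(d)


def substitute_known(model: OdeModel) -> OdeModel:
    """Fold known parameters and known ICs into numeric constants.

    Known parameters move to the constants map (the unknown-parameter list
    shrinks accordingly); known initial-condition values are already numeric
    in the state specs.  The operation is idempotent.
    """
    known = model.known_parameters
    if not known:
        return model
    constants = dict(model.constants)
    for p in known:
        constants[p.name] = float(p.value)
    return replace(
        model,
        parameters=tuple(p for p in model.parameters if not p.known),
        constants=constants,
    )


@dataclass
class ObservationSetup:
    """Which outputs are measured and how initial conditions are treated.

    ``ic_overrides`` maps a state name to ``None`` (treat its IC as unknown)
    or to a number (treat it as known at that value), overriding the model's
    own declaration.  ``input_class`` states the assumption on the input
    signal for structural analysis: a generic smooth signal (derivatives are
    free indeterminates), a constant, or no input at all.
    """

    measured_outputs: tuple[str, ...]
    ic_overrides: dict[str, float | None] = field(default_factory=dict)
    input_class: str = "generic_smooth"

    def __post_init__(self):
        self.measured_outputs = tuple(self.measured_outputs)
        if self.input_class not in ("generic_smooth", "constant", "none"):
            raise ModelValidationError(
                f"unknown input_class {self.input_class!r}"
            )

    def validate_for(self, model: OdeModel) -> None:
        if not self.measured_outputs:
            raise ModelValidationError("measured_outputs must be non-empty")
        for y in self.measured_outputs:
            if y not in model.outputs:
                raise ModelValidationError(f"{y!r} is not an output of {model.name!r}")
        for s in self.ic_overrides:
            if s not in model.state_names:
                raise ModelValidationError(f"{s!r} is not a state of {model.name!r}")

    def effective_ics(self, model: OdeModel) -> dict[str, float | None]:
        """Per-state IC status after overrides: value if known, None if unknown."""
        out: dict[str, float | None] = {}
        for s in model.states:
            if s.name in self.ic_overrides:
                ov = self.ic_overrides[s.name]
                out[s.name] = None if ov is None else float(ov)
            else:
                out[s.name] = float(s.ic_value) if s.ic_known else None
        return out

    def unknown_names(self, model: OdeModel) -> list[str]:
        """Unknown quantities under this setup (params first, then ICs)."""
        ics = self.effective_ics(model)
        return [p.name for p in model.unknown_parameters] + [
            ic_name(s.name) for s in model.states if ics[s.name] is None
        ]
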