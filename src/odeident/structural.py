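"""Local structural identifiability via the observability rank condition.

The time derivatives of a measured output y = h(x, u, p) along the vector
field f are its Lie derivatives,

    L^0 h = h,    L^{j+1} h = (dL^j h/dx) f + sum_i (dL^j h/du^(i)) u^(i+1),

and the Taylor coefficients of y at t = 0 are the Lie derivatives evaluated
at the initial state.  A quantity (unknown parameter or unknown initial
condition) is locally structurally identifiable exactly when the Jacobian of
the stacked Lie derivatives with respect to the unknown-quantity vector has,
generically, full column rank; rank deficiency exposes locally compensable
parameter directions through the Jacobian null space.

Rank evaluation is exact: the Jacobian is evaluated at random *rational*
points and its rank computed in exact arithmetic, so there is no
floating-point rank tolerance to tune.  Non-rational models (exponential
growth kinetics) stay exact too: after substituting the rational point every
``exp`` atom has a rational argument q, and since e^q is transcendental for
rational q != 0 all such atoms are integer powers of a single transcendental
generator, which is replaced by a fresh symbol before the rank is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model import ModelValidationError, ObservationSetup, OdeModel, ic_name

__all__ = [
    "StructuralResult",
    "SolutionCount",
    "BudgetExceededError",
    "lie_derivatives",
    "test_local_identifiability",
    "nullspace_directions",
    "count_output_equivalent_params",
    "input_derivative_symbol",
]

LOCALLY_IDENTIFIABLE = "locally_identifiable"
NON_IDENTIFIABLE = "non_identifiable"


class BudgetExceededError(RuntimeError):
    """Raised when stacked Lie derivatives exceed the expression-node budget."""


def input_derivative_symbol(name: str, order: int) -> sp.Symbol:
    """Symbol for the ``order``-th time derivative of input ``name``."""
    if order == 0:
        return sp.Symbol(name, real=True)
    return sp.Symbol(f"{name}_d{order}", real=True)


class _LieStack:
    """Incrementally stacked Lie derivatives of the measured outputs."""

    def __init__(self, model: OdeModel, setup: ObservationSetup,
                 node_budget: int = 500_000):
        self.model = model
        self.setup = setup
        self.node_budget = node_budget
        self.state_syms = [sp.Symbol(s, real=True) for s in model.state_names]
        self.f = [model.odes[s] for s in model.state_names]
        self.current = [model.outputs[y] for y in setup.measured_outputs]
        self.rows: list[sp.Expr] = list(self.current)
        self.order = 0

    def extend(self) -> list[sp.Expr]:
        """Add one more derivative order; return the new rows."""
        j = self.order
        new = []
        for e in self.current:
            d = sum(sp.diff(e, x) * fx for x, fx in zip(self.state_syms, self.f))
            if self.setup.input_class == "generic_smooth":
                for u in self.model.inputs:
                    for i in range(j + 1):
                        du = sp.diff(e, input_derivative_symbol(u, i))
                        if du != 0:
                            d = d + du * input_derivative_symbol(u, i + 1)
            new.append(sp.expand(d) if d.is_Add else d)
        self.current = new
        self.rows.extend(new)
        self.order += 1
        nodes = sum(sp.count_ops(e) for e in self.rows)
        if nodes > self.node_budget:
            raise BudgetExceededError(
                f"Lie-derivative stack reached {nodes} expression nodes at "
                f"order {self.order} (budget {self.node_budget})"
            )
        return new


def lie_derivatives(model: OdeModel, setup: ObservationSetup, order: int,
                    node_budget: int = 500_000) -> list[sp.Expr]:
    """Stacked Lie derivatives ``{L^0 h, ..., L^order h}``, order-major.

    Under ``input_class='generic_smooth'`` the input time derivatives enter
    as free indeterminates; under ``'constant'`` they vanish.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    setup.validate_for(model)
    stack = _LieStack(model, setup, node_budget)
    for _ in range(order):
        stack.extend()
    return stack.rows


# ---------------------------------------------------------------------------
# exact-arithmetic rank machinery


def _rationalize(value: float) -> sp.Rational:
    return sp.Rational(str(value))


def _exp_to_symbol(M: sp.Matrix) -> sp.Matrix:
    """Replace exp(rational) atoms by powers of one transcendental symbol."""
    exps = sorted(M.atoms(sp.exp), key=sp.default_sort_key)
    if not exps:
        return M
    args = []
    for e in exps:
        a = e.args[0]
        if not a.is_Rational:
            raise ValueError(f"non-rational exponential argument {a} after "
                             "point substitution")
        args.append(a)
    g = args[0]
    for a in args[1:]:
        g = sp.gcd(g, a)
    gen = sp.Symbol("_expgen", positive=True)
    sub = {e: gen ** int(a / g) for e, a in zip(exps, args)}
    return M.xreplace(sub)


def _exact_rank(M: sp.Matrix) -> int:
    if M.rows == 0 or M.cols == 0:
        return 0
    if all(e.is_Rational for e in M):
        return M.rank()
    return M.rank(
        iszerofunc=lambda e: bool(sp.cancel(sp.together(e)) == 0),
        simplify=lambda e: sp.cancel(sp.together(e)),
    )


def _normalize_rational_vector(v: sp.Matrix) -> list:
    entries = list(v)
    if not all(e.is_Rational for e in entries):
        entries = [sp.cancel(e) for e in entries]
        if not all(e.is_Rational for e in entries):
            return entries
    denoms = [e.q for e in entries]
    lcm = sp.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
    ints = [sp.Integer(e * lcm) for e in entries]
    nonzero = [abs(i) for i in ints if i != 0]
    g = sp.igcd(*nonzero) if len(nonzero) > 1 else (nonzero[0] if nonzero else 1)
    ints = [sp.Integer(i / g) for i in ints]
    lead = next((i for i in ints if i != 0), sp.Integer(1))
    if lead < 0:
        ints = [-i for i in ints]
    return ints


@dataclass
class StructuralResult:
    """Outcome of the generic rank test for one model and observation setup."""

    model_name: str
    measured_outputs: tuple[str, ...]
    generic_rank: int
    n_unknowns: int
    unknown_names: list[str]
    per_quantity_verdict: dict[str, str]
    nullspace_basis: list[list]
    evaluation_points_used: int
    seed: int
    orders_used: int
    warnings: list[str] = field(default_factory=list)
    # internals kept for nullspace_directions and diagnostics
    _matrix: sp.Matrix | None = field(default=None, repr=False, compare=False)
    _point: dict | None = field(default=None, repr=False, compare=False)

    @property
    def all_identifiable(self) -> bool:
        return self.generic_rank == self.n_unknowns

    def identifiable(self) -> list[str]:
        return [q for q, v in self.per_quantity_verdict.items()
                if v == LOCALLY_IDENTIFIABLE]

    def non_identifiable(self) -> list[str]:
        return [q for q, v in self.per_quantity_verdict.items()
                if v == NON_IDENTIFIABLE]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "measured_outputs": list(self.measured_outputs),
            "generic_rank": self.generic_rank,
            "n_unknowns": self.n_unknowns,
            "verdicts": dict(self.per_quantity_verdict),
            "nullspace": [[str(e) for e in v] for v in self.nullspace_basis],
            "evaluation_points_used": self.evaluation_points_used,
            "orders_used": self.orders_used,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def _evaluation_point(rng: np.random.Generator, symbols: list[sp.Symbol]) -> dict:
    return {s: sp.Integer(int(rng.integers(1, 1000))) for s in symbols}


def test_local_identifiability(
    model: OdeModel,
    setup: ObservationSetup | None = None,
    max_order: int | None = None,
    n_points: int = 3,
    seed: int = 17,
    node_budget: int = 500_000,
) -> StructuralResult:
    """Generic rank test of the observability-identifiability Jacobian.

    The Jacobian of the stacked Lie derivatives is taken with respect to the
    unknown quantities (unknown parameters, then unknown initial
    conditions); known initial conditions fix their states, so those columns
    carry no unknowns.  Derivative orders are added until the rank is
    unchanged for one extra order, full, or the cap
    ``n_states + n_unknowns - 1`` is reached.  The per-quantity verdict uses
    column elimination: a quantity is locally identifiable iff removing its
    column strictly decreases the rank.

    A diagnostic re-evaluates the final Jacobian at the *specific* known
    initial-condition values and warns when that rank is lower than the
    generic one (particular initial conditions can destroy identifiability).
    """
    if setup is None:
        setup = ObservationSetup(tuple(model.outputs))
    setup.validate_for(model)
    ics = setup.effective_ics(model)

    unknown_syms = [sp.Symbol(p.name, real=True) for p in model.unknown_parameters]
    unknown_names = [p.name for p in model.unknown_parameters]
    for s in model.states:
        if ics[s.name] is None:
            unknown_syms.append(sp.Symbol(s.name, real=True))
            unknown_names.append(ic_name(s.name))
    n_unknowns = len(unknown_syms)
    if n_unknowns == 0:
        raise ModelValidationError(
            f"model {model.name!r} has no unknown quantities under this setup"
        )
    n_states = len(model.states)
    cap = max_order if max_order is not None else n_states + n_unknowns - 1

    # every symbol that can appear in any Lie derivative up to the cap
    all_syms = [sp.Symbol(n, real=True) for n in (
        model.state_names + model.param_names + list(model.constants)
    )]
    for u in model.inputs:
        for j in range(cap + 2):
            all_syms.append(input_derivative_symbol(u, j))

    rng = np.random.default_rng(seed)
    points = [_evaluation_point(rng, all_syms) for _ in range(n_points)]

    stack = _LieStack(model, setup, node_budget)
    grads: list[list[sp.Expr]] = []
    mats: list[list[list]] = [[] for _ in points]
    warnings: list[str] = []

    def add_rows(exprs):
        for e in exprs:
            row = [sp.diff(e, s) for s in unknown_syms]
            grads.append(row)
            for pt, mat in zip(points, mats):
                mat.append([r.xreplace(pt) for r in row])

    add_rows(stack.rows)
    prev_rank = None
    while True:
        ranks = [_exact_rank(_exp_to_symbol(sp.Matrix(mat))) for mat in mats]
        r = max(ranks)
        if r == n_unknowns:
            break
        if prev_rank is not None and r == prev_rank and (r > 0 or stack.order >= 2):
            break
        if stack.order >= cap:
            break
        prev_rank = r
        add_rows(stack.extend())

    generic_rank = max(ranks)
    disagree = sum(1 for rk in ranks if rk != generic_rank)
    if disagree > 1:
        warnings.append(
            f"rank disagreement across evaluation points: {ranks} "
            f"({disagree} of {len(ranks)} points below the generic rank)"
        )

    best = ranks.index(generic_rank)
    M_best = _exp_to_symbol(sp.Matrix(mats[best]))

    verdicts: dict[str, str] = {}
    for i, name in enumerate(unknown_names):
        cols = [c for c in range(n_unknowns) if c != i]
        sub_rank = _exact_rank(M_best[:, cols]) if cols else 0
        verdicts[name] = (
            LOCALLY_IDENTIFIABLE if sub_rank < generic_rank else NON_IDENTIFIABLE
        )

    nullspace = [_normalize_rational_vector(v) for v in M_best.nullspace()]

    # diagnostic: generic verdict versus the specific known IC values
    known_subs = {
        sp.Symbol(s, real=True): _rationalize(v)
        for s, v in ics.items() if v is not None
    }
    if known_subs:
        pt = dict(points[best])
        pt.update(known_subs)
        try:
            M_spec = _exp_to_symbol(
                sp.Matrix([[r.xreplace(pt) for r in row] for row in grads])
            )
            spec_rank = _exact_rank(M_spec)
        except (ValueError, ZeroDivisionError):
            spec_rank = None
            warnings.append(
                "could not evaluate the Jacobian at the specific initial "
                "conditions (singular substitution)"
            )
        if spec_rank is not None and spec_rank < generic_rank:
            warnings.append(
                f"rank drops from {generic_rank} to {spec_rank} at the "
                "specific known initial conditions; these initial conditions "
                "may destroy identifiability"
            )

    return StructuralResult(
        model_name=model.name,
        measured_outputs=tuple(setup.measured_outputs),
        generic_rank=generic_rank,
        n_unknowns=n_unknowns,
        unknown_names=unknown_names,
        per_quantity_verdict=verdicts,
        nullspace_basis=nullspace,
        evaluation_points_used=len(points),
        seed=seed,
        orders_used=stack.order,
        warnings=warnings,
        _matrix=M_best,
        _point=points[best],
    )


def nullspace_directions(result: StructuralResult) -> list[list]:
    """Null-space basis of the identifiability Jacobian, smallest-integer form.

    Each vector is a locally compensable direction in unknown-quantity space
    (coordinates ordered as ``result.unknown_names``).  Full-rank results
    give an empty list.
    """
    if result.generic_rank >= result.n_unknowns:
        return []
    return [list(v) for v in result.nullspace_basis]


@dataclass
class SolutionCount:
    """Number of admissible parameterizations indistinguishable at the output."""

    count: int | str
    witnesses: list[dict]
    reference: dict

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "witnesses": [
                {k: float(v) for k, v in w.items()} for w in self.witnesses
            ],
            "reference": {k: float(v) for k, v in self.reference.items()},
        }


def count_output_equivalent_params(
    model: OdeModel,
    setup: ObservationSetup | None = None,
    taylor_order: int | None = None,
    seed: int = 23,
) -> SolutionCount:
    """Count parameterizations producing identical outputs, by exact solving.

    Equates the first Taylor coefficients of every measured output at t = 0
    between a random rational reference parameterization and a free one, and
    solves the resulting system symbolically.  Admissible solutions are real
    and respect declared positivity.  Intended for small models only
    (guarded at <= 4 unknowns and <= 3 states); a solver failure is reported
    as ``count='symbolic-failure'``, never as a silent wrong count.
    """
    if setup is None:
        setup = ObservationSetup(tuple(model.outputs))
    setup.validate_for(model)
    ics = setup.effective_ics(model)

    unknown_syms: list[sp.Symbol] = []
    positivity: dict[sp.Symbol, bool] = {}
    for p in model.unknown_parameters:
        s = sp.Symbol(p.name, real=True)
        unknown_syms.append(s)
        positivity[s] = p.positive
    for st in model.states:
        if ics[st.name] is None:
            s = sp.Symbol(st.name, real=True)
            unknown_syms.append(s)
            positivity[s] = st.positive
    n_unknowns = len(unknown_syms)
    if n_unknowns == 0:
        raise ModelValidationError("no unknown quantities to solve for")
    if n_unknowns > 4 or len(model.states) > 3:
        raise ModelValidationError(
            "exact solution counting is guarded to <= 4 unknowns and "
            f"<= 3 states; got {n_unknowns} unknowns, {len(model.states)} states"
        )
    order = taylor_order if taylor_order is not None else n_unknowns + 1
    if order < n_unknowns:
        raise ValueError("taylor_order must be at least the number of unknowns")

    # inputs are held constant at a random rational level shared by both sides
    const_setup = ObservationSetup(
        setup.measured_outputs, setup.ic_overrides, input_class="constant"
    )
    rows = lie_derivatives(model, const_setup, order)

    rng = np.random.default_rng(seed)
    fixed_subs: dict[sp.Symbol, sp.Rational] = {}
    for name, val in model.constants.items():
        fixed_subs[sp.Symbol(name, real=True)] = _rationalize(val)
    for p in model.known_parameters:
        fixed_subs[sp.Symbol(p.name, real=True)] = _rationalize(p.value)
    for name, val in ics.items():
        if val is not None:
            fixed_subs[sp.Symbol(name, real=True)] = _rationalize(val)
    for u in model.inputs:
        fixed_subs[sp.Symbol(u, real=True)] = sp.Integer(int(rng.integers(1, 20)))

    while True:
        reference = {
            s: sp.Rational(int(rng.integers(2, 20)), int(rng.integers(1, 7)))
            for s in unknown_syms
        }
        if len(set(reference.values())) == n_unknowns:
            break

    eqs = []
    for row in rows:
        lhs = row.xreplace(fixed_subs)
        rhs = lhs.xreplace(reference)
        eq = sp.Eq(lhs, rhs)
        if eq is sp.true:
            continue
        eqs.append(eq)
    if not eqs:
        return SolutionCount("symbolic-failure", [], _named(reference))

    try:
        sols = sp.solve(eqs, unknown_syms, dict=True)
    except Exception:
        return SolutionCount("symbolic-failure", [], _named(reference))
    if not sols:
        # the reference itself satisfies the system, so an empty answer
        # means the solver failed
        return SolutionCount("symbolic-failure", [], _named(reference))

    admissible = []
    for sol in sols:
        if set(sol) != set(unknown_syms):
            return SolutionCount("symbolic-failure", [], _named(reference))
        vals = {s: sp.nsimplify(sol[s]) for s in unknown_syms}
        if not all(v.is_number for v in vals.values()):
            continue
        if any(sp.im(v) != 0 for v in vals.values()):
            continue
        if any(positivity[s] and not (v > 0) for s, v in vals.items()):
            continue
        if any(vals == prev for prev in admissible):
            continue
        admissible.append(vals)

    witnesses = [_named(a) for a in admissible]
    return SolutionCount(len(admissible), witnesses, _named(reference))


def _named(d: dict) -> dict:
    return {s.name: v for s, v in d.items()}
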