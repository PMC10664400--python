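"""Expression grammar for model definitions.

Right-hand sides and output maps are written as plain strings over declared
symbols with ``+ - * / ^`` (``**`` accepted as an alias for ``^``), real
literals, and the functions ``exp``, ``log`` and ``sqrt``.  Anything else —
undeclared names, other functions, conditionals — is rejected at parse time
so that symbolic differentiation downstream is total.
"""

from __future__ import annotations

import tokenize

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

ALLOWED_FUNCTIONS: dict[str, sp.FunctionClass] = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
}


class ExpressionError(ValueError):
    """Base class for model-expression problems."""


class MalformedExpressionError(ExpressionError):
    """Raised when an expression string does not parse under the grammar."""

    def __init__(self, text: str, position: int | None, reason: str):
        self.text = text
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"malformed expression {text!r}{where}: {reason}")


class UndeclaredSymbolError(ExpressionError):
    """Raised when an expression references a name the model does not declare."""

    def __init__(self, symbol: str, text: str):
        self.symbol = symbol
        super().__init__(
            f"expression {text!r} references undeclared symbol {symbol!r}"
        )


def parse_expression(text: str, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    """Parse ``text`` into a sympy expression over the declared ``symbols``.

    Raises :class:`MalformedExpressionError` on syntax errors and
    :class:`UndeclaredSymbolError` when an unknown name appears.
    """
    if not isinstance(text, str) or not text.strip():
        raise MalformedExpressionError(str(text), None, "empty expression")
    source = text.replace("^", "**")
    local = dict(symbols)
    local.update(ALLOWED_FUNCTIONS)
    try:
        expr = parse_expr(
            source,
            local_dict=local,
            transformations=standard_transformations,
            evaluate=True,
        )
    except (SyntaxError, tokenize.TokenError) as exc:
        pos = getattr(exc, "offset", None)
        raise MalformedExpressionError(text, pos, str(exc)) from None
    except Exception as exc:  # sympification errors carry no position
        raise MalformedExpressionError(text, None, str(exc)) from None
    if not isinstance(expr, sp.Expr):
        raise MalformedExpressionError(text, None, "not a scalar expression")
    for sym in expr.free_symbols:
        if sym.name not in symbols:
            raise UndeclaredSymbolError(sym.name, text)
    for func in expr.atoms(sp.Function):
        name = type(func).__name__
        if name not in ALLOWED_FUNCTIONS:
            raise MalformedExpressionError(
                text, None, f"function {name!r} is not part of the grammar"
            )
    return expr


def serialize_expression(expr: sp.Expr) -> str:
    """Canonical string form (sympy printing, ``**`` for powers)."""
    return sp.sstr(expr)
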