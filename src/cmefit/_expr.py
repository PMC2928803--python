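"""Safe arithmetic expressions for config-defined propensities.

Supports numbers, named variables (species counts and rate constants),
``+ - * / **`` and unary minus.  The expression is validated against a
whitelist of AST node types before compilation, so model files can never
execute arbitrary code.
"""

from __future__ import annotations

import ast
from typing import Callable, Mapping

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Constant,
    ast.Name,
    ast.Load,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
)


class ExpressionError(ValueError):
    """Raised when a propensity formula is malformed or unsafe."""


def parse_expression(formula: str) -> tuple[Callable[[Mapping[str, float]], float], frozenset[str]]:
    """Compile *formula* into an evaluator.

    Returns ``(fn, names)`` where ``fn(env)`` evaluates the formula with
    variable values from the mapping *env* and ``names`` is the set of
    variable identifiers the formula references.
    """
    try:
        tree = ast.parse(formula, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message detail only
        raise ExpressionError(f"cannot parse formula {formula!r}: {exc}") from exc
    names: set[str] = set()
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"disallowed syntax {type(node).__name__!r} in formula {formula!r}"
            )
        if isinstance(node, ast.Name):
            names.add(node.id)
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant in formula {formula!r}")
    code = compile(tree, "<propensity>", "eval")

    def evaluate(env: Mapping[str, float]) -> float:
        return float(eval(code, {"__builtins__": {}}, dict(env)))

    return evaluate, frozenset(names)
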