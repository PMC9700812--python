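"""Tiny Boolean-expression evaluator for declarative rule definitions.

Rules are written in the field's logical notation — ``&`` (AND), ``|`` (OR),
``~`` (NOT), parentheses, the seven variable names, and the constants ``0``
and ``1`` — e.g. ``"Clb2_M | (Clb2_G & Cdc20)"``.  Expressions are parsed
with :mod:`ast` and compiled to plain Python functions over a bit tuple; no
arbitrary code is ever evaluated.
"""

from __future__ import annotations

import ast
from typing import Callable, Sequence

from .state import VAR_INDEX

BitFunction = Callable[[Sequence[int]], int]


def _compile_node(node: ast.AST) -> BitFunction:
    if isinstance(node, ast.Expression):
        return _compile_node(node.body)
    if isinstance(node, ast.BinOp) and isinstance(node.op, ast.BitOr):
        left, right = _compile_node(node.left), _compile_node(node.right)
        return lambda b: left(b) | right(b)
    if isinstance(node, ast.BinOp) and isinstance(node.op, ast.BitAnd):
        left, right = _compile_node(node.left), _compile_node(node.right)
        return lambda b: left(b) & right(b)
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Invert):
        operand = _compile_node(node.operand)
        return lambda b: 1 - operand(b)
    if isinstance(node, ast.Name):
        try:
            idx = VAR_INDEX[node.id]
        except KeyError:
            raise ValueError(f"unknown variable {node.id!r} in rule expression") from None
        return lambda b: b[idx]
    if isinstance(node, ast.Constant) and node.value in (0, 1):
        value = int(node.value)
        return lambda b: value
    raise ValueError(
        f"unsupported syntax in rule expression: {ast.dump(node)}; "
        "only &, |, ~, parentheses, variable names and 0/1 are allowed"
    )


def compile_expression(expr: str) -> BitFunction:
    """Compile a Boolean rule expression to a function of the 7-bit state."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"cannot parse rule expression {expr!r}: {exc}") from exc
    return _compile_node(tree)
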