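"""Exact rational arithmetic kernel.

Symbolic analysis of reaction networks requires that every numeric constant
be an exact rational number: floating-point literals carry representation
error, and rounding during evaluation silently destroys algebraic identities
(a conservation law that holds only to 1e-16 is not a conservation law).
This module converts numeric literals to :class:`fractions.Fraction`,
evaluates constant expressions in exact arithmetic, and flags expressions
whose value is (or cannot be proven not to be) irrational.

The irrationality test is conservative by construction: any transcendental
head (exp, log, trig, pi, e, a non-integer power that is not an exact
perfect power) applied to a non-identity argument is flagged irrational,
even if the value happened to be rational.  A false reject keeps the
downstream system exact; a false accept would not.
"""

from __future__ import annotations

import math
from decimal import Decimal, InvalidOperation
from fractions import Fraction

import sympy as sp

__all__ = [
    "ExactArithmeticError",
    "InvalidLiteralError",
    "BindingError",
    "ArithmeticEvalError",
    "Irrational",
    "IRRATIONAL",
    "literal_to_rational",
    "double_to_rational",
    "to_sympy_rational",
    "eval_constant",
]


class ExactArithmeticError(ValueError):
    """Base class for errors raised by the exact-arithmetic kernel."""


class InvalidLiteralError(ExactArithmeticError):
    """A lexical numeral is empty, NaN, infinite, or otherwise unparseable."""


class BindingError(ExactArithmeticError):
    """A constant expression references an identifier with no known value."""


class ArithmeticEvalError(ExactArithmeticError):
    """Division by zero or an otherwise undefined exact evaluation."""


class Irrational:
    """Singleton flag: a constant expression with provably-or-possibly
    irrational value.  Falsy so that ``env.get(x) or default`` never
    silently treats it as a number."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "IRRATIONAL"

    def __bool__(self) -> bool:
        return False


IRRATIONAL = Irrational()


def literal_to_rational(lexical: str) -> Fraction:
    """Convert a decimal or scientific-notation numeral to the exact
    rational it denotes.

    The conversion is lexical: ``"0.1"`` becomes 1/10, the number the
    modeller wrote, not the nearest IEEE-754 double.

    >>> literal_to_rational("0.5")
    Fraction(1, 2)
    >>> literal_to_rational("1e-3")
    Fraction(1, 1000)
    """
    if lexical is None:
        raise InvalidLiteralError("missing numeric literal")
    text = lexical.strip()
    if not text:
        raise InvalidLiteralError("empty numeric literal")
    try:
        value = Decimal(text)
    except InvalidOperation as exc:
        raise InvalidLiteralError(f"not a decimal numeral: {lexical!r}") from exc
    if not value.is_finite():
        raise InvalidLiteralError(f"non-finite literal: {lexical!r}")
    return Fraction(value)


def double_to_rational(v: float) -> Fraction:
    """Convert a finite IEEE-754 double to the exact rational it stores.

    Every finite double is a dyadic rational; e.g. the double nearest 0.1
    is 3602879701896397/36028797018963968.  Used only when a value is
    reachable solely as a binary double (no lexical form available).
    """
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise InvalidLiteralError(f"not a float: {v!r}")
    if math.isnan(v) or math.isinf(v):
        raise InvalidLiteralError(f"non-finite double: {v!r}")
    return Fraction(float(v))


def to_sympy_rational(q: Fraction | int) -> sp.Rational:
    """Embed an exact rational into sympy without a float detour."""
    if isinstance(q, Fraction):
        return sp.Rational(q.numerator, q.denominator)
    return sp.Rational(q)


def _reevaluate(expr: sp.Basic) -> sp.Basic:
    """Rebuild an expression through sympy constructors so rational
    arithmetic (possibly held with evaluate=False) collapses, while
    transcendental heads stay symbolic."""
    if not expr.args:
        return expr
    return expr.func(*[_reevaluate(a) for a in expr.args])


def eval_constant(expr: sp.Basic, env: dict | None = None) -> Fraction | Irrational:
    """Evaluate a constant expression exactly, or flag it irrational.

    ``env`` maps identifier names (str) or symbols to :class:`Fraction`
    values.  Expressions closed under +, -, *, / and integer powers of
    rationals evaluate to an exact :class:`Fraction`.  Transcendental heads
    on non-identity arguments (``exp(1)``, ``pi`` …) yield ``IRRATIONAL``;
    identity cases such as ``exp(0) = 1`` still evaluate exactly because
    they simplify to rationals.  Rational powers ``p**(a/b)`` are rational
    only when ``p`` is an exact perfect ``b``-th power.

    Raises :class:`BindingError` for unbound identifiers and
    :class:`ArithmeticEvalError` for division by zero.
    """
    env = env or {}
    needed = expr.free_symbols
    subs = {}
    for key, val in env.items():
        sym = key if isinstance(key, sp.Symbol) else sp.Symbol(str(key))
        if sym not in needed:
            continue
        if isinstance(val, Irrational):
            # dependency already flagged: anything built on it is flagged too
            return IRRATIONAL
        subs[sym] = to_sympy_rational(val) if isinstance(val, (Fraction, int)) else val
    value = expr.xreplace(subs)
    if value.free_symbols:
        missing = ", ".join(sorted(str(s) for s in value.free_symbols))
        raise BindingError(f"unbound identifier(s) in constant expression: {missing}")
    if value.atoms(sp.Function) and any(
        isinstance(f, sp.core.function.AppliedUndef) for f in value.atoms(sp.Function)
    ):
        raise BindingError("unexpanded function call in constant expression")
    if value.has(sp.Float):
        # stray binary double: embed its exact dyadic value
        value = value.xreplace(
            {f: to_sympy_rational(Fraction(float(f))) for f in value.atoms(sp.Float)}
        )
    value = _reevaluate(value)
    if value.has(sp.zoo, sp.nan):
        raise ArithmeticEvalError(f"undefined exact value: {expr}")
    if value.has(sp.oo, -sp.oo):
        raise ArithmeticEvalError(f"infinite value: {expr}")
    # sympy's constructors auto-evaluate rational closures (including exact
    # perfect powers), so a rational-valued expression is Rational by now.
    if value.is_Rational:
        return Fraction(int(value.p), int(value.q))
    # anything left carries a transcendental head or an unresolved radical:
    # conservatively irrational
    return IRRATIONAL
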