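"""Content-MathML <-> sympy expression bridge.

SBML kinetic laws, rules, initial assignments and function definitions are
content MathML.  Parsing keeps every ``<cn>`` literal exact: the lexical
text is converted through :func:`~odelift.exact_arithmetic.literal_to_rational`,
so ``<cn>0.1</cn>`` enters the system as the rational 1/10, never as a
binary double.

The SBML ``time`` csymbol is mapped to the private :data:`TIME` symbol;
canonical renaming later turns it into the mathematical ``t``.  Using a
reserved internal name avoids capture by a model that happens to declare a
species or parameter called ``t``.

A small writer covers the grammar the fixture generator needs (rational
constants, symbols, +, *, /, integer powers); it is not a general MathML
emitter.
"""

from __future__ import annotations

from fractions import Fraction

import sympy as sp
from lxml import etree

from .exact_arithmetic import literal_to_rational, to_sympy_rational

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_M = "{%s}" % MATHML_NS

#: internal stand-in for the SBML "time" csymbol
TIME = sp.Symbol("__sbml_time__")

#: exact value of the avogadro csymbol fixed by the SBML Level 3 standard
AVOGADRO = sp.Integer(602214179) * sp.Integer(10) ** 15

__all__ = ["MathMLError", "TIME", "AVOGADRO", "parse_mathml", "expr_to_mathml"]


class MathMLError(ValueError):
    """Malformed or unsupported content MathML."""


def _localname(node) -> str:
    return etree.QName(node).localname


def _element_children(node):
    return [c for c in node if isinstance(c.tag, str)]


def _parse_cn(node) -> sp.Expr:
    ctype = node.get("type", "real")
    if ctype in ("real", "integer", "double"):
        text = (node.text or "").strip()
        if text.lower() in ("nan", "notanumber"):
            return sp.nan
        if text.lstrip("+-").upper() == "INF":
            return sp.oo if not text.startswith("-") else -sp.oo
        return to_sympy_rational(literal_to_rational(text))
    seps = [c for c in node if _localname(c) == "sep"]
    if ctype == "e-notation":
        if len(seps) != 1:
            raise MathMLError("e-notation cn needs one <sep/>")
        mantissa = literal_to_rational((node.text or "").strip())
        exponent = int((seps[0].tail or "").strip())
        return to_sympy_rational(mantissa * Fraction(10) ** exponent)
    if ctype == "rational":
        if len(seps) != 1:
            raise MathMLError("rational cn needs one <sep/>")
        num = int((node.text or "").strip())
        den = int((seps[0].tail or "").strip())
        return sp.Rational(num, den)
    raise MathMLError(f"unsupported cn type: {ctype!r}")


def _parse_csymbol(node) -> sp.Expr:
    url = node.get("definitionURL", "")
    if url.endswith("/time"):
        return TIME
    if url.endswith("/avogadro"):
        return AVOGADRO
    if url.endswith("/delay"):
        raise MathMLError("delay csymbol is not supported")
    raise MathMLError(f"unknown csymbol: {url!r}")


_NARY = {
    "plus": lambda *a: sp.Add(*a) if a else sp.Integer(0),
    "times": lambda *a: sp.Mul(*a) if a else sp.Integer(1),
    "and": sp.And,
    "or": sp.Or,
    "xor": sp.Xor,
}

_UNARY = {
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "factorial": sp.factorial,
    "not": sp.Not,
    "sin": sp.sin, "cos": sp.cos, "tan": sp.tan,
    "sec": sp.sec, "csc": sp.csc, "cot": sp.cot,
    "sinh": sp.sinh, "cosh": sp.cosh, "tanh": sp.tanh,
    "arcsin": sp.asin, "arccos": sp.acos, "arctan": sp.atan,
    "arcsinh": sp.asinh, "arccosh": sp.acosh, "arctanh": sp.atanh,
}

_RELATIONAL = {
    "eq": sp.Eq, "neq": sp.Ne,
    "lt": sp.Lt, "leq": sp.Le,
    "gt": sp.Gt, "geq": sp.Ge,
}

_CONSTANTS = {
    "pi": sp.pi,
    "exponentiale": sp.E,
    "infinity": sp.oo,
    "notanumber": sp.nan,
    "true": sp.true,
    "false": sp.false,
}


def _parse_apply(node) -> sp.Expr:
    children = _element_children(node)
    if not children:
        raise MathMLError("empty <apply>")
    head, *rest = children
    name = _localname(head)
    if name == "ci":
        # user-defined function application; inlined later
        fname = (head.text or "").strip()
        return sp.Function(fname)(*[_convert(c) for c in rest])
    if name == "csymbol":
        _parse_csymbol(head)  # raises for delay; time/avogadro are not callable
        raise MathMLError(f"csymbol {head.get('definitionURL')!r} is not callable")
    args = None
    if name == "minus":
        args = [_convert(c) for c in rest]
        if len(args) == 1:
            return -args[0]
        if len(args) == 2:
            return args[0] - args[1]
        raise MathMLError("minus takes 1 or 2 arguments")
    if name == "divide":
        args = [_convert(c) for c in rest]
        if len(args) != 2:
            raise MathMLError("divide takes 2 arguments")
        return args[0] / args[1]
    if name == "power":
        args = [_convert(c) for c in rest]
        if len(args) != 2:
            raise MathMLError("power takes 2 arguments")
        return args[0] ** args[1]
    if name == "root":
        degree = sp.Integer(2)
        operands = []
        for c in rest:
            if _localname(c) == "degree":
                inner = _element_children(c)
                degree = _convert(inner[0]) if inner else sp.Integer(2)
            else:
                operands.append(_convert(c))
        if len(operands) != 1:
            raise MathMLError("root takes one radicand")
        return operands[0] ** (sp.Integer(1) / degree)
    if name == "log":
        base = sp.Integer(10)
        operands = []
        for c in rest:
            if _localname(c) == "logbase":
                inner = _element_children(c)
                base = _convert(inner[0]) if inner else sp.Integer(10)
            else:
                operands.append(_convert(c))
        if len(operands) != 1:
            raise MathMLError("log takes one argument")
        return sp.log(operands[0]) / sp.log(base)
    if name in _NARY:
        return _NARY[name](*[_convert(c) for c in rest])
    if name in _UNARY:
        args = [_convert(c) for c in rest]
        if len(args) != 1:
            raise MathMLError(f"{name} takes 1 argument")
        return _UNARY[name](args[0])
    if name in _RELATIONAL:
        args = [_convert(c) for c in rest]
        if len(args) != 2:
            raise MathMLError(f"{name} takes 2 arguments")
        return _RELATIONAL[name](*args)
    raise MathMLError(f"unsupported MathML operator: {name!r}")


def _parse_piecewise(node) -> sp.Expr:
    pieces = []
    otherwise = None
    for child in _element_children(node):
        name = _localname(child)
        inner = _element_children(child)
        if name == "piece":
            if len(inner) != 2:
                raise MathMLError("piece needs value and condition")
            pieces.append((_convert(inner[0]), _convert(inner[1])))
        elif name == "otherwise":
            if len(inner) != 1:
                raise MathMLError("otherwise needs one value")
            otherwise = _convert(inner[0])
        else:
            raise MathMLError(f"unexpected {name!r} in piecewise")
    if otherwise is not None:
        pieces.append((otherwise, sp.true))
    if not pieces:
        raise MathMLError("empty piecewise")
    return sp.Piecewise(*pieces)


def _convert(node) -> sp.Expr:
    name = _localname(node)
    if name == "apply":
        return _parse_apply(node)
    if name == "ci":
        ident = (node.text or "").strip()
        if not ident:
            raise MathMLError("empty <ci>")
        return sp.Symbol(ident)
    if name == "cn":
        return _parse_cn(node)
    if name == "csymbol":
        return _parse_csymbol(node)
    if name == "piecewise":
        return _parse_piecewise(node)
    if name in _CONSTANTS:
        return _CONSTANTS[name]
    if name == "math":
        children = _element_children(node)
        if len(children) != 1:
            raise MathMLError("<math> must hold exactly one expression")
        return _convert(children[0])
    raise MathMLError(f"unsupported MathML element: {name!r}")


def parse_mathml(node) -> sp.Expr:
    """Convert a content-MathML element (``<math>`` or a child) to sympy.

    All numeric constants come out as exact :class:`sympy.Rational` (or the
    special atoms oo/nan for INF/NaN literals, which gating rejects later).
    User-defined function calls become applied undefined functions.
    """
    if isinstance(node, (str, bytes)):
        node = etree.fromstring(node if isinstance(node, bytes) else node.encode())
    return _convert(node)


def _cn(text: str):
    el = etree.Element(_M + "cn")
    if "." not in text and "e" not in text and "E" not in text:
        el.set("type", "integer")
    el.text = text
    return el


def _ci(name: str):
    el = etree.Element(_M + "ci")
    el.text = name
    return el


def _apply(opname: str, *children):
    el = etree.Element(_M + "apply")
    etree.SubElement(el, _M + opname)
    for c in children:
        el.append(c)
    return el


def _emit(expr: sp.Expr):
    if expr is TIME:
        el = etree.Element(_M + "csymbol")
        el.set("encoding", "text")
        el.set("definitionURL", "http://www.sbml.org/sbml/symbols/time")
        el.text = "t"
        return el
    if isinstance(expr, sp.Symbol):
        return _ci(expr.name)
    if isinstance(expr, sp.Integer):
        return _cn(str(int(expr)))
    if isinstance(expr, sp.Rational):
        return _apply("divide", _cn(str(expr.p)), _cn(str(expr.q)))
    if isinstance(expr, sp.Add):
        return _apply("plus", *[_emit(a) for a in expr.args])
    if isinstance(expr, sp.Mul):
        num, den = expr.as_numer_denom()
        if den != 1:
            return _apply("divide", _emit(num), _emit(den))
        return _apply("times", *[_emit(a) for a in expr.args])
    if isinstance(expr, sp.Pow):
        base, exponent = expr.args
        if exponent == -1:
            return _apply("divide", _cn("1"), _emit(base))
        return _apply("power", _emit(base), _emit(exponent))
    raise MathMLError(f"writer does not cover expression head: {type(expr).__name__}")


def expr_to_mathml(expr: sp.Expr):
    """Render a (rational-constant) sympy expression as a ``<math>`` element."""
    root = etree.Element(_M + "math", nsmap={None: MATHML_NS})
    root.append(_emit(expr))
    return root
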