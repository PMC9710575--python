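"""Dataset serialization into computer-algebra dialects.

A complete per-model dataset (ODE system, matrices, conservation laws,
deficiency, classification, name map) renders into Maple, Reduce, SageMath
and LaTeX text plus a canonical JSON manifest.  Every number is printed as
an exact rational quotient ``p/q`` — a decimal point never appears in a
Maple/Reduce/SageMath export, so exactness survives the round trip into
the target computer-algebra system.  Rendering is deterministic:
byte-identical output for the same dataset.

The SageMath dialect doubles as a machine-readable interchange format:
:func:`parse_sagemath_export` recovers equations, parameter values and
matrices for round-trip verification.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction

import sympy as sp
from sympy.printing.maple import maple_code
from sympy.printing.str import StrPrinter

from .conservation_laws import ConservationLaw
from .crnt_metrics import ClassificationReport, DeficiencyReport
from .ode_assembly import ODESystem

__all__ = [
    "DialectError",
    "ExportParseError",
    "ManifestError",
    "Dataset",
    "ExportDocument",
    "DIALECTS",
    "render",
    "parse_sagemath_export",
    "validate_manifest",
]

TOOL_NAME = "odelift"
TOOL_VERSION = "0.1.0"

DIALECTS = ("maple", "reduce", "sagemath", "latex", "manifest")


class DialectError(ValueError):
    """Unknown export dialect."""


class ExportParseError(ValueError):
    """A SageMath export that cannot be read back."""


class ManifestError(ValueError):
    """A manifest missing required structure."""


@dataclass(frozen=True)
class Dataset:
    """Everything computed for one model, self-contained."""

    ode_system: ODESystem
    stoich: sp.MatrixBase
    kinetic: sp.MatrixBase
    conservation: tuple          # ConservationLaw, parallel to conservation constraints
    deficiency: DeficiencyReport
    classification: ClassificationReport
    source: str = ""
    model_id: str = ""
    timestamp: str | None = None   # None keeps renders reproducible


@dataclass(frozen=True)
class ExportDocument:
    dialect: str
    text: str


class _ReducePrinter(StrPrinter):
    """Infix printer with caret powers for Reduce input."""

    def _print_Pow(self, expr, rational=False):
        base, exponent = expr.args
        if exponent is sp.S.NegativeOne:
            return f"1/{self.parenthesize(base, 75)}"
        return (
            f"{self.parenthesize(base, 75)}^{self.parenthesize(exponent, 75)}"
        )


_reduce_printer = _ReducePrinter()


def _q(value: Fraction) -> str:
    return f"{value.numerator}/{value.denominator}" if value.denominator != 1 else str(
        value.numerator
    )


def _name_map_lines(ds: Dataset, comment: str) -> list[str]:
    nm = ds.ode_system.name_map
    lines = [f"{comment} name map (mathematical name = SBML id):"]
    for sbml_id, math_name in nm.species_map.items():
        lines.append(f"{comment}   {math_name} = {sbml_id}")
    for sbml_id, math_name in nm.parameter_map.items():
        lines.append(f"{comment}   {math_name} = {sbml_id}")
    return lines


def _matrix_rows(matrix: sp.MatrixBase, fmt) -> list[str]:
    return [
        "[" + ", ".join(fmt(matrix[i, j]) for j in range(matrix.cols)) + "]"
        for i in range(matrix.rows)
    ]


def _render_maple(ds: Dataset) -> str:
    ode = ds.ode_system
    lines = [f"# {TOOL_NAME} dataset for model {ds.model_id!r} (Maple)"]
    lines += _name_map_lines(ds, "#")
    lines.append("vars := [%s]:" % ", ".join(str(v) for v in ode.variables))
    for v, f in zip(ode.variables, ode.equations):
        lines.append(f"f_{v} := {maple_code(f)}:")
    lines.append(
        "params := [%s]:"
        % ", ".join(f"{k} = {_q(v)}" for k, v in ode.parameter_values.items())
    )
    lines.append(
        "initials := [%s]:"
        % ", ".join(f"{k} = {_q(v)}" for k, v in ode.initial_values.items())
    )
    lines.append(
        "constraints := [%s]:"
        % ", ".join(
            f"{maple_code(c.left)} = {maple_code(c.right)}" for c in ode.constraints
        )
    )
    lines.append("S := Matrix([%s]):" % ", ".join(_matrix_rows(ds.stoich, maple_code)))
    lines.append(
        "Kin := Matrix([%s]):" % ", ".join(_matrix_rows(ds.kinetic, maple_code))
    )
    lines.append(f"n_complexes := {ds.deficiency.n_complexes}:")
    lines.append(f"n_linkage_classes := {ds.deficiency.n_linkage_classes}:")
    lines.append(f"rank_S := {ds.deficiency.rank}:")
    lines.append(f"deficiency := {ds.deficiency.deficiency}:")
    lines.append(f'vector_field_class := "{ds.classification.vector_field_class}":')
    lines.append(f"mass_action := {str(ds.classification.mass_action).lower()}:")
    return "\n".join(lines) + "\n"


def _render_reduce(ds: Dataset) -> str:
    p = _reduce_printer.doprint
    ode = ds.ode_system
    lines = [f"% {TOOL_NAME} dataset for model {ds.model_id!r} (Reduce)"]
    lines += _name_map_lines(ds, "%")
    lines.append("vars := {%s};" % ", ".join(str(v) for v in ode.variables))
    for v, f in zip(ode.variables, ode.equations):
        lines.append(f"f_{v} := {p(f)};")
    lines.append(
        "params := {%s};"
        % ", ".join(f"{k} = {_q(v)}" for k, v in ode.parameter_values.items())
    )
    lines.append(
        "constraints := {%s};"
        % ", ".join(f"{p(c.left)} = {p(c.right)}" for c in ode.constraints)
    )
    rows = [
        "(" + ", ".join(p(ds.stoich[i, j]) for j in range(ds.stoich.cols)) + ")"
        for i in range(ds.stoich.rows)
    ]
    lines.append("smat := mat(%s);" % ", ".join(rows))
    rows = [
        "(" + ", ".join(p(ds.kinetic[i, j]) for j in range(ds.kinetic.cols)) + ")"
        for i in range(ds.kinetic.rows)
    ]
    lines.append("kmat := mat(%s);" % ", ".join(rows))
    lines.append(f"deficiency := {ds.deficiency.deficiency};")
    return "\n".join(lines) + "\n"


def _render_sagemath(ds: Dataset) -> str:
    s = sp.sstr
    ode = ds.ode_system
    nm = ode.name_map
    all_syms = [str(v) for v in nm.species_symbols()] + [
        str(k) for k in nm.parameter_symbols()
    ] + ["t"]
    lines = [f"# {TOOL_NAME} dataset for model {ds.model_id!r} (SageMath)"]
    lines += _name_map_lines(ds, "#")
    lines.append("var('%s')" % " ".join(all_syms))
    lines.append("variables = [%s]" % ", ".join(str(v) for v in ode.variables))
    for v, f in zip(ode.variables, ode.equations):
        lines.append(f"f_{v} = {s(f)}")
    lines.append(
        "parameters = {%s}"
        % ", ".join(f"{k}: {_q(v)}" for k, v in ode.parameter_values.items())
    )
    lines.append(
        "initials = {%s}"
        % ", ".join(f"{k}: {_q(v)}" for k, v in ode.initial_values.items())
    )
    for idx, c in enumerate(ode.constraints, start=1):
        lines.append(f"constraint_{idx} = ({s(c.left)}) == ({s(c.right)})")
    lines.append(
        "S = matrix(QQ, [%s])" % ", ".join(_matrix_rows(ds.stoich, sp.sstr))
    )
    lines.append(
        "Kin = matrix(QQ, [%s])" % ", ".join(_matrix_rows(ds.kinetic, sp.sstr))
    )
    lines.append(f"deficiency = {ds.deficiency.deficiency}")
    lines.append(f"vector_field_class = {ds.classification.vector_field_class!r}")
    lines.append(f"mass_action = {ds.classification.mass_action}")
    return "\n".join(lines) + "\n"


def _render_latex(ds: Dataset) -> str:
    ode = ds.ode_system
    lines = [f"% {TOOL_NAME} dataset for model {ds.model_id!r} (LaTeX)"]
    lines += _name_map_lines(ds, "%")
    lines.append(r"\begin{align*}")
    for v, f in zip(ode.variables, ode.equations):
        lines.append(rf"\dot{{{sp.latex(v)}}} &= {sp.latex(f)}\\")
    lines.append(r"\end{align*}")
    if ode.constraints:
        lines.append(r"\begin{align*}")
        for c in ode.constraints:
            lines.append(rf"{sp.latex(c.left)} &= {sp.latex(c.right)}\\")
        lines.append(r"\end{align*}")
    if ode.parameter_values:
        lines.append(r"\begin{align*}")
        for k, v in ode.parameter_values.items():
            lines.append(
                rf"{sp.latex(k)} &= {sp.latex(sp.Rational(v.numerator, v.denominator))}\\"
            )
        lines.append(r"\end{align*}")
    lines.append(r"\[ S = " + sp.latex(sp.Matrix(ds.stoich)) + r" \]")
    lines.append(r"\[ \delta = %d \]" % ds.deficiency.deficiency)
    return "\n".join(lines) + "\n"


def _manifest_dict(ds: Dataset) -> dict:
    ode = ds.ode_system
    nm = ode.name_map
    return {
        "tool": TOOL_NAME,
        "tool_version": TOOL_VERSION,
        "source": ds.source,
        "model_id": ds.model_id,
        "generated": ds.timestamp,
        "name_map": {
            "species": dict(nm.species_map),
            "parameters": dict(nm.parameter_map),
        },
        "variables": [str(v) for v in ode.variables],
        "equations": {str(v): sp.sstr(f) for v, f in zip(ode.variables, ode.equations)},
        "autonomous": ode.is_autonomous,
        "parameter_values": {str(k): _q(v) for k, v in ode.parameter_values.items()},
        "initial_values": {str(k): _q(v) for k, v in ode.initial_values.items()},
        "constraints": [
            {"kind": c.kind, "left": sp.sstr(c.left), "right": sp.sstr(c.right), "origin": c.origin}
            for c in ode.constraints
        ],
        "conservation_laws": [
            {
                "coefficients": list(law.coefficients),
                "species_indices": list(law.species_indices),
                "total": _q(law.total) if isinstance(law.total, Fraction) else sp.sstr(law.total)
                if law.total is not None
                else None,
            }
            for law in ds.conservation
        ],
        "stoichiometric_matrix": [
            [sp.sstr(ds.stoich[i, j]) for j in range(ds.stoich.cols)]
            for i in range(ds.stoich.rows)
        ],
        "kinetic_matrix": [
            [sp.sstr(ds.kinetic[i, j]) for j in range(ds.kinetic.cols)]
            for i in range(ds.kinetic.rows)
        ],
        "deficiency": {
            "complexes": ds.deficiency.n_complexes,
            "linkage_classes": ds.deficiency.n_linkage_classes,
            "rank": ds.deficiency.rank,
            "deficiency": ds.deficiency.deficiency,
        },
        "classification": {
            "vector_field": ds.classification.vector_field_class,
            "constraints": ds.classification.constraints_class,
            "mass_action": ds.classification.mass_action,
            "reaction_mass_action": list(ds.classification.reaction_mass_action),
        },
    }


_MANIFEST_REQUIRED = {
    "tool": str,
    "tool_version": str,
    "source": str,
    "model_id": str,
    "name_map": dict,
    "variables": list,
    "equations": dict,
    "autonomous": bool,
    "parameter_values": dict,
    "initial_values": dict,
    "constraints": list,
    "conservation_laws": list,
    "stoichiometric_matrix": list,
    "kinetic_matrix": list,
    "deficiency": dict,
    "classification": dict,
}


def validate_manifest(manifest: dict) -> None:
    """Structural validation of a manifest dictionary (raises on defects)."""
    for key, typ in _MANIFEST_REQUIRED.items():
        if key not in manifest:
            raise ManifestError(f"manifest missing key {key!r}")
        if not isinstance(manifest[key], typ):
            raise ManifestError(f"manifest key {key!r} has wrong type")
    for sub in ("species", "parameters"):
        if sub not in manifest["name_map"]:
            raise ManifestError(f"name_map missing {sub!r}")
    for sub in ("complexes", "linkage_classes", "rank", "deficiency"):
        if sub not in manifest["deficiency"]:
            raise ManifestError(f"deficiency missing {sub!r}")
    d = manifest["deficiency"]
    if d["deficiency"] != d["complexes"] - d["linkage_classes"] - d["rank"]:
        raise ManifestError("deficiency fields are mutually inconsistent")
    if set(manifest["equations"]) != set(manifest["variables"]):
        raise ManifestError("equations do not cover exactly the variables")


def render(ds: Dataset, dialect: str) -> ExportDocument:
    """Render the dataset in the requested dialect (deterministic)."""
    if dialect == "maple":
        text = _render_maple(ds)
    elif dialect == "reduce":
        text = _render_reduce(ds)
    elif dialect == "sagemath":
        text = _render_sagemath(ds)
    elif dialect == "latex":
        text = _render_latex(ds)
    elif dialect == "manifest":
        manifest = _manifest_dict(ds)
        validate_manifest(manifest)
        text = json.dumps(manifest, indent=2, sort_keys=False) + "\n"
    else:
        raise DialectError(f"unknown dialect {dialect!r}")
    return ExportDocument(dialect=dialect, text=text)


_SAGE_LINE = re.compile(r"^(?P<name>[A-Za-z_][A-Za-z0-9_]*) = (?P<value>.+)$")


def parse_sagemath_export(text: str) -> dict:
    """Read back a SageMath export for round-trip verification.

    Returns a dict with ``variables`` (list of symbols), ``equations``
    (symbol → expression), ``parameter_values``, ``stoich``, ``kinetic``
    and ``deficiency``.  Raises :class:`ExportParseError` when the text is
    empty, malformed, or an equation for a declared variable is missing.
    """
    if not text.strip():
        raise ExportParseError("empty export")
    variables = None
    equations = {}
    parameter_values = {}
    stoich = None
    kinetic = None
    defic = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("var("):
            continue
        match = _SAGE_LINE.match(line)
        if match is None:
            if line.startswith("constraint_"):
                continue
            raise ExportParseError(f"unparseable line: {line!r}")
        name, value = match.group("name"), match.group("value")
        try:
            if name == "variables":
                variables = [sp.Symbol(v.strip()) for v in value.strip("[]").split(",") if v.strip()]
            elif name.startswith("f_"):
                equations[sp.Symbol(name[2:])] = sp.sympify(value, rational=True)
            elif name == "parameters":
                inner = value.strip("{}").strip()
                if inner:
                    for pair in inner.split(","):
                        k, _, v = pair.partition(":")
                        parameter_values[sp.Symbol(k.strip())] = sp.sympify(v.strip(), rational=True)
            elif name in ("S", "Kin"):
                body = re.match(r"matrix\(QQ, (\[.*\])\)$", value)
                if body is None:
                    raise ExportParseError(f"malformed matrix line: {line!r}")
                rows = sp.sympify(body.group(1), rational=True)
                matrix = sp.Matrix(rows)
                if name == "S":
                    stoich = matrix
                else:
                    kinetic = matrix
            elif name == "deficiency":
                defic = int(value)
        except (sp.SympifyError, ValueError, TypeError) as exc:
            raise ExportParseError(f"cannot parse line {line!r}: {exc}") from exc
    if variables is None or stoich is None:
        raise ExportParseError("export lacks variables or stoichiometric matrix")
    missing = [v for v in variables if v not in equations]
    if missing:
        raise ExportParseError(f"missing equations for: {missing}")
    return {
        "variables": variables,
        "equations": equations,
        "parameter_values": parameter_values,
        "stoich": stoich,
        "kinetic": kinetic,
        "deficiency": defic,
    }
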