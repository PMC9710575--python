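"""SBML (Level 2/3) ingestion and feature gating.

Reads an SBML document into a :class:`RawModel` — a faithful, unprocessed
image of the file: species, reactions, parameters, compartments, rules,
initial assignments and function definitions, with every numeric attribute
kept as its *lexical* string so downstream conversion can build exact
rationals from the decimal text rather than from binary doubles.

A model is only allowed into the symbolic pipeline if it uses exclusively
the recognized feature set: species with boundary condition, local
parameters, parameter and species assignment rules, parameter and species
initial assignments, species rate rules, and function definitions.
Documents with events, parameter (or compartment) rate rules, algebraic
rules, non-constant compartments, or irrational constant values are
rejected by :func:`check_supported` with an itemized violation list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from graphlib import CycleError as _GraphCycleError, TopologicalSorter

import sympy as sp
from lxml import etree

from .exact_arithmetic import (
    IRRATIONAL,
    ArithmeticEvalError,
    BindingError,
    InvalidLiteralError,
    Irrational,
    eval_constant,
    literal_to_rational,
    to_sympy_rational,
)
from .mathml import MathMLError, parse_mathml

__all__ = [
    "SBMLError",
    "SBMLParseError",
    "SBMLFormatError",
    "UnsupportedLevelError",
    "DefinitionCycleError",
    "ArityMismatchError",
    "RawSpecies",
    "RawParameter",
    "RawCompartment",
    "RawReaction",
    "RawModel",
    "SupportReport",
    "parse_sbml",
    "check_supported",
    "inline_function_definitions",
    "inline_all",
    "lift_local_parameters",
    "constant_environment",
]


class SBMLError(Exception):
    """Base class for ingestion errors."""


class SBMLParseError(SBMLError):
    """Malformed XML or inconsistent SBML content."""


class SBMLFormatError(SBMLError):
    """Well-formed XML whose root is not an SBML document."""


class UnsupportedLevelError(SBMLError):
    """SBML Level 1 (or another unhandled level)."""


class DefinitionCycleError(SBMLError):
    """Recursive or mutually recursive function definitions / assignments."""


class ArityMismatchError(SBMLError):
    """A function call whose argument count differs from the definition."""


@dataclass(frozen=True)
class RawSpecies:
    id: str
    compartment: str | None
    boundary_condition: bool = False
    constant: bool = False
    initial_amount: str | None = None
    initial_concentration: str | None = None
    has_only_substance_units: bool = False
    document_order: int = 0


@dataclass(frozen=True)
class RawParameter:
    id: str
    value: str | None = None          # lexical numeric string
    constant: bool = True
    origin: tuple | None = None       # ("local", reaction_id, original_id) once lifted
    document_order: int = 0


@dataclass(frozen=True)
class RawCompartment:
    id: str
    size: str | None = None           # lexical; None means unspecified (treated as 1)
    constant: bool = True
    document_order: int = 0


@dataclass(frozen=True)
class RawReaction:
    id: str
    reactants: tuple = ()             # ((species id, stoichiometry lexical), ...)
    products: tuple = ()
    modifiers: tuple = ()
    reversible: bool = True
    kinetic_law: sp.Expr | None = None
    local_parameters: tuple = ()      # RawParameter with origin None until lifted
    stoichiometry_math: bool = False
    document_order: int = 0


@dataclass(frozen=True)
class RawModel:
    level: int
    version: int
    model_id: str
    species: tuple = ()
    reactions: tuple = ()
    global_parameters: tuple = ()
    compartments: tuple = ()
    function_definitions: dict = field(default_factory=dict)   # id -> (args, body)
    assignment_rules: dict = field(default_factory=dict)       # target -> expr
    initial_assignments: dict = field(default_factory=dict)
    rate_rules: dict = field(default_factory=dict)
    algebraic_rules_present: bool = False
    events_present: bool = False
    constraints_present: bool = False
    math_errors: tuple = ()           # ((context, message), ...)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def entity_ids(self) -> set[str]:
        ids = {s.id for s in self.species}
        ids |= {p.id for p in self.global_parameters}
        ids |= {c.id for c in self.compartments}
        return ids


@dataclass(frozen=True)
class SupportReport:
    supported: bool
    violations: tuple = ()            # ((feature, entity id, message), ...)


def _localname(node) -> str:
    try:
        return etree.QName(node).localname
    except ValueError:
        return ""


def _children(node, name):
    return [c for c in node if isinstance(c.tag, str) and _localname(c) == name]


def _first(node, name):
    found = _children(node, name)
    return found[0] if found else None


def _bool(value: str | None, default: bool) -> bool:
    if value is None:
        return default
    return value.strip().lower() in ("true", "1")


def _math_expr(parent, context: str, errors: list) -> sp.Expr | None:
    math = _first(parent, "math")
    if math is None:
        return None
    try:
        return parse_mathml(math)
    except (MathMLError, InvalidLiteralError) as exc:
        errors.append((context, str(exc)))
        return None


def parse_sbml(document: str | bytes) -> RawModel:
    """Parse an SBML Level 2/3 document into a :class:`RawModel`.

    Raises :class:`SBMLParseError` on malformed XML or duplicate/unresolved
    ids, :class:`SBMLFormatError` if the root element is not ``<sbml>`` and
    :class:`UnsupportedLevelError` for SBML Level 1.
    """
    data = document.encode() if isinstance(document, str) else document
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"malformed XML: {exc}") from exc
    if _localname(root) != "sbml":
        raise SBMLFormatError(f"root element is {_localname(root)!r}, not 'sbml'")
    try:
        level = int(root.get("level", "0"))
        version = int(root.get("version", "0"))
    except ValueError as exc:
        raise SBMLFormatError("non-integer SBML level/version") from exc
    if level < 2:
        raise UnsupportedLevelError(f"SBML Level {level} is not supported (need 2 or 3)")
    if level > 3:
        raise UnsupportedLevelError(f"unknown SBML Level {level}")
    model_el = _first(root, "model")
    if model_el is None:
        raise SBMLParseError("document has no <model>")

    order = 0
    math_errors: list = []

    compartments = []
    lo = _first(model_el, "listOfCompartments")
    for el in _children(lo, "compartment") if lo is not None else []:
        compartments.append(
            RawCompartment(
                id=el.get("id"),
                size=el.get("size", el.get("volume")),
                constant=_bool(el.get("constant"), True),
                document_order=order,
            )
        )
        order += 1

    species = []
    lo = _first(model_el, "listOfSpecies")
    for el in _children(lo, "species") if lo is not None else []:
        species.append(
            RawSpecies(
                id=el.get("id"),
                compartment=el.get("compartment"),
                boundary_condition=_bool(el.get("boundaryCondition"), False),
                constant=_bool(el.get("constant"), False),
                initial_amount=el.get("initialAmount"),
                initial_concentration=el.get("initialConcentration"),
                has_only_substance_units=_bool(el.get("hasOnlySubstanceUnits"), False),
                document_order=order,
            )
        )
        order += 1

    parameters = []
    lo = _first(model_el, "listOfParameters")
    for el in _children(lo, "parameter") if lo is not None else []:
        parameters.append(
            RawParameter(
                id=el.get("id"),
                value=el.get("value"),
                constant=_bool(el.get("constant"), True),
                document_order=order,
            )
        )
        order += 1

    function_definitions = {}
    lo = _first(model_el, "listOfFunctionDefinitions")
    for el in _children(lo, "functionDefinition") if lo is not None else []:
        fid = el.get("id")
        math = _first(el, "math")
        lam = _first(math, "lambda") if math is not None else None
        if lam is None:
            raise SBMLParseError(f"function definition {fid!r} has no lambda")
        args = []
        body = None
        for child in lam:
            if not isinstance(child.tag, str):
                continue
            if _localname(child) == "bvar":
                ci = _first(child, "ci")
                if ci is None or not (ci.text or "").strip():
                    raise SBMLParseError(f"function {fid!r}: malformed bvar")
                args.append(ci.text.strip())
            else:
                try:
                    body = parse_mathml(child)
                except (MathMLError, InvalidLiteralError) as exc:
                    math_errors.append((f"functionDefinition {fid}", str(exc)))
        if body is None and not any(
            ctx.endswith(fid) for ctx, _ in math_errors
        ):
            raise SBMLParseError(f"function definition {fid!r} has no body")
        function_definitions[fid] = (tuple(args), body)

    assignment_rules: dict = {}
    rate_rules: dict = {}
    initial_assignments: dict = {}
    algebraic = False
    lo = _first(model_el, "listOfRules")
    for el in _children(lo, "assignmentRule") if lo is not None else []:
        target = el.get("variable")
        assignment_rules[target] = _math_expr(el, f"assignmentRule {target}", math_errors)
    for el in _children(lo, "rateRule") if lo is not None else []:
        target = el.get("variable")
        rate_rules[target] = _math_expr(el, f"rateRule {target}", math_errors)
    if lo is not None and _children(lo, "algebraicRule"):
        algebraic = True

    lo = _first(model_el, "listOfInitialAssignments")
    for el in _children(lo, "initialAssignment") if lo is not None else []:
        target = el.get("symbol")
        initial_assignments[target] = _math_expr(
            el, f"initialAssignment {target}", math_errors
        )

    reactions = []
    lo = _first(model_el, "listOfReactions")
    for el in _children(lo, "reaction") if lo is not None else []:
        rid = el.get("id")

        def refs(list_name):
            out = []
            stoich_math = False
            container = _first(el, list_name)
            for ref in _children(container, "speciesReference") if container is not None else []:
                if _first(ref, "stoichiometryMath") is not None:
                    stoich_math = True
                out.append((ref.get("species"), ref.get("stoichiometry", "1")))
            return tuple(out), stoich_math

        reactants, sm_r = refs("listOfReactants")
        products, sm_p = refs("listOfProducts")
        modifiers = tuple(
            ref.get("species")
            for container in ([_first(el, "listOfModifiers")] if _first(el, "listOfModifiers") is not None else [])
            for ref in _children(container, "modifierSpeciesReference")
        )
        kl = _first(el, "kineticLaw")
        law = None
        locals_: list = []
        if kl is not None:
            law = _math_expr(kl, f"kineticLaw {rid}", math_errors)
            for list_name in ("listOfParameters", "listOfLocalParameters"):
                lop = _first(kl, list_name)
                tag = "parameter" if list_name == "listOfParameters" else "localParameter"
                for p in _children(lop, tag) if lop is not None else []:
                    locals_.append(
                        RawParameter(
                            id=p.get("id"),
                            value=p.get("value"),
                            constant=True,
                            document_order=order,
                        )
                    )
                    order += 1
        reversible_default = True if level == 2 else False
        reactions.append(
            RawReaction(
                id=rid,
                reactants=reactants,
                products=products,
                modifiers=modifiers,
                reversible=_bool(el.get("reversible"), reversible_default),
                kinetic_law=law,
                local_parameters=tuple(locals_),
                stoichiometry_math=sm_r or sm_p,
                document_order=order,
            )
        )
        order += 1

    events = _first(model_el, "listOfEvents")
    events_present = events is not None and bool(_children(events, "event"))
    constraints = _first(model_el, "listOfConstraints")
    constraints_present = constraints is not None and bool(
        _children(constraints, "constraint")
    )

    model = RawModel(
        level=level,
        version=version,
        model_id=model_el.get("id") or "model",
        species=tuple(species),
        reactions=tuple(reactions),
        global_parameters=tuple(parameters),
        compartments=tuple(compartments),
        function_definitions=function_definitions,
        assignment_rules=assignment_rules,
        initial_assignments=initial_assignments,
        rate_rules=rate_rules,
        algebraic_rules_present=algebraic,
        events_present=events_present,
        constraints_present=constraints_present,
        math_errors=tuple(math_errors),
    )
    _validate_references(model)
    return model


def _validate_references(model: RawModel) -> None:
    ids = []
    for s in model.species:
        ids.append(s.id)
    for p in model.global_parameters:
        ids.append(p.id)
    for c in model.compartments:
        ids.append(c.id)
    seen = set()
    for i in ids:
        if i is None:
            raise SBMLParseError("entity without an id")
        if i in seen:
            raise SBMLParseError(f"duplicate id {i!r}")
        seen.add(i)
    species_ids = {s.id for s in model.species}
    for r in model.reactions:
        for sid, _ in r.reactants + r.products:
            if sid not in species_ids:
                raise SBMLParseError(
                    f"reaction {r.id!r} references unknown species {sid!r}"
                )
    targets = (
        set(model.assignment_rules)
        | set(model.rate_rules)
        | set(model.initial_assignments)
    )
    unknown = targets - model.entity_ids()
    if unknown:
        raise SBMLParseError(f"rule/assignment targets unknown ids: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# function-definition inlining


def _check_definition_cycles(defs: dict) -> None:
    graph = {}
    for name, (_args, body) in defs.items():
        callees = set()
        if body is not None:
            for f in body.atoms(sp.Function):
                if isinstance(f, sp.core.function.AppliedUndef) and f.func.__name__ in defs:
                    callees.add(f.func.__name__)
        graph[name] = callees
    try:
        tuple(TopologicalSorter(graph).static_order())
    except _GraphCycleError as exc:
        raise DefinitionCycleError(f"recursive function definitions: {exc}") from exc


def inline_function_definitions(expr: sp.Expr, defs: dict) -> sp.Expr:
    """Expand every user-defined function call in ``expr``.

    ``defs`` maps a function id to ``(formal argument names, body)``.
    Substitution of the actual arguments for the formals is simultaneous
    (capture-avoiding), and nested calls are fully expanded.  Raises
    :class:`DefinitionCycleError` for (mutually) recursive definitions and
    :class:`ArityMismatchError` when call and definition disagree.
    """
    _check_definition_cycles(defs)

    def expand(e: sp.Basic) -> sp.Basic:
        if isinstance(e, sp.core.function.AppliedUndef) and e.func.__name__ in defs:
            params, body = defs[e.func.__name__]
            if body is None:
                raise SBMLParseError(
                    f"function {e.func.__name__!r} has no parseable body"
                )
            if len(e.args) != len(params):
                raise ArityMismatchError(
                    f"{e.func.__name__} called with {len(e.args)} argument(s), "
                    f"defined with {len(params)}"
                )
            actuals = [expand(a) for a in e.args]
            body = expand(body)
            return body.xreplace(
                {sp.Symbol(p): a for p, a in zip(params, actuals)}
            )
        if not e.args:
            return e
        new_args = [expand(a) for a in e.args]
        if all(n is o for n, o in zip(new_args, e.args)):
            return e
        return e.func(*new_args)

    return expand(expr)


def _map_math(model: RawModel, fn) -> RawModel:
    reactions = tuple(
        replace(r, kinetic_law=fn(r.kinetic_law) if r.kinetic_law is not None else None)
        for r in model.reactions
    )

    def map_dict(d):
        return {k: (fn(v) if v is not None else None) for k, v in d.items()}

    return replace(
        model,
        reactions=reactions,
        assignment_rules=map_dict(model.assignment_rules),
        initial_assignments=map_dict(model.initial_assignments),
        rate_rules=map_dict(model.rate_rules),
    )


def inline_all(model: RawModel) -> RawModel:
    """Inline function definitions into every expression of the model."""
    defs = model.function_definitions
    if not defs:
        return model
    return _map_math(model, lambda e: inline_function_definitions(e, defs))


def lift_local_parameters(model: RawModel) -> RawModel:
    """Promote reaction-local parameters to uniquely named globals.

    SBML scoping makes a local parameter shadow a global of the same id
    inside its reaction's kinetic law.  Each local becomes a global named
    ``<reaction id>_<local id>`` (suffixed until unique); the law is
    rewritten to the lifted id and the origin is recorded.  Applying the
    operation twice equals applying it once.
    """
    if not any(r.local_parameters for r in model.reactions):
        return model
    taken = set(model.entity_ids())
    new_globals = list(model.global_parameters)
    new_reactions = []
    for r in model.reactions:
        law = r.kinetic_law
        for local in r.local_parameters:
            fresh = f"{r.id}_{local.id}"
            while fresh in taken:
                fresh += "_l"
            taken.add(fresh)
            new_globals.append(
                RawParameter(
                    id=fresh,
                    value=local.value,
                    constant=True,
                    origin=("local", r.id, local.id),
                    document_order=local.document_order,
                )
            )
            if law is not None:
                law = law.xreplace({sp.Symbol(local.id): sp.Symbol(fresh)})
        new_reactions.append(replace(r, kinetic_law=law, local_parameters=()))
    return replace(
        model, reactions=tuple(new_reactions), global_parameters=tuple(new_globals)
    )


# ---------------------------------------------------------------------------
# constant-value resolution (shared by gating and by ODE assembly)


def constant_environment(model: RawModel):
    """Resolve every entity's constant value in dependency order.

    Returns ``(env, problems)``.  ``env`` maps entity id to a
    :class:`fractions.Fraction`, to :data:`IRRATIONAL`, or to ``None`` when
    the value is not a constant (it references species, time, or an entity
    without a value).  ``problems`` lists ``(entity id, kind)`` pairs with
    kind ``"irrational"``, ``"non-finite"`` or ``"cycle"``.

    Value precedence per SBML semantics: initial assignment, then
    (constant) assignment rule, then the declared attribute value.
    """
    exprs: dict[str, sp.Expr | None] = {}
    problems: list = []

    def literal(target: str, text: str | None):
        if text is None:
            return None
        try:
            return to_sympy_rational(literal_to_rational(text))
        except InvalidLiteralError:
            problems.append((target, "non-finite"))
            return None

    def first_not_none(*candidates):
        for cand in candidates:
            if cand is not None:
                return cand
        return None

    for p in model.global_parameters:
        exprs[p.id] = first_not_none(
            model.initial_assignments.get(p.id),
            model.assignment_rules.get(p.id),
            literal(p.id, p.value),
        )
    for c in model.compartments:
        exprs[c.id] = first_not_none(
            model.initial_assignments.get(c.id),
            model.assignment_rules.get(c.id),
            literal(c.id, c.size),
            sp.Integer(1),
        )
    for s in model.species:
        expr = first_not_none(
            model.initial_assignments.get(s.id), model.assignment_rules.get(s.id)
        )
        if expr is None:
            if s.initial_concentration is not None:
                expr = literal(s.id, s.initial_concentration)
            elif s.initial_amount is not None:
                amount = literal(s.id, s.initial_amount)
                if amount is not None and not s.has_only_substance_units and s.compartment:
                    expr = amount / sp.Symbol(s.compartment)
                else:
                    expr = amount
        exprs[s.id] = expr

    graph = {}
    for target, expr in exprs.items():
        deps = set()
        if expr is not None and isinstance(expr, sp.Basic):
            deps = {str(s) for s in expr.free_symbols if str(s) in exprs}
        graph[target] = deps
    try:
        ordered = list(TopologicalSorter(graph).static_order())
    except _GraphCycleError as exc:
        cyclic = sorted(set(exprs) - set())
        problems.append((";".join(cyclic), "cycle"))
        raise DefinitionCycleError(f"cyclic value dependencies: {exc}") from exc

    env: dict = {}
    for target in ordered:
        expr = exprs.get(target)
        if expr is None:
            env[target] = None
            continue
        known = {
            name: val
            for name, val in env.items()
            if isinstance(val, (Fraction, Irrational))
        }
        try:
            env[target] = eval_constant(expr, known)
        except BindingError:
            env[target] = None  # depends on time or a value-less entity
        except ArithmeticEvalError:
            env[target] = None
            problems.append((target, "non-finite"))
    for target, val in env.items():
        if isinstance(val, Irrational):
            problems.append((target, "irrational"))
    return env, problems


def check_supported(model: RawModel) -> SupportReport:
    """Report every unsupported-feature occurrence in the model.

    The model is supported exactly when the violation list is empty.
    Checked: events, parameter rate rules, algebraic rules, non-constant
    compartments, SBML constraint elements, stoichiometry math, missing or
    unparseable kinetic laws, and constant values that are non-finite or
    provably irrational.
    """
    violations: list = []
    if model.events_present:
        violations.append(("events", model.model_id, "model contains SBML events"))
    if model.algebraic_rules_present:
        violations.append(
            ("algebraic rule", model.model_id, "algebraic rules are not supported")
        )
    if model.constraints_present:
        violations.append(
            ("constraint element", model.model_id, "SBML constraints are not supported")
        )
    param_ids = {p.id for p in model.global_parameters}
    comp_ids = {c.id for c in model.compartments}
    for target in model.rate_rules:
        if target in param_ids:
            violations.append(
                ("parameter rate rule", target, f"rate rule targets parameter {target!r}")
            )
        elif target in comp_ids:
            violations.append(
                ("non-constant compartment", target, f"rate rule targets compartment {target!r}")
            )
    for c in model.compartments:
        if not c.constant or c.id in model.assignment_rules:
            violations.append(
                ("non-constant compartment", c.id, f"compartment {c.id!r} is not constant")
            )
    for r in model.reactions:
        if r.stoichiometry_math:
            violations.append(
                ("stoichiometry math", r.id, "stoichiometryMath is not supported")
            )
        if r.kinetic_law is None:
            violations.append(
                ("missing kinetic law", r.id, f"reaction {r.id!r} has no kinetic law")
            )
        else:
            for sid, stoich in r.reactants + r.products:
                try:
                    value = literal_to_rational(stoich)
                    if value <= 0:
                        violations.append(
                            ("invalid stoichiometry", r.id, f"non-positive stoichiometry for {sid!r}")
                        )
                except InvalidLiteralError:
                    violations.append(
                        ("invalid stoichiometry", r.id, f"unparseable stoichiometry for {sid!r}")
                    )
    for context, message in model.math_errors:
        violations.append(("unsupported math", context, message))
    try:
        _env, problems = constant_environment(model)
    except DefinitionCycleError as exc:
        problems = []
        violations.append(("cyclic values", model.model_id, str(exc)))
    for target, kind in problems:
        if kind == "irrational":
            violations.append(
                ("irrational parameter value", target, f"{target!r} has an irrational constant value")
            )
        elif kind == "non-finite":
            violations.append(
                ("non-finite value", target, f"{target!r} has a NaN/infinite or undefined value")
            )
    return SupportReport(supported=not violations, violations=tuple(violations))
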