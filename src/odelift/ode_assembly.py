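"""Assembly of the explicit first-order ODE system.

Species concentrations become x1 … xn (document order); parameters and
compartment sizes become k1 … km (globals in document order, then
compartments, then lifted locals in reaction order).  For a dynamic
species the right-hand side is the stoichiometry-weighted sum of kinetic
laws, divided by the species' (constant, rational) compartment size so the
equation governs a concentration; boundary species get f = 0, rate-rule
species get the rule's expression, and assignment-rule species are
eliminated by substitution and survive as formal constraints.

All constants on every right-hand side are exact rationals; a model whose
laws mention the SBML time csymbol yields a non-autonomous system with the
reserved symbol ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from graphlib import CycleError as _GraphCycleError, TopologicalSorter

import sympy as sp

from .exact_arithmetic import to_sympy_rational
from .mathml import TIME
from .network_model import ReactionNetwork, stoichiometric_matrix
from .sbml_ingest import DefinitionCycleError, RawModel, constant_environment

__all__ = [
    "AssemblyError",
    "TIME_SYMBOL",
    "NameMap",
    "Constraint",
    "ODESystem",
    "build_name_map",
    "resolve_values",
    "species_assignment_constraints",
    "assemble_odes",
]

#: canonical time symbol of the assembled system
TIME_SYMBOL = sp.Symbol("t")


class AssemblyError(ValueError):
    """Inconsistent input to ODE assembly."""


class NameMap:
    """Bijection between SBML ids and canonical mathematical names.

    Species map to ``x1 … xn``, parameters and compartments to ``k1 … km``;
    both directions are exposed and indices are contiguous from 1.
    """

    def __init__(self, species_pairs, parameter_pairs):
        self.species_map = dict(species_pairs)          # sbml id -> "xi"
        self.parameter_map = dict(parameter_pairs)      # sbml id -> "kj"
        self._inverse = {v: k for k, v in self.species_map.items()}
        inv_params = {v: k for k, v in self.parameter_map.items()}
        if len(self._inverse) != len(self.species_map) or len(inv_params) != len(
            self.parameter_map
        ):
            raise AssemblyError("name map is not bijective")
        self._inverse.update(inv_params)

    def to_math(self, sbml_id: str) -> str:
        if sbml_id in self.species_map:
            return self.species_map[sbml_id]
        return self.parameter_map[sbml_id]

    def to_sbml(self, math_name: str) -> str:
        return self._inverse[math_name]

    def species_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(self.species_map[s]) for s in self.species_map]

    def parameter_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(self.parameter_map[p]) for p in self.parameter_map]

    def substitution(self) -> dict:
        subs = {sp.Symbol(k): sp.Symbol(v) for k, v in self.species_map.items()}
        subs.update({sp.Symbol(k): sp.Symbol(v) for k, v in self.parameter_map.items()})
        subs[TIME] = TIME_SYMBOL
        return subs

    def rename(self, expr: sp.Expr) -> sp.Expr:
        return expr.xreplace(self.substitution())


@dataclass(frozen=True)
class Constraint:
    kind: str                 # "species-assignment" | "parameter-assignment" | "conservation"
    left: sp.Expr
    right: sp.Expr
    origin: str = ""

    def as_equation(self) -> sp.Eq:
        return sp.Eq(self.left, self.right, evaluate=False)


@dataclass
class ODESystem:
    variables: list            # sympy symbols xi, species with an ODE
    equations: list            # f_i aligned with variables
    constraints: list = field(default_factory=list)
    name_map: NameMap | None = None
    parameter_values: dict = field(default_factory=dict)   # Symbol(kj) -> Fraction
    initial_values: dict = field(default_factory=dict)     # Symbol(xi) -> Fraction

    @property
    def is_autonomous(self) -> bool:
        return all(TIME_SYMBOL not in f.free_symbols for f in self.equations)

    def rhs(self, variable) -> sp.Expr:
        return self.equations[self.variables.index(variable)]


def build_name_map(net: ReactionNetwork) -> NameMap:
    """Number species and parameters into the canonical x/k namespace."""
    species_pairs = [(s.id, f"x{i + 1}") for i, s in enumerate(net.species)]
    parameter_pairs = [(p.id, f"k{j + 1}") for j, p in enumerate(net.parameters)]
    return NameMap(species_pairs, parameter_pairs)


def resolve_values(model: RawModel, nm: NameMap):
    """Resolve parameter and species initial values to exact rationals.

    Follows SBML precedence (initial assignment over assignment rule over
    declared attribute), evaluated in dependency order.  Entities whose
    value is not a constant are simply absent from the result maps.
    Returns ``(parameter_values, initial_values)`` keyed by canonical
    symbols.
    """
    try:
        env, _problems = constant_environment(model)
    except DefinitionCycleError as exc:
        raise AssemblyError(str(exc)) from exc
    parameter_values = {}
    initial_values = {}
    for sbml_id, value in env.items():
        if not isinstance(value, Fraction):
            continue
        if sbml_id in nm.species_map:
            initial_values[sp.Symbol(nm.species_map[sbml_id])] = value
        elif sbml_id in nm.parameter_map:
            parameter_values[sp.Symbol(nm.parameter_map[sbml_id])] = value
    return parameter_values, initial_values


def _assignment_substitution(model: RawModel, env: dict) -> dict:
    """Closed-form substitution map for assignment-rule targets.

    Species assignment rules are always substituted (they eliminate the
    species from the state).  Parameter/compartment assignment rules are
    substituted only when their value is *not* a constant — constant ones
    are handled through ``parameter_values`` and keep their symbol.
    Nested targets are expanded in dependency order; cycles are an error.
    """
    species_ids = {s.id for s in model.species}
    targets = {}
    for target, expr in model.assignment_rules.items():
        if expr is None:
            raise AssemblyError(f"assignment rule for {target!r} has no expression")
        if target in species_ids or not isinstance(env.get(target), Fraction):
            targets[target] = expr
    graph = {
        t: {str(s) for s in e.free_symbols if str(s) in targets}
        for t, e in targets.items()
    }
    try:
        order = list(TopologicalSorter(graph).static_order())
    except _GraphCycleError as exc:
        raise AssemblyError(f"cyclic assignment-rule dependencies: {exc}") from exc
    closed: dict = {}
    for target in order:
        expr = targets[target].xreplace(
            {sp.Symbol(t): e for t, e in closed.items()}
        )
        closed[target] = expr
    return {sp.Symbol(t): e for t, e in closed.items()}


def species_assignment_constraints(model: RawModel, nm: NameMap) -> list[Constraint]:
    """One formal constraint ``xi = g(x, k, t)`` per species assignment rule."""
    env, _ = constant_environment(model)
    subs = _assignment_substitution(model, env)
    constraints = []
    for s in model.species:
        if s.id not in model.assignment_rules:
            continue
        rhs = subs[sp.Symbol(s.id)]
        constraints.append(
            Constraint(
                kind="species-assignment",
                left=sp.Symbol(nm.species_map[s.id]),
                right=nm.rename(rhs),
                origin=s.id,
            )
        )
    return constraints


def assemble_odes(
    net: ReactionNetwork,
    model: RawModel,
    nm: NameMap,
    compartment_division: bool = True,
) -> ODESystem:
    """Assemble ``dx_i/dt = f_i(x, k, t)`` for every non-eliminated species.

    ``compartment_division=True`` (default) converts the amount-rate SBML
    kinetic laws to concentration rates by dividing each reaction term by
    the species' exact compartment size; species declared amount-based
    (``hasOnlySubstanceUnits``) are left undivided.
    """
    env, _problems = constant_environment(model)
    subs = _assignment_substitution(model, env)
    S = stoichiometric_matrix(net)
    rename = nm.substitution()

    comp_sizes = {}
    for c in model.compartments:
        value = env.get(c.id)
        comp_sizes[c.id] = value if isinstance(value, Fraction) else None

    laws = []
    for rec in net.reactions:
        law = rec.kinetic_law.xreplace(subs).xreplace(rename)
        laws.append(law)

    rate_rules = {
        target: expr for target, expr in model.rate_rules.items() if expr is not None
    }

    variables = []
    equations = []
    for i, s in enumerate(net.species):
        if s.has_assignment_rule:
            continue
        x = sp.Symbol(nm.species_map[s.id])
        variables.append(x)
        if s.id in rate_rules:
            f = rate_rules[s.id].xreplace(subs).xreplace(rename)
        elif s.boundary:
            f = sp.Integer(0)
        else:
            f = sp.Integer(0)
            for j in range(len(net.reactions)):
                coeff = S[i, j]
                if coeff != 0:
                    f = f + coeff * laws[j]
            if compartment_division and not s.amount_based and s.compartment:
                size = comp_sizes.get(s.compartment)
                if size is None:
                    raise AssemblyError(
                        f"compartment {s.compartment!r} has no constant rational size"
                    )
                if size == 0:
                    raise AssemblyError(f"compartment {s.compartment!r} has size zero")
                if size != 1:
                    f = f / to_sympy_rational(size)
        equations.append(f)

    parameter_values, initial_values = resolve_values(model, nm)
    constraints = species_assignment_constraints(model, nm)
    for target, expr in model.assignment_rules.items():
        if target in nm.parameter_map and not isinstance(env.get(target), Fraction):
            constraints.append(
                Constraint(
                    kind="parameter-assignment",
                    left=sp.Symbol(nm.parameter_map[target]),
                    right=nm.rename(expr.xreplace(subs)),
                    origin=target,
                )
            )

    system = ODESystem(
        variables=variables,
        equations=equations,
        constraints=constraints,
        name_map=nm,
        parameter_values=parameter_values,
        initial_values=initial_values,
    )
    _check_symbol_closure(system)
    return system


def _check_symbol_closure(system: ODESystem) -> None:
    allowed = set(system.name_map.species_symbols())
    allowed |= set(system.name_map.parameter_symbols())
    allowed.add(TIME_SYMBOL)
    for f in system.equations:
        stray = f.free_symbols - allowed
        if stray:
            raise AssemblyError(f"unrenamed symbols in right-hand side: {stray}")
    for c in system.constraints:
        stray = (c.left.free_symbols | c.right.free_symbols) - allowed
        stray = {s for s in stray if not str(s).startswith("c")}
        if stray:
            raise AssemblyError(f"unrenamed symbols in constraint: {stray}")
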