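"""Chemical reaction network theory metrics and kinetics classification.

The deficiency of a network is δ = c − ℓ − s: the number of distinct
complexes, minus the number of linkage classes (connected components of
the complex graph), minus the rank of the stoichiometric matrix.  It is a
purely structural index — zero for many well-behaved networks, positive
when the reaction vectors are more dependent than the linkage structure
alone forces — and it is always nonnegative.

Complexes are compared as exact composition maps: ``2A`` and ``A`` are
different complexes even though their reaction vectors are parallel, and
the empty (zero) complex representing inflow/outflow is a complex like any
other.  A reversible reaction contributes arrows in both directions, which
never changes c, ℓ or s.

Classification asks whether the assembled vector field is polynomial or
rational in the state (the shapes computer algebra handles best), and — in
the polynomial case — whether each kinetic law differs from mass-action
kinetics only by a factor free of species and time, a conservative
heuristic for detecting mass-action models.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import sympy as sp

from .network_model import (
    ReactionNetwork,
    kinetic_matrix,
    network_rank,
    stoichiometric_matrix,
)
from .ode_assembly import TIME_SYMBOL, NameMap, ODESystem

__all__ = [
    "Complex",
    "DeficiencyReport",
    "ClassificationReport",
    "enumerate_complexes",
    "linkage_classes",
    "deficiency",
    "classify_vector_field",
    "is_mass_action",
    "classify",
]


@dataclass(frozen=True)
class Complex:
    """A formal nonnegative combination of species (empty = zero complex)."""

    composition: tuple  # sorted ((species index, Fraction coeff), ...)

    @classmethod
    def from_stoich(cls, stoich: dict) -> "Complex":
        return cls(tuple(sorted((i, Fraction(c)) for i, c in stoich.items() if c != 0)))

    @property
    def is_zero(self) -> bool:
        return not self.composition


@dataclass(frozen=True)
class DeficiencyReport:
    n_complexes: int
    n_linkage_classes: int
    rank: int

    @property
    def deficiency(self) -> int:
        return self.n_complexes - self.n_linkage_classes - self.rank


@dataclass(frozen=True)
class ClassificationReport:
    vector_field_class: str      # "polynomial" | "rational" | "other"
    constraints_class: str
    mass_action: bool
    reaction_mass_action: tuple = ()   # per-reaction flags, document order


def enumerate_complexes(net: ReactionNetwork):
    """Distinct reactant/product complexes and the reaction arrows between
    them (reverse arrows included for reversible reactions)."""
    complexes: list[Complex] = []
    seen = {}

    def intern(c: Complex) -> Complex:
        if c.composition not in seen:
            seen[c.composition] = c
            complexes.append(c)
        return seen[c.composition]

    arrows = []
    for rec in net.reactions:
        source = intern(Complex.from_stoich(rec.reactant_stoich))
        target = intern(Complex.from_stoich(rec.product_stoich))
        arrows.append((source, target))
        if rec.reversible:
            arrows.append((target, source))
    return complexes, arrows


def linkage_classes(complexes, arrows):
    """Connected components of the undirected complex graph."""
    graph = nx.Graph()
    graph.add_nodes_from(c.composition for c in complexes)
    graph.add_edges_from((a.composition, b.composition) for a, b in arrows)
    by_key = {c.composition: c for c in complexes}
    return [
        frozenset(by_key[k] for k in component)
        for component in nx.connected_components(graph)
    ]


def deficiency(net: ReactionNetwork) -> DeficiencyReport:
    """δ = c − ℓ − s with the exact stoichiometric rank; δ ≥ 0 always."""
    complexes, arrows = enumerate_complexes(net)
    classes = linkage_classes(complexes, arrows)
    S = stoichiometric_matrix(net)
    report = DeficiencyReport(
        n_complexes=len(complexes),
        n_linkage_classes=len(classes),
        rank=network_rank(S),
    )
    if report.deficiency < 0:
        raise AssertionError(f"negative deficiency computed: {report}")
    return report


def _expression_class(expr: sp.Expr, state_syms, all_syms) -> str:
    gens = list(state_syms) + [TIME_SYMBOL]
    try:
        if expr.is_polynomial(*gens) and expr.is_rational_function(*all_syms):
            return "polynomial"
        if expr.is_rational_function(*all_syms):
            return "rational"
    except sp.PolynomialError:
        pass
    return "other"


_ORDER = {"polynomial": 0, "rational": 1, "other": 2}


def classify_vector_field(ode: ODESystem) -> tuple[str, str]:
    """Classify the right-hand sides and the constraints as polynomial /
    rational / other in (x, t) with coefficients rational in k."""
    nm = ode.name_map
    state = nm.species_symbols()
    all_syms = state + nm.parameter_symbols() + [TIME_SYMBOL]
    field_class = "polynomial"
    for f in ode.equations:
        field_class = max(
            field_class, _expression_class(f, state, all_syms), key=_ORDER.get
        )
    constraints_class = "polynomial"
    for c in ode.constraints:
        constraints_class = max(
            constraints_class,
            _expression_class(c.right - c.left, state, all_syms),
            key=_ORDER.get,
        )
    return field_class, constraints_class


def is_mass_action(net: ReactionNetwork, nm: NameMap):
    """Per-reaction mass-action test by symbolic quotient.

    Reaction j (with renamed law v_j) passes when
    ``v_j / Π x_i^Kin[i,j]`` cancels to an expression free of species
    symbols and of time — a constant factor in the mass-action sense,
    which may involve parameters, compartment sizes and rationals.
    Failure to cancel counts as not mass-action (conservative direction).
    """
    Kin = kinetic_matrix(net)
    rename = nm.substitution()
    state = set(nm.species_symbols())
    flags = []
    for j, rec in enumerate(net.reactions):
        law = rec.kinetic_law.xreplace(rename)
        monomial = sp.Integer(1)
        for i in range(len(net.species)):
            e = Kin[i, j]
            if e != 0:
                monomial *= sp.Symbol(nm.species_map[net.species[i].id]) ** e
        try:
            quotient = sp.cancel(sp.together(law / monomial))
        except sp.PolynomialError:
            flags.append(False)
            continue
        if quotient.has(sp.Piecewise):
            flags.append(False)
            continue
        free = quotient.free_symbols
        flags.append(not (free & state) and TIME_SYMBOL not in free)
    return tuple(flags)


def classify(net: ReactionNetwork, ode: ODESystem) -> ClassificationReport:
    """Model-level classification: field/constraint classes and the
    mass-action flag (all reactions pass *and* the field is polynomial,
    so mass_action implies polynomial by construction)."""
    field_class, constraints_class = classify_vector_field(ode)
    flags = is_mass_action(net, ode.name_map)
    model_flag = bool(flags) and all(flags) and field_class == "polynomial"
    return ClassificationReport(
        vector_field_class=field_class,
        constraints_class=constraints_class,
        mass_action=model_flag,
        reaction_mass_action=flags,
    )
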