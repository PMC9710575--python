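"""Synthetic SBML generator with ground truth known by construction.

The generator assembles random reaction networks whose properties are
known *because the generator built them*: a mass-action law is written as
``k · Π x^a`` directly from the chosen stoichiometry, so its kinetics
label is true by definition, and the stoichiometric matrix in the
ground-truth manifest is the one the reactions were constructed from, not
a re-derivation.  Structural quantities that are not immediate from the
construction (rank, conservation span, deficiency counts) are computed in
this module by a deliberately simple, independent path — sympy's own
rational elimination and a hand-rolled union-find — so that the manifest
never depends on the conversion pipeline it is used to test.

Rate constants and initial concentrations are drawn as small rationals
whose denominators divide a power of ten, so their decimal attribute
strings in the XML are exact and round-trip losslessly into fractions.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

import sympy as sp
from lxml import etree

from .mathml import expr_to_mathml

__all__ = ["FixtureSpecError", "FixtureSpec", "FixtureManifest", "generate", "named_toys"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_S = "{%s}" % SBML_NS

KINETICS = ("mass-action", "michaelis-menten", "mixed")


class FixtureSpecError(ValueError):
    """An unsatisfiable or malformed fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    n_species: int = 4
    n_reactions: int = 3
    kinetics: str = "mass-action"
    reversible_fraction: float = 0.0
    include_boundary: bool = False
    include_rules: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise FixtureSpecError("need at least one species")
        if self.n_reactions < 0:
            raise FixtureSpecError("negative reaction count")
        if self.include_rules and self.n_reactions == 0 and self.n_species < 2:
            raise FixtureSpecError("rules need at least two species or a reaction")
        if self.kinetics not in KINETICS:
            raise FixtureSpecError(f"unknown kinetics {self.kinetics!r}")
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise FixtureSpecError("reversible_fraction must be in [0, 1]")


@dataclass
class FixtureManifest:
    """Ground truth for a generated document (independent of the pipeline)."""

    species_ids: list
    boundary_ids: list
    assignment_rule_ids: list
    dynamic_species_ids: list
    reactions: list                      # dicts: id, kinetics, reversible, law, mass_action_quotient
    stoich: list                         # rows over all species, Fractions as str
    kinetic: list
    parameter_values: dict               # id -> Fraction as str
    initial_concentrations: dict
    expected_deficiency: dict            # complexes / linkage_classes / rank / deficiency
    expected_conservation_span: list     # vectors over dynamic species, str entries
    expected_vector_field: str
    expected_mass_action: bool
    compartment: str = "cell"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# exact decimal strings for XML attributes


def _decimal_attr(value: Fraction) -> str:
    """Render a fraction with 10-smooth denominator as an exact decimal."""
    quotient = Decimal(value.numerator) / Decimal(value.denominator)
    text = format(quotient.normalize(), "f")
    return text


def _random_constant(rng: random.Random) -> Fraction:
    return Fraction(rng.randint(1, 9), rng.choice([1, 2, 4, 5, 10]))


# ---------------------------------------------------------------------------
# independent structural ground truth (simple code paths, no pipeline)


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self) -> int:
        return len({self.find(x) for x in self.parent})


def _structural_truth(species_ids, reactions, dynamic_ids):
    """Complexes, linkage classes, rank, deficiency and conservation span
    by direct composition comparison, union-find and sympy elimination."""
    index = {sid: i for i, sid in enumerate(species_ids)}
    n = len(species_ids)
    S_rows = [[Fraction(0)] * len(reactions) for _ in range(n)]
    K_rows = [[Fraction(0)] * len(reactions) for _ in range(n)]
    uf = _UnionFind()
    complex_keys = set()
    for j, rec in enumerate(reactions):
        source = tuple(sorted((sid, str(c)) for sid, c in rec["reactants"]))
        target = tuple(sorted((sid, str(c)) for sid, c in rec["products"]))
        complex_keys.add(source)
        complex_keys.add(target)
        uf.add(source)
        uf.add(target)
        uf.union(source, target)
        for sid, c in rec["reactants"]:
            S_rows[index[sid]][j] -= c
            K_rows[index[sid]][j] += c
        for sid, c in rec["products"]:
            S_rows[index[sid]][j] += c
    S = sp.Matrix(
        [[sp.Rational(f.numerator, f.denominator) for f in row] for row in S_rows]
    ) if reactions else sp.zeros(n, 0)
    rank = S.rank() if reactions else 0
    dyn_rows = [index[sid] for sid in dynamic_ids]
    if reactions and dyn_rows:
        S_dyn = S[dyn_rows, :]
        span = [
            [sp.sstr(v[i]) for i in range(len(dyn_rows))]
            for v in S_dyn.T.nullspace()
        ]
    else:
        span = [
            ["1" if i == j else "0" for i in range(len(dyn_rows))]
            for j in range(len(dyn_rows))
        ]
    deficiency = len(complex_keys) - uf.n_components() - rank
    return {
        "S": [[str(f) for f in row] for row in S_rows],
        "K": [[str(f) for f in row] for row in K_rows],
        "deficiency": {
            "complexes": len(complex_keys),
            "linkage_classes": uf.n_components(),
            "rank": rank,
            "deficiency": deficiency,
        },
        "span": span,
    }


# ---------------------------------------------------------------------------
# XML assembly


def _build_sbml(
    model_id,
    species,                  # (id, boundary: bool, initial: Fraction|None)
    parameters,               # (id, Fraction)
    reactions,                # dicts with id, reactants, products, law, reversible
    assignment_rules=(),      # (target, sympy expr)
    initial_assignments=(),   # (target, sympy expr)
    rate_rules=(),
    compartment="cell",
) -> str:
    root = etree.Element(
        _S + "sbml", nsmap={None: SBML_NS}, level="3", version="2"
    )
    model = etree.SubElement(root, _S + "model", id=model_id)
    loc = etree.SubElement(model, _S + "listOfCompartments")
    etree.SubElement(
        loc, _S + "compartment", id=compartment, size="1", constant="true"
    )
    los = etree.SubElement(model, _S + "listOfSpecies")
    for sid, boundary, initial in species:
        attrs = {
            "id": sid,
            "compartment": compartment,
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if boundary else "false",
            "constant": "false",
        }
        if initial is not None:
            attrs["initialConcentration"] = _decimal_attr(initial)
        etree.SubElement(los, _S + "species", **attrs)
    if parameters:
        lop = etree.SubElement(model, _S + "listOfParameters")
        for pid, value in parameters:
            attrs = {"id": pid, "constant": "true"}
            if value is not None:
                attrs["value"] = _decimal_attr(value)
            etree.SubElement(lop, _S + "parameter", **attrs)
    if assignment_rules or rate_rules:
        lor = etree.SubElement(model, _S + "listOfRules")
        for target, expr in assignment_rules:
            rule = etree.SubElement(lor, _S + "assignmentRule", variable=target)
            rule.append(expr_to_mathml(expr))
        for target, expr in rate_rules:
            rule = etree.SubElement(lor, _S + "rateRule", variable=target)
            rule.append(expr_to_mathml(expr))
    if initial_assignments:
        loi = etree.SubElement(model, _S + "listOfInitialAssignments")
        for target, expr in initial_assignments:
            ia = etree.SubElement(loi, _S + "initialAssignment", symbol=target)
            ia.append(expr_to_mathml(expr))
    lorx = etree.SubElement(model, _S + "listOfReactions")
    for rec in reactions:
        rx = etree.SubElement(
            lorx,
            _S + "reaction",
            id=rec["id"],
            reversible="true" if rec["reversible"] else "false",
        )
        if rec["reactants"]:
            lref = etree.SubElement(rx, _S + "listOfReactants")
            for sid, coeff in rec["reactants"]:
                etree.SubElement(
                    lref,
                    _S + "speciesReference",
                    species=sid,
                    stoichiometry=_decimal_attr(Fraction(coeff)),
                    constant="true",
                )
        if rec["products"]:
            lref = etree.SubElement(rx, _S + "listOfProducts")
            for sid, coeff in rec["products"]:
                etree.SubElement(
                    lref,
                    _S + "speciesReference",
                    species=sid,
                    stoichiometry=_decimal_attr(Fraction(coeff)),
                    constant="true",
                )
        kl = etree.SubElement(rx, _S + "kineticLaw")
        kl.append(expr_to_mathml(rec["law"]))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


# ---------------------------------------------------------------------------
# random generation


def _sample_complex(rng, ids):
    """A random reactant or product complex over 1–2 species."""
    if len(ids) >= 2 and rng.random() < 0.4:
        pair = rng.sample(ids, 2)
        return [(pair[0], Fraction(1)), (pair[1], Fraction(1))]
    sid = rng.choice(ids)
    coeff = Fraction(2) if rng.random() < 0.25 else Fraction(1)
    return [(sid, coeff)]


def _sample_reaction(rng, ids, boundary_ids):
    """Reactant/product complexes that differ and move ≥1 dynamic species."""
    boundary = set(boundary_ids)
    for _ in range(200):
        reactants = _sample_complex(rng, ids)
        products = _sample_complex(rng, ids)
        if sorted(reactants) == sorted(products):
            continue
        net: dict = {}
        for sid, c in reactants:
            net[sid] = net.get(sid, Fraction(0)) - c
        for sid, c in products:
            net[sid] = net.get(sid, Fraction(0)) + c
        if any(v != 0 and sid not in boundary for sid, v in net.items()):
            return reactants, products
    raise FixtureSpecError("could not sample a usable reaction")


def _mass_action_law(k_sym, reactants):
    law = k_sym
    for sid, coeff in reactants:
        law = law * sp.Symbol(sid) ** sp.Rational(coeff.numerator, coeff.denominator)
    return law


def generate(spec: FixtureSpec):
    """Generate ``(SBML text, FixtureManifest)``; same seed, same bytes."""
    rng = random.Random(spec.seed)
    ids = [f"S{i + 1}" for i in range(spec.n_species)]
    boundary_ids = [ids[0]] if spec.include_boundary and spec.n_species >= 1 else []

    parameters: list = []
    reactions: list = []
    manifest_reactions: list = []
    for j in range(spec.n_reactions):
        rid = f"R{j + 1}"
        if spec.kinetics == "mixed":
            kind = rng.choice(["mass-action", "michaelis-menten"])
        else:
            kind = spec.kinetics
        if kind == "michaelis-menten":
            sid = rng.choice(ids)
            others = [s for s in ids if s != sid] or ids
            pid = rng.choice(others)
            if sid in boundary_ids and pid in boundary_ids:
                pid = next(s for s in ids if s not in boundary_ids)
            v_name, k_name = f"V_{rid}", f"K_{rid}"
            v_val, k_val = _random_constant(rng), _random_constant(rng)
            parameters += [(v_name, v_val), (k_name, k_val)]
            law = sp.Symbol(v_name) * sp.Symbol(sid) / (sp.Symbol(k_name) + sp.Symbol(sid))
            reactants = [(sid, Fraction(1))]
            products = [(pid, Fraction(1))]
            reversible = False
            quotient_flag = False
        else:
            reactants, products = _sample_reaction(rng, ids, boundary_ids)
            reversible = rng.random() < spec.reversible_fraction
            kf_name = f"kf_{rid}"
            kf_val = _random_constant(rng)
            parameters.append((kf_name, kf_val))
            law = _mass_action_law(sp.Symbol(kf_name), reactants)
            if reversible:
                kr_name = f"kr_{rid}"
                kr_val = _random_constant(rng)
                parameters.append((kr_name, kr_val))
                law = law - _mass_action_law(sp.Symbol(kr_name), products)
                quotient_flag = False   # net law depends on product species
            else:
                quotient_flag = True
        reactions.append(
            {
                "id": rid,
                "reactants": reactants,
                "products": products,
                "law": law,
                "reversible": reversible,
            }
        )
        manifest_reactions.append(
            {
                "id": rid,
                "kinetics": kind,
                "reversible": reversible,
                "law": sp.sstr(law),
                "reactants": [[sid, str(c)] for sid, c in reactants],
                "products": [[sid, str(c)] for sid, c in products],
                "mass_action_quotient": quotient_flag,
            }
        )

    initials = {sid: _random_constant(rng) for sid in ids}
    assignment_rules = []
    initial_assignments = []
    rule_ids: list = []
    if spec.include_rules:
        obs = "Sobs"
        rule_ids.append(obs)
        if spec.n_species >= 2:
            rule_expr = sp.Symbol(ids[0]) + sp.Symbol(ids[1])
        else:
            rule_expr = sp.Integer(2) * sp.Symbol(ids[0])
        assignment_rules.append((obs, rule_expr))
        parameters.append(("k_ia", None))
        initial_assignments.append(("k_ia", sp.Rational(3, 2)))

    species_rows = [(sid, sid in boundary_ids, initials[sid]) for sid in ids]
    if rule_ids:
        species_rows += [(sid, False, None) for sid in rule_ids]
    all_ids = ids + rule_ids
    dynamic_ids = [s for s in ids if s not in boundary_ids]

    sbml = _build_sbml(
        model_id=f"fixture_seed{spec.seed}",
        species=species_rows,
        parameters=parameters,
        reactions=reactions,
        assignment_rules=assignment_rules,
        initial_assignments=initial_assignments,
    )

    truth = _structural_truth(
        all_ids,
        [
            {"reactants": r["reactants"], "products": r["products"]}
            for r in reactions
        ],
        dynamic_ids,
    )
    kinds = {r["kinetics"] for r in manifest_reactions}
    vector_field = "rational" if "michaelis-menten" in kinds else "polynomial"
    mass_action = (
        bool(manifest_reactions)
        and all(r["mass_action_quotient"] for r in manifest_reactions)
        and vector_field == "polynomial"
    )
    manifest = FixtureManifest(
        species_ids=all_ids,
        boundary_ids=boundary_ids,
        assignment_rule_ids=rule_ids,
        dynamic_species_ids=dynamic_ids,
        reactions=manifest_reactions,
        stoich=truth["S"],
        kinetic=truth["K"],
        parameter_values={
            pid: str(val) for pid, val in parameters if val is not None
        },
        initial_concentrations={sid: str(v) for sid, v in initials.items()},
        expected_deficiency=truth["deficiency"],
        expected_conservation_span=truth["span"],
        expected_vector_field=vector_field,
        expected_mass_action=mass_action,
    )
    return sbml, manifest


# ---------------------------------------------------------------------------
# canonical toy networks


def named_toys() -> dict:
    """Canonical small networks with hand-checkable structure.

    * ``iso``   — A⇌B (two irreversible directions): δ=0, conservation (1,1)
    * ``bind``  — A+B⇌C: δ=0, two conservation laws
    * ``def1``  — {A→B, 2A→2B}: the classic deficiency-one pair
    * ``inflow``— ∅→A→∅: δ=0, no conservation law
    * ``mm``    — one Michaelis–Menten conversion: rational vector field
    """
    toys = {}
    half = Fraction(1, 2)

    def entry(name, sbml, truth, labels, mass_action, vector_field):
        manifest = FixtureManifest(
            species_ids=truth["ids"],
            boundary_ids=[],
            assignment_rule_ids=[],
            dynamic_species_ids=truth["ids"],
            reactions=labels,
            stoich=truth["S"],
            kinetic=truth["K"],
            parameter_values=truth["params"],
            initial_concentrations=truth["initials"],
            expected_deficiency=truth["deficiency"],
            expected_conservation_span=truth["span"],
            expected_vector_field=vector_field,
            expected_mass_action=mass_action,
        )
        toys[name] = (sbml, manifest)

    def make(name, species, parameters, reactions, labels, mass_action, vector_field):
        ids = [s[0] for s in species]
        for lab, rec in zip(labels, reactions):
            lab.setdefault("reversible", rec["reversible"])
            lab["law"] = sp.sstr(rec["law"])
            lab["reactants"] = [[sid, str(c)] for sid, c in rec["reactants"]]
            lab["products"] = [[sid, str(c)] for sid, c in rec["products"]]
        sbml = _build_sbml(name, species, parameters, reactions)
        truth = _structural_truth(
            ids,
            [{"reactants": r["reactants"], "products": r["products"]} for r in reactions],
            ids,
        )
        truth["ids"] = ids
        truth["params"] = {p: str(v) for p, v in parameters}
        truth["initials"] = {s[0]: str(s[2]) for s in species if s[2] is not None}
        entry(name, sbml, truth, labels, mass_action, vector_field)

    one = Fraction(1)
    make(
        "iso",
        [("A", False, Fraction(2)), ("B", False, half)],
        [("k1", one), ("k2", Fraction(3, 2))],
        [
            {"id": "R1", "reactants": [("A", one)], "products": [("B", one)],
             "law": sp.Symbol("k1") * sp.Symbol("A"), "reversible": False},
            {"id": "R2", "reactants": [("B", one)], "products": [("A", one)],
             "law": sp.Symbol("k2") * sp.Symbol("B"), "reversible": False},
        ],
        [{"id": "R1", "kinetics": "mass-action", "mass_action_quotient": True},
         {"id": "R2", "kinetics": "mass-action", "mass_action_quotient": True}],
        mass_action=True,
        vector_field="polynomial",
    )
    make(
        "bind",
        [("A", False, one), ("B", False, Fraction(2)), ("C", False, Fraction(0))],
        [("kon", half), ("koff", Fraction(1, 5))],
        [
            {"id": "R1", "reactants": [("A", one), ("B", one)], "products": [("C", one)],
             "law": sp.Symbol("kon") * sp.Symbol("A") * sp.Symbol("B"), "reversible": False},
            {"id": "R2", "reactants": [("C", one)], "products": [("A", one), ("B", one)],
             "law": sp.Symbol("koff") * sp.Symbol("C"), "reversible": False},
        ],
        [{"id": "R1", "kinetics": "mass-action", "mass_action_quotient": True},
         {"id": "R2", "kinetics": "mass-action", "mass_action_quotient": True}],
        mass_action=True,
        vector_field="polynomial",
    )
    make(
        "def1",
        [("A", False, one), ("B", False, one)],
        [("k1", one), ("k2", Fraction(2))],
        [
            {"id": "R1", "reactants": [("A", one)], "products": [("B", one)],
             "law": sp.Symbol("k1") * sp.Symbol("A"), "reversible": False},
            {"id": "R2", "reactants": [("A", Fraction(2))], "products": [("B", Fraction(2))],
             "law": sp.Symbol("k2") * sp.Symbol("A") ** 2, "reversible": False},
        ],
        [{"id": "R1", "kinetics": "mass-action", "mass_action_quotient": True},
         {"id": "R2", "kinetics": "mass-action", "mass_action_quotient": True}],
        mass_action=True,
        vector_field="polynomial",
    )
    make(
        "inflow",
        [("A", False, one)],
        [("kin", Fraction(4, 5)), ("kout", half)],
        [
            {"id": "R1", "reactants": [], "products": [("A", one)],
             "law": sp.Symbol("kin"), "reversible": False},
            {"id": "R2", "reactants": [("A", one)], "products": [],
             "law": sp.Symbol("kout") * sp.Symbol("A"), "reversible": False},
        ],
        [{"id": "R1", "kinetics": "mass-action", "mass_action_quotient": True},
         {"id": "R2", "kinetics": "mass-action", "mass_action_quotient": True}],
        mass_action=True,
        vector_field="polynomial",
    )
    make(
        "mm",
        [("S", False, Fraction(5)), ("P", False, Fraction(0))],
        [("V", Fraction(3, 2)), ("K", Fraction(2))],
        [
            {"id": "R1", "reactants": [("S", one)], "products": [("P", one)],
             "law": sp.Symbol("V") * sp.Symbol("S") / (sp.Symbol("K") + sp.Symbol("S")),
             "reversible": False},
        ],
        [{"id": "R1", "kinetics": "michaelis-menten", "mass_action_quotient": False}],
        mass_action=False,
        vector_field="rational",
    )
    return toys
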