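"""Reaction-network core: exact stoichiometric and kinetic matrices.

The network view of a model is the pair of species × reactions matrices
over exact rationals:

* the stoichiometric matrix ``S`` with ``S[i, j]`` the *net* change of
  species ``i`` in reaction ``j`` (product minus reactant coefficient), and
* the kinetic (kinetic-order) matrix ``Kin`` with the reactant-side
  coefficient, the exponent mass-action kinetics would assign.

Boundary-condition species keep their rows: the matrices report network
structure; the constancy of boundary species is enforced at ODE assembly.
A reversible SBML reaction contributes a single column for the forward
direction as written — its kinetic law encodes the net rate.

The rank of ``S`` is computed with fraction-free (Bareiss) elimination on
an integer scaling of the matrix, exact at every step; sympy's rational
rank serves as an independent cross-check in the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import lcm

import sympy as sp

from .exact_arithmetic import literal_to_rational, to_sympy_rational
from .sbml_ingest import RawModel

__all__ = [
    "NetworkError",
    "NetworkSpecies",
    "NetworkParameter",
    "ReactionRecord",
    "ReactionNetwork",
    "build_network",
    "stoichiometric_matrix",
    "kinetic_matrix",
    "network_rank",
    "matrix_to_fractions",
]


class NetworkError(ValueError):
    """Inconsistent network construction input."""


@dataclass(frozen=True)
class NetworkSpecies:
    id: str
    compartment: str | None
    boundary: bool              # boundaryCondition or constant species
    has_assignment_rule: bool
    has_rate_rule: bool
    amount_based: bool          # hasOnlySubstanceUnits


@dataclass(frozen=True)
class NetworkParameter:
    id: str
    value: Fraction | None
    origin: str                 # "global" | "compartment" | "local:<reaction id>"


@dataclass(frozen=True)
class ReactionRecord:
    id: str
    reactant_stoich: dict       # species index -> Fraction > 0
    product_stoich: dict
    kinetic_law: sp.Expr
    reversible: bool


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple              # NetworkSpecies, document order
    reactions: tuple            # ReactionRecord, document order
    parameters: tuple           # NetworkParameter: globals, compartments, lifted locals

    def species_index(self, sid: str) -> int:
        for i, s in enumerate(self.species):
            if s.id == sid:
                return i
        raise KeyError(sid)


def build_network(model: RawModel) -> ReactionNetwork:
    """Build the :class:`ReactionNetwork` from a gated, inlined, lifted model.

    Parameters are ordered globals-first (document order), then constant
    compartment sizes, then lifted local parameters in reaction order —
    the order canonical naming will follow.
    """
    from .sbml_ingest import constant_environment

    env, _problems = constant_environment(model)

    species = tuple(
        NetworkSpecies(
            id=s.id,
            compartment=s.compartment,
            boundary=s.boundary_condition or s.constant,
            has_assignment_rule=s.id in model.assignment_rules,
            has_rate_rule=s.id in model.rate_rules,
            amount_based=s.has_only_substance_units,
        )
        for s in model.species
    )
    index = {s.id: i for i, s in enumerate(species)}

    def as_fraction(value):
        return value if isinstance(value, Fraction) else None

    params = []
    for p in model.global_parameters:
        if p.origin is None:
            params.append(
                NetworkParameter(id=p.id, value=as_fraction(env.get(p.id)), origin="global")
            )
    for c in model.compartments:
        params.append(
            NetworkParameter(
                id=c.id, value=as_fraction(env.get(c.id)), origin="compartment"
            )
        )
    for r in model.reactions:
        if r.local_parameters:
            raise NetworkError(
                f"reaction {r.id!r} still has local parameters; lift them first"
            )
    for p in model.global_parameters:
        if p.origin is not None:
            params.append(
                NetworkParameter(
                    id=p.id, value=as_fraction(env.get(p.id)), origin=f"local:{p.origin[1]}"
                )
            )

    reactions = []
    for r in model.reactions:
        if r.kinetic_law is None:
            raise NetworkError(f"reaction {r.id!r} has no kinetic law")

        def stoich_map(refs):
            out: dict[int, Fraction] = {}
            for sid, stoich in refs:
                if sid not in index:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
                out[index[sid]] = out.get(index[sid], Fraction(0)) + literal_to_rational(
                    stoich
                )
            return out

        reactions.append(
            ReactionRecord(
                id=r.id,
                reactant_stoich=stoich_map(r.reactants),
                product_stoich=stoich_map(r.products),
                kinetic_law=r.kinetic_law,
                reversible=r.reversible,
            )
        )
    return ReactionNetwork(
        species=species, reactions=tuple(reactions), parameters=tuple(params)
    )


def stoichiometric_matrix(net: ReactionNetwork) -> sp.ImmutableMatrix:
    """Net-change matrix ``S``: entry (i, j) = product − reactant coefficient."""
    n, r = len(net.species), len(net.reactions)
    entries = sp.zeros(n, max(r, 0))
    for j, rec in enumerate(net.reactions):
        for i, coeff in rec.product_stoich.items():
            entries[i, j] += to_sympy_rational(coeff)
        for i, coeff in rec.reactant_stoich.items():
            entries[i, j] -= to_sympy_rational(coeff)
    return sp.ImmutableMatrix(entries)


def kinetic_matrix(net: ReactionNetwork) -> sp.ImmutableMatrix:
    """Kinetic-order matrix: entry (i, j) = reactant-side coefficient."""
    n, r = len(net.species), len(net.reactions)
    entries = sp.zeros(n, max(r, 0))
    for j, rec in enumerate(net.reactions):
        for i, coeff in rec.reactant_stoich.items():
            entries[i, j] = to_sympy_rational(coeff)
    return sp.ImmutableMatrix(entries)


def matrix_to_fractions(matrix: sp.MatrixBase) -> list[list[Fraction]]:
    """Copy a rational sympy matrix into nested Fractions."""
    rows = []
    for i in range(matrix.rows):
        row = []
        for j in range(matrix.cols):
            e = sp.nsimplify(matrix[i, j], rational=True)
            if not e.is_Rational:
                raise NetworkError(f"non-rational matrix entry at ({i}, {j}): {e}")
            row.append(Fraction(int(e.p), int(e.q)))
        rows.append(row)
    return rows


def _integerize_rows(rows: list[list[Fraction]]) -> list[list[int]]:
    out = []
    for row in rows:
        denom = lcm(*(f.denominator for f in row)) if row else 1
        out.append([int(f * denom) for f in row])
    return out


def network_rank(S) -> int:
    """Exact rank over the rationals via fraction-free Bareiss elimination.

    Accepts a rational sympy matrix or nested ``Fraction`` rows.  Rows are
    first scaled to integers; all intermediate quantities stay integers,
    avoiding both rounding and coefficient blow-up from naive fraction
    arithmetic.
    """
    rows = matrix_to_fractions(S) if isinstance(S, sp.MatrixBase) else [list(r) for r in S]
    if not rows or not rows[0]:
        return 0
    m = _integerize_rows(rows)
    n_rows, n_cols = len(m), len(m[0])
    rank = 0
    prev_pivot = 1
    for col in range(n_cols):
        if rank >= n_rows:
            break
        pivot_row = next((i for i in range(rank, n_rows) if m[i][col] != 0), None)
        if pivot_row is None:
            continue
        m[rank], m[pivot_row] = m[pivot_row], m[rank]
        pivot = m[rank][col]
        for i in range(rank + 1, n_rows):
            for j in range(col + 1, n_cols):
                # Bareiss step: division is exact by construction
                m[i][j] = (pivot * m[i][j] - m[i][col] * m[rank][j]) // prev_pivot
            m[i][col] = 0
        prev_pivot = pivot
        rank += 1
    return rank
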