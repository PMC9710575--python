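"""Linear conservation laws from the left kernel of the stoichiometric matrix.

A vector ``y`` with ``yᵀ S_dyn = 0`` makes ``Σ y_i x_i`` constant along
every trajectory of the reaction dynamics, whatever the kinetic laws.
``S_dyn`` is the stoichiometric matrix restricted to the *dynamic* species:
boundary, constant, assignment-rule and rate-rule species are excluded,
because their rows do not describe the assembled dynamics (a boundary
species is pinned, a rate-rule species follows its own equation).

The kernel is computed by exact reduced row echelon form over Fractions —
no tolerance anywhere; each basis vector is normalized to a primitive
integer vector with positive leading coefficient, and a best-effort pass
replaces mixed-sign vectors by nonnegative combinations when a small
positive combination of basis vectors achieves it (full nonnegative-basis
computation by extreme rays is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm

import sympy as sp

from .exact_arithmetic import to_sympy_rational
from .network_model import ReactionNetwork, matrix_to_fractions
from .ode_assembly import Constraint, NameMap

__all__ = [
    "ConservationLaw",
    "dynamic_species_indices",
    "left_kernel_basis",
    "conservation_constraints",
]


@dataclass(frozen=True)
class ConservationLaw:
    coefficients: tuple          # primitive integers over dynamic species
    species_indices: tuple       # matching global species indices
    total: object = None         # Fraction, sympy Symbol, or None


def dynamic_species_indices(net: ReactionNetwork) -> list[int]:
    """Indices of species whose dynamics come from the reaction fluxes."""
    return [
        i
        for i, s in enumerate(net.species)
        if not (s.boundary or s.has_assignment_rule or s.has_rate_rule)
    ]


def _rref(rows: list[list[Fraction]]):
    """Exact RREF over Fractions; returns (rref rows, pivot column list)."""
    m = [list(r) for r in rows]
    n_rows = len(m)
    n_cols = len(m[0]) if m else 0
    pivots = []
    row = 0
    for col in range(n_cols):
        pivot = next((i for i in range(row, n_rows) if m[i][col] != 0), None)
        if pivot is None:
            continue
        m[row], m[pivot] = m[pivot], m[row]
        inv = m[row][col]
        m[row] = [v / inv for v in m[row]]
        for i in range(n_rows):
            if i != row and m[i][col] != 0:
                factor = m[i][col]
                m[i] = [a - factor * b for a, b in zip(m[i], m[row])]
        pivots.append(col)
        row += 1
        if row == n_rows:
            break
    return m[:row], pivots


def _primitive(vector: list[Fraction]) -> list[int]:
    denom = lcm(*(f.denominator for f in vector)) if vector else 1
    ints = [int(f * denom) for f in vector]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    leading = next((v for v in ints if v != 0), 0)
    if leading < 0:
        ints = [-v for v in ints]
    return ints


def _prefer_nonnegative(basis: list[list[int]]) -> list[list[int]]:
    """Replace mixed-sign vectors by nonnegative positive combinations
    of basis vectors when a small multiplier achieves it (best effort)."""
    out = [list(v) for v in basis]
    for _ in range(2):
        for i, v in enumerate(out):
            if all(e >= 0 for e in v):
                continue
            for j, w in enumerate(out):
                if i == j:
                    continue
                replaced = False
                # alpha*v + c*w with alpha = +/-1 keeps the basis a basis
                for alpha, c in ((1, 1), (1, 2), (1, 3), (-1, 1), (-1, 2), (-1, 3)):
                    cand = [alpha * a + c * b for a, b in zip(v, w)]
                    if any(cand) and all(e >= 0 for e in cand):
                        out[i] = _primitive([Fraction(e) for e in cand])
                        replaced = True
                        break
                if replaced:
                    break
    return out


def left_kernel_basis(S_dyn) -> list[list[int]]:
    """Primitive-integer basis of ``{y : yᵀ S_dyn = 0}``.

    ``S_dyn`` is a rational sympy matrix or nested Fractions (rows =
    dynamic species).  The basis size equals ``n_dyn − rank(S_dyn)``; the
    empty list means the kernel is trivial.  Every returned vector
    annihilates ``S_dyn`` identically in exact arithmetic.
    """
    rows = (
        matrix_to_fractions(S_dyn)
        if isinstance(S_dyn, sp.MatrixBase)
        else [list(r) for r in S_dyn]
    )
    n = len(rows)
    if n == 0:
        return []
    n_cols = len(rows[0]) if rows[0] else 0
    if n_cols == 0:
        # no reactions: every species total is trivially conserved
        basis = []
        for i in range(n):
            v = [0] * n
            v[i] = 1
            basis.append(v)
        return basis
    # left kernel of S = nullspace of S transposed
    transposed = [[rows[i][j] for i in range(n)] for j in range(n_cols)]
    rref, pivots = _rref(transposed)
    free_cols = [j for j in range(n) if j not in pivots]
    basis = []
    for fc in free_cols:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for row_idx, pc in enumerate(pivots):
            v[pc] = -rref[row_idx][fc]
        basis.append(_primitive(v))
    return _prefer_nonnegative(basis)


def conservation_constraints(
    basis: list[list[int]],
    dyn_indices: list[int],
    net: ReactionNetwork,
    initial_values: dict,
    nm: NameMap,
) -> tuple[list[ConservationLaw], list[Constraint]]:
    """Turn kernel vectors into conserved-total constraints.

    Each vector yields ``Σ y_i x_i = total``; the total is the exact
    rational dot product with the initial values when every species with a
    nonzero coefficient has a known initial value, otherwise a fresh
    symbolic constant ``c1, c2, …``.
    """
    laws = []
    constraints = []
    const_counter = 0
    for vector in basis:
        lhs = sp.Integer(0)
        total: object
        known = Fraction(0)
        all_known = True
        for coeff, global_idx in zip(vector, dyn_indices):
            if coeff == 0:
                continue
            x = sp.Symbol(nm.species_map[net.species[global_idx].id])
            lhs = lhs + sp.Integer(coeff) * x
            x0 = initial_values.get(x)
            if isinstance(x0, Fraction):
                known += coeff * x0
            else:
                all_known = False
        if all_known:
            total = known
            rhs = to_sympy_rational(known)
        else:
            const_counter += 1
            total = sp.Symbol(f"c{const_counter}")
            rhs = total
        laws.append(
            ConservationLaw(
                coefficients=tuple(vector), species_indices=tuple(dyn_indices), total=total
            )
        )
        constraints.append(
            Constraint(kind="conservation", left=lhs, right=rhs, origin=f"conservation-{len(laws)}")
        )
    return laws, constraints
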