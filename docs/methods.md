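# Methods

This note records what the converter computes, the semantic choices made
where SBML or the mathematics leaves room, and what the test fixtures do
and do not establish.

## Model

An SBML reaction network is read as a set of species with concentrations
`x(t)`, constant parameters `k`, constant compartment sizes, and reactions
with kinetic laws `v_j(x, k, t)`. The assembled system is

    dx_i/dt = f_i(x, k, t) = sum_j S[i, j] * v_j(x, k, t) / vol(i)

where `S` is the net stoichiometric matrix and `vol(i)` the (exact,
rational) size of species *i*'s compartment. The system is autonomous
unless a kinetic law or rate rule references SBML's `time` csymbol.

Species semantics follow SBML:

- *boundary-condition* and *constant* species keep their matrix rows but
  get `f_i = 0` — the matrices describe network structure, the pinning is
  a property of the dynamics;
- a species with a *rate rule* uses the rule's expression as its `f_i`;
- a species with an *assignment rule* is not a state variable: the rule is
  substituted into every law (in dependency order; cycles are an error)
  and survives as a formal constraint `x_i = g(x, k, t)`.

Every species therefore carries exactly one of an ODE or an assignment
constraint, an invariant the test suite checks on random models.

## Exact arithmetic

All constants are rationals. Conversion is **lexical-first**: the XML
attribute text `0.1` means 1/10 (the number the modeller wrote), so
`literal_to_rational` parses the decimal string; `double_to_rational`
exists for values only reachable as binary doubles and recovers the exact
dyadic rational of the bit pattern. No operation on the conversion path
produces a floating-point intermediate.

Constant expressions (initial assignments, constant assignment rules) are
evaluated exactly under `+ − × ÷` and integer powers. Irrationality
detection is *conservative by construction*: any transcendental head —
`exp`, `log`, trigonometric functions, `pi`, `e`, or a fractional power
that is not an exact perfect power — applied to a non-identity argument
flags the value irrational and the model is rejected. Identity cases
(`exp(0)`, perfect powers such as `4^(1/2)`) still evaluate to rationals
because sympy's constructors collapse them before the check. The flag can
reject a coincidentally rational value; it cannot accept an irrational
one. One caveat inherits from the constructor-evaluation strategy:
compositions that sympy collapses on construction (e.g. `exp(log(2))`)
are accepted as the rational they evaluate to.

## Feature gating

Supported: species with boundary condition, local parameters, parameter
and species assignment rules, parameter and species initial assignments,
species rate rules, function definitions. Rejected, each with an itemized
violation: events, parameter (and compartment) rate rules, algebraic
rules, SBML `constraint` elements, non-constant compartments,
`stoichiometryMath`, reactions without kinetic laws, `delay` csymbols,
NaN/infinite literals, and irrational constant values. SBML Level 1 is
rejected at parse time; Levels 2 and 3 are accepted. Gating is checked
*after* function inlining and local-parameter lifting, so locals with
irrational values are caught too.

Local parameters are lifted to globals named `<reaction>_<id>` (suffixed
until unique) with SBML shadowing respected: the reaction's own law is
rewritten to the lifted id, other laws are untouched. Lifting is
idempotent.

## Canonical naming

Species are numbered `x1 … xn` in document order; parameters `k1 … km`
with globals first (document order), then compartments, then lifted
locals in reaction order. The `time` csymbol becomes the reserved symbol
`t` (internally a private symbol, so a model that declares an entity
called `t` cannot capture it). All tie-breaks are document order, so two
runs on the same file produce byte-identical output.

## Compartment-size division

SBML kinetic laws yield substance-amount rates; the assembled equations
govern concentrations, so each reaction term is divided by the species'
compartment size — as an exact rational value, a no-op for size-1
compartments. Species flagged `hasOnlySubstanceUnits` are left undivided
(their state *is* an amount). The division can be switched off
(`compartment_division=False`, CLI `--no-compartment-division`) for users
who want raw amount rates. A compartment without a declared size is taken
as size 1.

## Conservation laws

`S_dyn` restricts `S` to dynamic species: boundary, constant,
assignment-rule **and rate-rule** species are excluded — a rate-rule
species does not follow `S·v`, so including its row would produce
"conservation laws" the assembled dynamics violate. The left kernel is
computed by exact reduced row echelon form over `Fraction`s (the kernel
identity `yᵀ S_dyn = 0` holds identically, not within a tolerance);
each vector is scaled to a primitive integer vector with positive leading
entry, giving a canonical, diff-stable output. A best-effort pass replaces
mixed-sign vectors by nonnegative combinations `±v + c·w` (c ≤ 3) when one
exists; a guaranteed nonnegative basis would require extreme-ray
computation, which is out of scope. Totals are exact dot products with the
initial values when all are known, otherwise fresh symbolic constants
`c1, c2, …`.

The rank needed for the completeness identity (basis size =
n_dyn − rank) is computed by fraction-free Bareiss elimination on an
integer scaling of the matrix — exact at every step and without the
coefficient blow-up of naive fraction arithmetic. sympy's own rational
elimination serves as an independent oracle in the tests, never as the
implementation.

## Complexes, linkage classes, deficiency

Complexes are the distinct reactant- and product-side compositions,
compared as exact maps: `2A` and `A` are different complexes; the empty
composition (inflow/outflow) is a complex like any other. Each reaction
contributes one arrow, plus the reverse arrow when marked reversible.
Linkage classes are connected components of the undirected complex graph.
The deficiency is `δ = c − ℓ − s` with `s = rank(S)`; it is nonnegative by
theorem, and the implementation asserts this on every computation.
Whether a reversible reaction counts as one reaction or two is immaterial
for `c`, `ℓ`, `s` (the reverse arrow connects already-connected complexes
and spans coincide); the tests verify this invariance explicitly.

## Kinetics classification

The vector field is *polynomial* when every `f_i` is polynomial in
`(x, t)` and rational overall (coefficients may be rational functions of
`k`), *rational* when every `f_i` is a ratio of such polynomials, *other*
otherwise (e.g. `exp` of a state variable, piecewise expressions).
Constraints are classified the same way.

The mass-action test forms, for each reaction, the quotient of its law by
the mass-action monomial `Π x_i^Kin[i,j]` and cancels over the
rational-function field. The reaction passes when the result is free of
species symbols and of `t` — "constant factor" deliberately admits
parameters, compartment sizes and rationals. Failure to cancel counts as
not mass-action: the heuristic errs toward rejection. The model-level
flag is the conjunction of the per-reaction flags *and* a polynomial
vector field, so `mass_action ⇒ polynomial` holds by construction. Note
that a reversible reaction encoded as a single net law `kf·Πx_r − kr·Πx_p`
fails the quotient test; this is the intended conservative behaviour.

## Synthetic-model generator

The generator emits SBML Level 3 Version 2 documents whose ground truth
is known by construction: stoichiometries are the ones the reactions were
assembled from; a mass-action label is true because the law was written
as `k·Πx^a` from that stoichiometry; Michaelis–Menten laws have the shape
`V·x/(K + x)`. Quantities not immediate from construction (rank,
conservation span, complex/linkage counts) are computed inside the
generator by a deliberately simple independent path — sympy's elimination
and a hand-rolled union-find — never by the pipeline under test.

Default conditions: 4 species, 3 reactions, mass-action kinetics,
irreversible reactions, no boundary species, no rules. Rate constants and
initial concentrations are drawn as fractions `p/q` with `p ≤ 9` and `q ∈
{1, 2, 4, 5, 10}` so their decimal XML attributes are exact. One
compartment of size 1 is used, which keeps amount and concentration rates
identical and makes the floating-point faithfulness comparison
assumption-free.

What the generator does **not** emulate: the size distribution of curated
model repositories (hundreds of species), annotation layers, unit
systems, multi-compartment transport, events, or delay terms. Passing
tests therefore demonstrate correctness of the conversion semantics on
networks of this structural family, not performance or coverage on a
full curated corpus.

## Verification problem sizes

The property suites run the full pipeline on the five named toys plus
seeded random networks: 200 networks (≤ 6 species, ≤ 6 reactions) for the
deficiency oracle, 100 for conservation laws, 100 for classification, and
50 × 10 random rational evaluation points for floating-point
faithfulness (tolerance 10⁻⁹ relative per component; observed errors are
at machine precision, ~10⁻¹⁵). `scripts/acceptance.py` re-runs all of
these from scratch with a user-supplied seed.

## Numerical and degenerate-input choices

- Duplicate species references in one reaction sum their stoichiometries.
- A model with zero reactions yields `S` with zero columns, an empty
  complex set, zero linkage classes, deficiency 0, and one conservation
  law per dynamic species.
- Division by a size-zero compartment, value-dependency cycles, and
  recursive function definitions are hard errors, not warnings.
- Export rendering is deterministic; the manifest's `generated` field is
  left null unless a timestamp is supplied, so renders are byte-stable.

## Known limitations

- No SBML writing, no `comp`/`fbc`/`layout` packages, no unit analysis.
- Algebraic rules and events are rejected rather than approximated.
- The nonnegativity preference for conservation vectors is heuristic.
- Piecewise kinetic laws parse and classify as "other" but are not
  otherwise analyzed.
- Mathematica/Matlab dialects are not implemented; the exporter registry
  is the extension point.
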