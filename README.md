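# odelift

**odelift** turns SBML reaction-network models into exact symbolic ODE
systems ready for computer algebra.

Most SBML tooling targets numerical simulation: kinetic laws are compiled
to floating-point code, numbers carry representation error, and species
keep whatever free-form identifiers the modeller chose. Symbolic methods
from chemical reaction network theory — steady-state variety analysis,
multistationarity tests, model reduction, deficiency-based structure
theorems — need something different: polynomials and rational functions
over **exact rational numbers**, canonical variable names, and explicit
structural objects (stoichiometric matrix, conservation laws, complexes).
odelift produces exactly that, for anyone who wants to feed curated
systems-biology models into Maple, Reduce, SageMath, or their own
computer-algebra pipeline.

## What it computes

For a network with species concentrations *x₁ … xₙ*, parameters
*k₁ … kₘ* and reaction rate laws *v₁ … v_r*:

- **ODEs** `dxᵢ/dt = fᵢ(x, k, t) = Σⱼ Sᵢⱼ vⱼ(x, k, t)` with every constant
  an exact rational (the decimal text `0.1` becomes `1/10`, never a binary
  double). Boundary-condition species are pinned (`fᵢ = 0`), rate-rule
  species take the rule's expression, and assignment-rule species are
  eliminated into formal constraints.
- **Stoichiometric matrix** `S` (net change, products − reactants) and
  **kinetic matrix** (reactant-side kinetic orders), both over ℚ.
- **Linear conservation laws**: a primitive-integer basis of
  `{y : yᵀ S_dyn = 0}`, each giving `Σ yᵢ xᵢ = const`, with the constant
  evaluated exactly from initial values when they are known.
- **Deficiency** `δ = c − ℓ − s` (complexes, linkage classes, rank) from
  chemical reaction network theory, computed with exact arithmetic.
- **Classification**: is the vector field polynomial / rational / other in
  the state, and does every rate law differ from mass-action kinetics only
  by a factor free of species and time (a conservative mass-action test)?
- **Name map**: a bijection between SBML ids and the canonical `x`/`k`
  names, so results can be translated back.

Models using SBML events, parameter rate rules, algebraic rules,
non-constant compartments, or irrational constant values (e.g. a parameter
set to `exp(1)`) are rejected with an itemized report — exactness cannot
be guaranteed for them.

## Worked example

The package ships a generator of small SBML models with known structure.
Convert the bundled Michaelis–Menten toy and render it for Maple:

```python
from odelift.fixtures import named_toys
from odelift import convert, render

sbml, _ = named_toys()["mm"]          # one reaction S -> P, law V*S/(K+S)
dataset = convert(sbml, source="mm")
print(render(dataset, "maple").text)
```

This prints:

```
# odelift dataset for model 'mm' (Maple)
# name map (mathematical name = SBML id):
#   x1 = S
#   x2 = P
#   k1 = V
#   k2 = K
#   k3 = cell
vars := [x1, x2]:
f_x1 := -k1*x1/(k2 + x1):
f_x2 := k1*x1/(k2 + x1):
params := [k1 = 3/2, k2 = 2, k3 = 1]:
initials := [x1 = 5, x2 = 0]:
constraints := [x1 + x2 = 5]:
S := Matrix([[-1], [1]]):
Kin := Matrix([[1], [0]]):
n_complexes := 2:
n_linkage_classes := 1:
rank_S := 1:
deficiency := 0:
vector_field_class := "rational":
mass_action := false:
```

Reading the output: the substrate/product pair became `x1`, `x2`; the two
kinetic parameters and the compartment size became `k1`–`k3` with their
exact values; `x1 + x2 = 5` is the conservation law found in the left
kernel of `S`, with the total evaluated from the initial concentrations
(5 + 0); the network has two complexes in one linkage class with rank 1,
hence deficiency 0; and the vector field is rational but not polynomial,
so the model is not mass-action.

The same dataset renders to Reduce, SageMath and LaTeX (`render(dataset,
"sagemath")`, …), and `parse_sagemath_export` reads the SageMath text back
for round-trip verification.

### Command line

```sh
odelift convert model.xml --out results -f maple,latex
odelift fixtures toys --out toys
odelift fixtures generate --spec '{"n_species": 5, "n_reactions": 4, "seed": 7}'
```

`convert` exits 0 on success (one file per dialect plus a JSON manifest),
1 on a missing/unreadable input, and 2 for an unsupported model, writing
`<name>.rejection.json` with the violation list.

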