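# Methods

## Model and assumptions

A metabolic network is a pair (S, bounds): S ∈ ℝ^{m×n} is the stoichiometric
matrix over the m *internal* metabolites (external species impose no balance
row), and each reaction j carries flux bounds v_min,j ≤ v_j ≤ v_max,j. The
sign convention is negative = consumed, positive = produced. The network
objective τ is linear, cᵀv, and flux balance analysis (FBA) maximizes it over
the polyhedron P = { v : S v = 0, v_min ≤ v ≤ v_max }. Fluxes are treated as
dimensionless rates (mmol·gDW⁻¹·h⁻¹ by convention); no unit conversions are
performed.

Mass conservation is enforced through the mass matrix M, whose entry (k, l)
counts atoms of element k in the sum formula of internal metabolite l. An
internal reaction is chemically admissible iff its stoichiometric column lies
in ker M. Formulas are plain Hill-style strings (no isotopes, no
parentheses); charge is stored and can be appended as an optional
pseudo-element row of M, but is off by default because models routinely
write bare protons. Metabolites without formulas are allowed but can never
enter a mass-balance-constrained computation.

Thermodynamic feasibility of a net conversion r uses standard-condition
Gibbs formation energies only (T, kJ/mol): Tᵀ r ≤ 0 in the direction the
conversion is written. No concentration correction (transformed energies) is
applied, and the inequality is weak — a conversion at equilibrium is
admitted.

## The capacitance MILP

The search for the best admissible addition is

max cᵀv  over (v, ρ, x) subject to S v + ρ = 0; M ρ = 0; Tᵀ ρ ≤ 0;
−λ x_i ≤ ρ_i ≤ λ x_i with x_i binary; Σ x_i ≤ μ; x_i = 0 outside the allowed
set E; v within its bounds.

The bilinear pair (stoichiometry r, flux w) is replaced by the flux-scaled
net production ρ = w·r. Every condition on r is invariant under positive
scaling, so constraining ρ is equivalent; λ is simultaneously the big-M
constant and the per-metabolite bound on the scaled flux through the
addition. ρ = 0 is always feasible, so the solved optimum never falls below
the plain FBA optimum, and μ = 0 reduces the problem to FBA exactly.

Tunable parameters:

| parameter | default | meaning |
|---|---|---|
| μ | 4 | maximum support size of the conversion (genome-scale screening setting; the packaged worked example uses 6) |
| λ | 1000 | bound on the flux-scaled net production per metabolite, flux units; reported optima and percentage increases depend on it |
| E | all annotated internal metabolites | allowed support (e.g. one compartment) |
| thermo | auto | Gibbs constraint on; enabled whenever any ΔG_f annotation is present |
| support_tol | 1e-6 | threshold for reading off the support from ρ |

Optima are rarely unique, so the solve is staged lexicographically for
deterministic output: (1) maximize cᵀv, (2) minimize Σ x_i at that optimum,
(3) minimize Σ|ρ_i| via epigraph variables. A consequence worth knowing: on
the packaged worked example the minimum-support stage prefers a
five-metabolite alternative over the six-metabolite glyoxylate-shunt sum;
both achieve the same objective, and the shunt sum is recovered by the
unit-coefficient enumeration oracle. Alternatives are enumerated by no-good
cuts Σ_{i∈support} x_i ≤ |support| − 1, which also exclude supersets of
already-seen supports; enumeration stops at a configurable count or when the
optimum drops below a fraction (default 0.999) of the first.

### Integerization

The solver returns ρ in floats; the reported stoichiometry must be an exact
integer vector. Entrywise continued-fraction rounding is unsafe here: the
L1-minimal ρ may mix several kernel directions, and rounding a mixture
entrywise need not stay balanced. Instead the exact rational kernel basis of
M restricted to the support columns is computed (sympy), ρ is expressed in
that basis by least squares, the *coordinates* are rationalized (continued
fractions, denominator cap 10⁴), and the integer vector is reassembled — in
ker M by construction — then gcd-reduced to coprime coefficients with the
sign fixed to the exergonic direction. If no small rational kernel member
matches ρ within relative 1e-5, the raw vector is reported unconverted and
flagged. The standalone `integerize` helper keeps the plain per-entry
algorithm for vectors without kernel structure.

## Flux analyses

Blocked reactions are those with max |v_i| = 0 over P (two LPs per
reaction). Flux variability minimizes/maximizes each flux over
P ∩ { cᵀv ≥ γ·τ* }; γ is exposed (γ = 1 is the definition of "all optimal
flux distributions", smaller values are a numerical safety valve on large
models). Classification at γ = 1 with tolerance 1e-6: *excluded* if the
range is {0}, *indispensable* if the range excludes 0, else *variable*.
When τ* = 0 the optimal face is all of P and classification coincides with
the blocked-reaction analysis; this case is exercised by the packaged
fixture, whose baseline optimum is exactly zero.

A reaction is *essential* for τ when forcing v_i = 0 collapses the optimum
to 0; equivalently there is α^i > 0 with cᵀv ≤ α^i v_i on P. The tightest
α^i = sup { cᵀv / v_i } is a linear-fractional program solved by
Charnes–Cooper transformation, computed only on demand. The essential
reactions give the bound τ* ≤ min_i α^i·v_max,i; the bound is reported as
+∞ when an essential reaction has an unbounded upper flux bound, and
equality holds when every essential reaction attains its upper bound in some
optimal flux distribution (tested on models where this is known by
construction).

## Decomposition over known reactions

A conversion r is a net conversion of a reaction database when
A α + B β = r and C β = 0, with A the columns touching only internal
metabolites and [B; C] the columns involving m′ additional species (rows C).
C β = 0 forces the additional species to be strict intermediates — the only
reading under which the combination's *net* conversion equals r.
Irreversible columns constrain their coefficient ≥ 0. The default solution
minimizes Σ|α| + Σ|β| (positive/negative splitting); an exact
minimum-support MILP refinement is available behind a flag. Infeasibility is
certified by a Farkas vector y (yᵀ·column ≤ 0 on usable columns, yᵀ r > 0),
computed by an auxiliary LP with box-normalized y. Directional energies of
used columns are checked against T/T′ and reported as violations by
default; a flag turns the check into a hard sign restriction. Feasible
results are re-verified in exact rational arithmetic (coefficients snapped
by continued fractions), which yields residuals of exactly 0 on integer
inputs.

## Numerical choices

* Solver: HiGHS via scipy.optimize (`linprog`, `milp`), MIP gap 0,
  deterministic default settings; one process, repeated runs give identical
  output.
* Feasibility tolerance is the solver's (~1e-9); classification and support
  tolerances 1e-6; oracle-agreement comparisons at 1e-6.
* Stage-2/3 re-solves keep the objective within 1e-7·max(1, |τ|) of the
  stage-1 optimum.
* Degenerate inputs: empty objective, infeasible or unbounded LPs are
  reported as statuses, not exceptions, at the FBA level; the MILP raises
  only on genuine solver failure (ρ = 0 keeps it feasible); the brute-force
  oracle refuses instances beyond 10⁷ candidates.

## The packaged fixture

`krebs_fixture()` is a 24-metabolite, 22-reaction reconstruction of human
glycolysis/gluconeogenesis plus the Krebs cycle: the eight cycle reactions,
PEP carboxykinase, a lumped (reversible) gluconeogenesis/glycolysis step
from PEP, lumped respiration and phosphorylation steps, an ATP maintenance
drain, and exchanges for acetyl-CoA (uptake ≤ 10), CoA, glucose, CO₂, O₂,
water and phosphate. The objective is glucose export. Sum formulas are
neutral protonated species with the NAD(H)/FAD(H₂) two-hydrogen convention
so redox reactions balance without explicit protons; every internal reaction
is elementally balanced (tested). The six Gibbs formation energies carried
by the model (acetyl-CoA, CoA, isocitrate, malate, succinate, water) are
synthetic reconstructions assembled from standard biochemistry references to
be internally consistent — chosen once so that known reaction directions
come out right (the glyoxylate-shunt sum is exergonic by ≈ −71 kJ/mol,
matching the sign and order of magnitude of the real enzyme pair) — and are
not transcriptions of any published table.

## The synthetic generator

Random networks are used where the method must be validated against
exhaustive enumeration. Elemental balance is guaranteed by construction:
every formula is a positive combination a·X + b·Y of two random building
blocks, so ker M is exactly the set of conversions conserving the block
coordinates, and reactions are sampled as small integer kernel vectors
(coefficients capped, default 3, keeping brute-force enumeration
tractable). Each network carries a 4-reaction backbone from an
uptake-limited substrate (default bound 5) to an exported product — so the
objective optimum is positive and known — plus random decoy conversions
over random metabolite triples, ~30% of them reversible. Gibbs energies are
linear in the block coordinates plus per-metabolite offsets; the linear part
cancels on every balanced conversion, so reaction energies equal offset
differences, which are ordered to make the backbone exergonic forward
(otherwise the thermodynamic constraint would make recovery tests vacuous).
Planted instances remove one backbone reaction (alternating a 2-metabolite
isomerization and a 3-metabolite condensation by seed parity) and re-roll
the draw when decoys happen to bypass the gap.

What the generator does *not* emulate: realistic compound chemistry, the
degree distribution of genome-scale networks, cofactor coupling, or
compartments. Passing the recovery and oracle tests therefore demonstrates
correctness of the optimization machinery on balanced networks of this
scale, not predictive performance on real reconstructions — for those, the
SBML path plus per-model annotations is the intended route.

## Problem sizes and scope

The shipped analyses run on desk-sized instances: the 22-reaction fixture,
10-metabolite synthetic networks, 20-instance batches for the agreement and
recovery rates, and brute-force enumeration up to (2·2+1)⁶ candidate
conversions. Published genome-scale models (BiGG-style SBML) are accepted
inputs for the same pipeline — screening there is bounded by MILP time
limits (config-exposed, with explicit suboptimality flagging) — but no
external model files are packaged, and percentage yield increases on such
models depend on the choice of λ and so are reported, never asserted.

## Known limitations

* Standard-condition thermodynamics only; a conversion infeasible at
  physiological concentrations can pass, and vice versa.
* λ is a modelling choice with no canonical value; percent increases are
  only meaningful alongside it.
* The no-good cut excludes supersets of found supports, so a larger support
  achieving the same optimum may never be enumerated (visible on the worked
  example; the enumeration oracle covers the gap at small scale).
* Shadow prices of the balance rows are exposed for environmental
  sensitivity analysis, but no environment-relaxation design procedure is
  built on them.
* FVA classification near the 1e-6 flux tolerance can shift boundary cases
  on large models.
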