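# stoichcap

Constraint-based metabolic models answer "how much can this network make?"
by linear programming: flux balance analysis (FBA) maximizes a linear
objective cᵀv over the steady-state polyhedron
P = { v : S v = 0, v_min ≤ v ≤ v_max }, where S is the stoichiometric matrix
over the internal metabolites. `stoichcap` answers the next question: **what
is the best single chemically feasible reaction — catalogued or not — that
you could add to the network to raise that optimum, and what would it do to
the rest of the system?** The answer is the network's *stoichiometric
capacitance*, a tool for metabolic engineers screening for synthetic
interventions and for judging how far a network sits below its theoretical
capacity.

## The method

A stoichiometric capacitance is a sparse net conversion r ∈ ℝᵐ of internal
metabolites such that adding it as a reaction raises the FBA optimum
τ* = max { cᵀv : v ∈ P }. Feasibility of r as a *chemical reaction* is
imposed structurally:

* **elemental balance** — M r = 0, where M is the mass matrix of atomic
  counts (elements × internal metabolites), so no atoms appear or vanish;
* **thermodynamic feasibility** — Tᵀ r ≤ 0, where T holds standard Gibbs
  free energies of formation (kJ/mol), so the conversion is exergonic;
* **sparsity** — |I(r)| ≤ μ nonzero entries, with support restricted to an
  allowed metabolite set E (e.g. one compartment).

Carrying both a stoichiometry r and a flux w through the added reaction is
bilinear, so the search optimizes the flux-scaled net production ρ = w·r
directly in one mixed-integer linear program:

```
max  c^T v
s.t. S v + ρ = 0
     M ρ = 0,   T^T ρ ≤ 0
     −λ x_i ≤ ρ_i ≤ λ x_i,   x_i ∈ {0,1},   Σ x_i ≤ μ,   x_i = 0 for i ∉ E
     v_min ≤ v ≤ v_max
```

All constraints on r are invariant under positive scaling, so they apply to
ρ verbatim; λ bounds the scaled flux through the addition. The reported
stoichiometry is the exact integerization of ρ (coprime coefficients,
written in the exergonic direction). Alternative optima are enumerated with
no-good cuts on the support, and any capacitance can be tested for
expressibility as a combination of known enzymatic reactions by the
decomposition LP ``A α + B β = r, C β = 0`` over a reaction database whose
columns are split into internal-only (A) and externally coupled ([B; C])
blocks. The system-wide effect is quantified by flux variability analysis:
each reaction is classified excluded / indispensable / variable from its
flux range over the optimal face, with and without the capacitance.

All LPs and MILPs are solved with HiGHS through SciPy; SBML I/O goes through
cobrapy; everything else is implemented here.

## Worked example: glucose from fatty acids

Fatty-acid degradation feeds acetyl-CoA into the Krebs cycle, but both
acetyl carbons are lost as CO₂ before oxaloacetate is regenerated, so the
cycle alone cannot support net gluconeogenesis. The packaged
glycolysis/gluconeogenesis + Krebs-cycle model reproduces this, and the
capacitance search restricted to six metabolites finds the fix:

```python
from stoichcap import (
    CapacitanceConfig, KREBS_CAPACITANCE_METABOLITES, brute_force_capacitance,
    build_database, decompose, find_capacitance, krebs_fixture,
    krebs_reaction_database, render_equation, solve_fba,
)

model = krebs_fixture()
print(solve_fba(model).tau_star)          # 0.0   — no glucose synthesis possible

config = CapacitanceConfig(mu=6, allowed_set=KREBS_CAPACITANCE_METABOLITES)
cap = find_capacitance(model, config)
print(cap.tau_star_r)                     # 2.5   — glucose export with the capacitance
print(render_equation(cap.r_int))         # 3 accoa + 2 h2o + icit = 3 coa + 3 succ

shunt = brute_force_capacitance(model, config, coeff_range=1)
print(render_equation(shunt.r_int))       # accoa + h2o + icit = coa + mal + succ
print(round(shunt.delta_g, 1))            # -71.3 kJ/mol

extra, reactions = krebs_reaction_database()
result = decompose(shunt.r_int, build_database(reactions, model, extra))
print(result.beta)                        # {'ICL': 1.0, 'MAS': 1.0}
```

The optimum is not unique: the MILP's deterministic tie-break (smallest
support, then smallest |ρ|) returns a five-metabolite alternative, while the
unit-coefficient enumeration recovers the classic glyoxylate-shunt sum
`accoa + h2o + icit = coa + mal + succ` — exactly isocitrate lyase (ICL)
plus malate synthase (MAS), the two enzymes whose addition is known to
enable gluconeogenesis from acetyl units. The decomposition confirms it with
coefficients (1, 1) and exact cancellation of the glyoxylate intermediate.

A CLI mirrors the library (`stoichcap fba|fva|essential|capacitance|
decompose|compare|synth|pipeline`); see `stoichcap --help`.

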