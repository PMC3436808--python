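"""Packaged toy model: glycolysis/gluconeogenesis + Krebs cycle.

The classic biochemical question behind this fixture: can glucose be
synthesized from fatty acids using only the Krebs cycle? Acetyl-CoA (the
product of fatty-acid beta-oxidation) enters the cycle by condensing with
oxaloacetate, but both acetyl carbons are lost as CO2 before oxaloacetate is
regenerated, so the cycle sustains no net gluconeogenic drain — FBA on this
model with a glucose-synthesis objective returns exactly 0. Adding the net
conversion of the glyoxylate shunt (isocitrate lyase + malate synthase,
AcCoA + Isocit + H2O -> CoA + Mal + Succ) bypasses both decarboxylations and
makes net glucose synthesis feasible.

All internal reactions are elementally balanced. Sum formulas are neutral
(fully protonated) species, with the nicotinamide/flavin cofactor convention
NAD(H) differing by two hydrogens, so that redox reactions balance without
explicit protons. Formulas and the six Gibbs formation energies carried by
the model are SYNTHETIC reconstructions from standard biochemistry
references, chosen to be internally consistent (in particular the
glyoxylate-shunt net conversion is exergonic by ~70 kJ/mol, the sign and
order of magnitude of the real reaction sum); they are not transcriptions of
any published model file.
"""

from __future__ import annotations

from .formulas import parse_formula
from .io import parse_equation
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["krebs_fixture", "krebs_reaction_database", "KREBS_CAPACITANCE_METABOLITES"]

#: The six metabolites the worked example restricts the capacitance to.
KREBS_CAPACITANCE_METABOLITES = frozenset({"accoa", "coa", "icit", "mal", "succ", "h2o"})

_FORMULAS = {
    "accoa": "C23H38N7O17P3S",
    "coa": "C21H36N7O16P3S",
    "oaa": "C4H4O5",
    "cit": "C6H8O7",
    "icit": "C6H8O7",
    "akg": "C5H6O5",
    "succoa": "C25H40N7O19P3S",
    "succ": "C4H6O4",
    "fum": "C4H4O4",
    "mal": "C4H6O5",
    "pep": "C3H5O6P",
    "glc": "C6H12O6",
    "h2o": "H2O",
    "co2": "CO2",
    "o2": "O2",
    "pi": "H3O4P",
    "nad": "C21H27N7O14P2",
    "nadh": "C21H29N7O14P2",
    "fad": "C27H33N9O15P2",
    "fadh2": "C27H35N9O15P2",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "gtp": "C10H16N5O14P3",
    "gdp": "C10H15N5O11P2",
}

_NAMES = {
    "accoa": "acetyl-CoA",
    "coa": "coenzyme A",
    "oaa": "oxaloacetate",
    "cit": "citrate",
    "icit": "isocitrate",
    "akg": "2-oxoglutarate",
    "succoa": "succinyl-CoA",
    "succ": "succinate",
    "fum": "fumarate",
    "mal": "(S)-malate",
    "pep": "phosphoenolpyruvate",
    "glc": "D-glucose",
    "h2o": "water",
}

# Synthetic standard Gibbs formation energies (kJ/mol) for the six metabolites
# the capacitance search is restricted to; chosen so known reaction energies
# come out with the right sign (glyoxylate-shunt sum ~ -71 kJ/mol).
_GIBBS = {
    "accoa": -60.0,
    "coa": -35.0,
    "icit": -959.6,
    "mal": -682.9,
    "succ": -530.6,
    "h2o": -157.6,
}

_BIG = 1000.0

# id, equation, lb, ub
_INTERNAL_REACTIONS = [
    ("CS", "accoa + oaa + h2o = cit + coa", 0.0, _BIG),
    ("ACONT", "cit = icit", -_BIG, _BIG),
    ("ICDH", "icit + nad = akg + co2 + nadh", 0.0, _BIG),
    ("AKGDH", "akg + nad + coa = succoa + co2 + nadh", 0.0, _BIG),
    ("SUCOAS", "succoa + adp + pi = succ + atp + coa", -_BIG, _BIG),
    ("SUCD", "succ + fad = fum + fadh2", 0.0, _BIG),
    ("FUM", "fum + h2o = mal", -_BIG, _BIG),
    ("MDH", "mal + nad = oaa + nadh", -_BIG, _BIG),
    ("PEPCK", "oaa + gtp = pep + co2 + gdp", 0.0, _BIG),
    # lumped gluconeogenesis from PEP (reverse = glycolysis to PEP)
    ("GNG", "2 pep + 2 atp + 2 nadh + 4 h2o = glc + 2 adp + 2 nad + 4 pi", -_BIG, _BIG),
    ("RESP_NADH", "2 nadh + o2 = 2 nad + 2 h2o", 0.0, _BIG),
    ("RESP_FADH2", "2 fadh2 + o2 = 2 fad + 2 h2o", 0.0, _BIG),
    ("ATPS", "adp + pi = atp + h2o", 0.0, _BIG),
    ("GTPS", "gdp + pi = gtp + h2o", 0.0, _BIG),
    ("ATPM", "atp + h2o = adp + pi", 0.0, _BIG),  # maintenance: lets the cycle run without gluconeogenesis
]

# exchanges: met, lb, ub (positive flux = export)
_EXCHANGES = [
    ("accoa", -10.0, 0.0),  # acetyl-CoA supplied by fatty-acid degradation
    ("coa", 0.0, _BIG),
    ("glc", 0.0, _BIG),
    ("co2", 0.0, _BIG),
    ("o2", -_BIG, 0.0),
    ("h2o", -_BIG, _BIG),
    ("pi", -_BIG, _BIG),
]


def krebs_fixture() -> MetabolicModel:
    """Build the packaged Krebs-cycle/gluconeogenesis model.

    Objective: glucose export ("synthesis of glucose"). Acetyl-CoA uptake is
    capped at 10 flux units; free CoA leaves the system (fatty-acid
    re-activation is outside the boundary). The baseline FBA optimum is 0.
    """
    metabolites = [
        Metabolite(
            id=mid,
            name=_NAMES.get(mid, mid),
            compartment="c",
            is_internal=True,
            formula=parse_formula(formula),
            gibbs_formation=_GIBBS.get(mid),
        )
        for mid, formula in _FORMULAS.items()
    ]
    known = set(_FORMULAS)
    reactions = [
        Reaction(rid, parse_equation(eq, known), lb, ub)
        for rid, eq, lb, ub in _INTERNAL_REACTIONS
    ]
    reactions += [
        Reaction(f"EX_{mid}", {mid: -1.0}, lb, ub, is_boundary=True)
        for mid, lb, ub in _EXCHANGES
    ]
    return MetabolicModel(metabolites, reactions, {"EX_glc": 1.0}, name="krebs_core")


def krebs_reaction_database() -> tuple[list[Metabolite], list[Reaction]]:
    """The two glyoxylate-shunt reactions, as a tiny known-reaction database.

    Glyoxylate is a metabolite outside the fixture's internal set, so both
    reactions couple to one additional species:

    * ICL (isocitrate lyase):  icit = succ + gly
    * MAS (malate synthase):   accoa + gly + h2o = coa + mal

    Their sum is the glyoxylate-shunt net conversion — the stoichiometric
    capacitance of the worked example.
    """
    extra = [
        Metabolite(
            id="gly",
            name="glyoxylate",
            compartment="c",
            is_internal=False,
            formula=parse_formula("C2H2O3"),
        )
    ]
    known = set(_FORMULAS) | {"gly"}
    reactions = [
        Reaction("ICL", parse_equation("icit = succ + gly", known), 0.0, _BIG),
        Reaction("MAS", parse_equation("accoa + gly + h2o = coa + mal", known), 0.0, _BIG),
    ]
    return extra, reactions
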