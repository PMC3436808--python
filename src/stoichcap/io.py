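"""Readers and writers: SBML (through cobrapy), a tabular toy dialect, ΔG_f tables.

The toy dialect stores a model as a directory of three UTF-8 files:

* ``model.json`` — name and the objective (reaction id → coefficient),
* ``metabolites.tsv`` — columns ``id name compartment internal formula charge
  gibbs_formation`` (empty field = absent),
* ``reactions.tsv`` — columns ``id equation lower_bound upper_bound boundary``,
  with the equation written ``"2 A + B = C"`` (``=`` is the reaction arrow,
  left side consumed, right side produced).

Round-trip ``load_toy_model(write_toy_model(m))`` reproduces S, bounds and
objective exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

from .formulas import parse_formula, hill_formula
from .model import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "parse_equation",
    "render_equation",
    "load_toy_model",
    "write_toy_model",
    "load_gibbs_table",
    "apply_gibbs_table",
    "load_sbml",
    "write_sbml",
]

_MET_COLUMNS = ["id", "name", "compartment", "internal", "formula", "charge", "gibbs_formation"]
_RXN_COLUMNS = ["id", "equation", "lower_bound", "upper_bound", "boundary"]


def parse_equation(text: str, known_metabolites: set[str] | None = None) -> dict[str, float]:
    """Parse ``"2 A + B = C"`` into a stoichiometry map {A: -2, B: -1, C: +1}.

    Metabolite tokens may carry trailing underscores from table typography
    (``N_2_`` → ``N2``). With ``known_metabolites`` given, any id outside the
    set raises a :class:`ModelError` naming it.
    """
    if text.count("=") != 1:
        raise ModelError(f"equation must contain exactly one '=': {text!r}")
    left, right = text.split("=")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        if not side.strip():  # boundary reactions may have an empty side
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelError(f"empty term in equation {text!r}")
            pieces = term.split()
            if len(pieces) == 1:
                coef, met = 1.0, pieces[0]
            elif len(pieces) == 2:
                try:
                    coef = float(pieces[0])
                except ValueError:
                    raise ModelError(f"bad coefficient {pieces[0]!r} in {text!r}") from None
                met = pieces[1]
            else:
                raise ModelError(f"cannot parse term {term!r} in {text!r}")
            met = met.replace("_", "")
            if coef <= 0:
                raise ModelError(f"non-positive coefficient in term {term!r}")
            if known_metabolites is not None and met not in known_metabolites:
                raise ModelError(f"equation references undeclared metabolite {met!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {m: c for m, c in stoich.items() if c != 0}


def _coef_str(value: float) -> str:
    if math.isclose(value, round(value)) and abs(value) < 1e15:
        value = int(round(value))
        return "" if value == 1 else f"{value} "
    return f"{value:g} "


def render_equation(stoich: Mapping[str, float]) -> str:
    """Render a stoichiometry map in the ``6 H2O + 2 nac = 2 glycogen + N2`` style.

    Reactants (negative coefficients) left of ``=``, products right, each side
    sorted by metabolite id; unit coefficients are omitted.
    """
    key = lambda item: (item[0].lower(), item[0])  # noqa: E731 - case-insensitive id order
    reactants = sorted(((m, -c) for m, c in stoich.items() if c < 0), key=key)
    products = sorted(((m, c) for m, c in stoich.items() if c > 0), key=key)

    def side(terms: list[tuple[str, float]]) -> str:
        return " + ".join(f"{_coef_str(c)}{m}" for m, c in terms)

    return f"{side(reactants)} = {side(products)}"


# --------------------------------------------------------------------- toy I/O
def write_toy_model(model: MetabolicModel, path: str | Path) -> Path:
    """Write a model in the toy dialect; returns the directory path."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    met_rows = []
    for met in model.metabolites.values():
        met_rows.append(
            {
                "id": met.id,
                "name": met.name,
                "compartment": met.compartment,
                "internal": int(met.is_internal),
                "formula": hill_formula(met.formula) if met.formula is not None else "",
                "charge": "" if met.charge is None else met.charge,
                "gibbs_formation": ""
                if met.gibbs_formation is None
                else repr(met.gibbs_formation),
            }
        )
    pd.DataFrame(met_rows, columns=_MET_COLUMNS).to_csv(
        root / "metabolites.tsv", sep="\t", index=False
    )
    rxn_rows = []
    for rxn in model.reactions.values():
        rxn_rows.append(
            {
                "id": rxn.id,
                "equation": render_equation(rxn.stoich),
                "lower_bound": repr(rxn.lower_bound),
                "upper_bound": repr(rxn.upper_bound),
                "boundary": int(rxn.is_boundary),
            }
        )
    pd.DataFrame(rxn_rows, columns=_RXN_COLUMNS).to_csv(
        root / "reactions.tsv", sep="\t", index=False
    )
    (root / "model.json").write_text(
        json.dumps({"name": model.name, "objective": model.objective}, indent=2),
        encoding="utf-8",
    )
    return root


def load_toy_model(path: str | Path) -> MetabolicModel:
    """Read a toy-dialect model directory back into a :class:`MetabolicModel`."""
    root = Path(path)
    header = json.loads((root / "model.json").read_text(encoding="utf-8"))
    mets = pd.read_csv(root / "metabolites.tsv", sep="\t", dtype=str, keep_default_na=False)
    metabolites = []
    for row in mets.itertuples(index=False):
        metabolites.append(
            Metabolite(
                id=row.id,
                name=row.name,
                compartment=row.compartment,
                is_internal=bool(int(row.internal)),
                formula=parse_formula(row.formula) if row.formula else None,
                charge=int(row.charge) if row.charge else None,
                gibbs_formation=float(row.gibbs_formation) if row.gibbs_formation else None,
            )
        )
    known = {m.id for m in metabolites}
    rxns = pd.read_csv(root / "reactions.tsv", sep="\t", dtype=str, keep_default_na=False)
    reactions = []
    for row in rxns.itertuples(index=False):
        reactions.append(
            Reaction(
                id=row.id,
                stoich=parse_equation(row.equation, known),
                lower_bound=float(row.lower_bound),
                upper_bound=float(row.upper_bound),
                is_boundary=bool(int(row.boundary)),
            )
        )
    return MetabolicModel(metabolites, reactions, header.get("objective", {}), header.get("name", ""))


# -------------------------------------------------------------------- ΔG table
def load_gibbs_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (metabolite id, ΔG_f in kJ/mol)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["id", "gibbs"])
    return {str(row.id): float(row.gibbs) for row in df.itertuples(index=False)}


def apply_gibbs_table(model: MetabolicModel, table: Mapping[str, float]) -> MetabolicModel:
    """Return a copy of the model with ΔG_f annotations merged in."""
    from dataclasses import replace

    metabolites = [
        replace(m, gibbs_formation=table.get(m.id, m.gibbs_formation))
        for m in model.metabolites.values()
    ]
    return MetabolicModel(
        metabolites, list(model.reactions.values()), dict(model.objective), model.name
    )


# ------------------------------------------------------------------------ SBML
def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    """Write a (small) model as SBML Level 3 + fbc through cobrapy.

    Intended for toy and synthetic models; Gibbs formation energies are not
    part of SBML-fbc and travel separately as a ΔG_f table.
    """
    import cobra

    cmodel = cobra.Model(model.name or "model")
    cmets = {}
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(
            met.id,
            formula=hill_formula(met.formula) if met.formula is not None else None,
            name=met.name,
            compartment=met.compartment or "c",
            charge=met.charge,
        )
        cmets[met.id] = cmet
    reactions = []
    for rxn in model.reactions.values():
        crxn = cobra.Reaction(rxn.id, name=rxn.name)
        crxn.add_metabolites({cmets[mid]: coef for mid, coef in rxn.stoich.items()})
        crxn.bounds = (rxn.lower_bound, rxn.upper_bound)
        reactions.append(crxn)
    cmodel.add_reactions(reactions)
    cmodel.objective = {
        cmodel.reactions.get_by_id(rid): coef for rid, coef in model.objective.items()
    }
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra.io.write_sbml_model(cmodel, str(path))
    return path


def load_sbml(path: str | Path) -> MetabolicModel:
    """Load an SBML (Level 3 + fbc, or Level 2 with bound annotations) model.

    cobrapy handles the SBML parsing; the result is converted to this
    package's container. Boundary species and species in boundary
    compartments are marked external; exchange/demand reactions are flagged
    as boundary reactions. Missing formulas produce a warning (the model
    still loads; formula-less metabolites simply cannot enter mass-balanced
    computations). A model without an objective is rejected.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise ModelError(f"SBML file not found: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # pragma: no cover - cobra error text varies
            raise ModelError(f"could not read SBML file {path}: {exc}") from exc

    objective = {}
    for rxn, coef in cobra.util.solver.linear_reaction_coefficients(cmodel).items():
        objective[rxn.id] = float(coef)
    if not objective:
        raise ModelError(f"SBML model {path} defines no (fbc) objective")

    boundary_ids = {r.id for r in cmodel.boundary}
    metabolites = []
    missing_formula = []
    for met in cmodel.metabolites:
        formula = None
        if met.formula:
            try:
                formula = parse_formula(met.formula)
            except Exception:
                formula = None
        if formula is None:
            missing_formula.append(met.id)
        metabolites.append(
            Metabolite(
                id=met.id,
                name=met.name or "",
                compartment=met.compartment or "",
                is_internal=not getattr(met, "boundary_condition", False),
                formula=formula,
                charge=met.charge if met.charge is not None else None,
            )
        )
    if missing_formula:
        warnings.warn(
            f"{len(missing_formula)} metabolites lack parseable formulas "
            f"(e.g. {missing_formula[:3]}); they are excluded from "
            "mass-balance-constrained computations",
            stacklevel=2,
        )
    reactions = []
    for rxn in cmodel.reactions:
        stoich = {m.id: float(c) for m, c in rxn.metabolites.items() if c != 0}
        if not stoich:
            continue
        reactions.append(
            Reaction(
                id=rxn.id,
                stoich=stoich,
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                is_boundary=rxn.id in boundary_ids,
                name=rxn.name or "",
            )
        )
    return MetabolicModel(metabolites, reactions, objective, cmodel.id or path.stem)
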