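"""Core data model: metabolites, reactions, stoichiometric and mass matrices.

The container mirrors the standard constraint-based formulation. A network
with m internal metabolites and n reactions is described by its
stoichiometric matrix S (rows = internal metabolites only; external species
impose no steady-state balance), per-reaction flux bounds v_min ≤ v ≤ v_max,
and a linear objective vector c. Mass conservation additionally requires
every internal reaction column to lie in the kernel of the mass matrix M,
whose entry (k, l) is the count of chemical element k in the sum formula of
internal metabolite l.

Sign convention throughout: negative stoichiometric coefficient = consumed,
positive = produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .formulas import ElementVector

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MassMatrix",
    "ModelError",
    "IncompleteAnnotationError",
    "build_mass_matrix",
    "check_reaction_mass_balance",
]


class ModelError(ValueError):
    """Structural problem in a metabolic model."""


class IncompleteAnnotationError(ModelError):
    """A computation needed formulas (or ΔG_f) that the model does not carry."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.

    ``is_internal`` species impose a steady-state balance row; external
    species (outside the system boundary) do not. ``gibbs_formation`` is the
    standard Gibbs free energy of formation in kJ/mol, used for the
    thermodynamic feasibility constraint on net conversions.
    """

    id: str
    name: str = ""
    compartment: str = ""
    is_internal: bool = True
    formula: Optional[ElementVector] = None
    charge: Optional[int] = None
    gibbs_formation: Optional[float] = None


@dataclass(frozen=True)
class Reaction:
    """A (possibly boundary) reaction with flux bounds.

    ``stoich`` maps metabolite id → coefficient; zero coefficients are never
    stored. Boundary reactions (exchanges/demands) cross the system boundary
    and are exempt from elemental balance.
    """

    id: str
    stoich: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    is_boundary: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if any(coef == 0 for coef in self.stoich.values()):
            raise ModelError(f"reaction {self.id!r} stores a zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoich", dict(self.stoich))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MassMatrix:
    """Atomic-count matrix M: rows = element symbols, columns = internal metabolites."""

    elements: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    matrix: np.ndarray  # integer dtype, shape (len(elements), len(metabolite_ids))

    def column(self, metabolite_id: str) -> np.ndarray:
        return self.matrix[:, self.metabolite_ids.index(metabolite_id)]


class MetabolicModel:
    """An ordered collection of metabolites and reactions with a linear objective.

    The objective maps reaction id → coefficient (the vector c of the FBA
    problem ``max c^T v`` subject to ``S v = 0`` and the flux bounds).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective: Mapping[str, float] | None = None,
        name: str = "",
    ):
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id!r}")
            for met_id in rxn.stoich:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            self.reactions[rxn.id] = rxn
        self.objective: dict[str, float] = dict(objective or {})
        for rxn_id in self.objective:
            if rxn_id not in self.reactions:
                raise ModelError(f"objective references unknown reaction {rxn_id!r}")
        self.name = name

    # ------------------------------------------------------------------ views
    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.metabolites)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(self.reactions)

    @property
    def internal_metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites.values() if m.is_internal)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """S with one row per internal metabolite, one column per reaction."""
        rows = {mid: i for i, mid in enumerate(self.internal_metabolite_ids)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coef in rxn.stoich.items():
                i = rows.get(met_id)
                if i is not None:
                    S[i, j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    def objective_array(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, rxn_id in enumerate(self.reactions):
            c[j] = self.objective.get(rxn_id, 0.0)
        return c

    def gibbs_vector(self) -> dict[str, float]:
        """ΔG_f per internal metabolite, only where annotated."""
        return {
            m.id: m.gibbs_formation
            for m in self.metabolites.values()
            if m.is_internal and m.gibbs_formation is not None
        }

    # ------------------------------------------------------------- modification
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolites.values()),
            list(self.reactions.values()),
            dict(self.objective),
            self.name,
        )

    def with_reaction(self, reaction: Reaction) -> "MetabolicModel":
        """Return a copy with one reaction added (the original is unchanged)."""
        return MetabolicModel(
            list(self.metabolites.values()),
            list(self.reactions.values()) + [reaction],
            dict(self.objective),
            self.name,
        )

    def with_bounds(self, reaction_id: str, lower: float, upper: float) -> "MetabolicModel":
        reactions = [
            replace(r, lower_bound=lower, upper_bound=upper) if r.id == reaction_id else r
            for r in self.reactions.values()
        ]
        return MetabolicModel(
            list(self.metabolites.values()), reactions, dict(self.objective), self.name
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.name!r}: {len(self.metabolites)} metabolites "
            f"({len(self.internal_metabolite_ids)} internal), "
            f"{len(self.reactions)} reactions>"
        )


def build_mass_matrix(
    model: MetabolicModel, include_charge: bool = False
) -> MassMatrix:
    """Assemble M: one row per element occurring in any internal metabolite.

    Every internal metabolite must carry a formula; offenders are listed in
    the raised :class:`IncompleteAnnotationError`. With ``include_charge``,
    an extra pseudo-element row ``charge`` is appended (off by default:
    reactions written with bare protons would otherwise fail the check).
    """
    internal = [model.metabolites[mid] for mid in model.internal_metabolite_ids]
    missing = [m.id for m in internal if m.formula is None]
    if missing:
        raise IncompleteAnnotationError(
            f"internal metabolites without formulas: {', '.join(missing)}"
        )
    elements = sorted({el for m in internal for el in m.formula})
    rows = list(elements)
    if include_charge:
        rows.append("charge")
    M = np.zeros((len(rows), len(internal)), dtype=np.int64)
    for l, met in enumerate(internal):
        for k, el in enumerate(elements):
            M[k, l] = met.formula.get(el, 0)
        if include_charge:
            M[-1, l] = met.charge or 0
    return MassMatrix(tuple(rows), tuple(m.id for m in internal), M)


def check_reaction_mass_balance(
    model: MetabolicModel, reaction_id: str
) -> dict[str, float]:
    """Per-element residual of one reaction; all-zero residuals = balanced.

    The residual of element e is ``Σ_i stoich_i · formula_i[e]`` over every
    metabolite of the reaction (internal or not — a reaction crossing into
    annotated external species can still be checked). Metabolites without a
    formula raise :class:`IncompleteAnnotationError`.
    """
    if reaction_id not in model.reactions:
        raise ModelError(f"unknown reaction {reaction_id!r}")
    rxn = model.reactions[reaction_id]
    missing = [
        mid for mid in rxn.stoich if model.metabolites[mid].formula is None
    ]
    if missing:
        raise IncompleteAnnotationError(
            f"reaction {reaction_id!r}: metabolites without formulas: "
            f"{', '.join(missing)}"
        )
    residual: dict[str, float] = {}
    for mid, coef in rxn.stoich.items():
        for el, count in model.metabolites[mid].formula.items():
            residual[el] = residual.get(el, 0.0) + coef * count
    return {
        el: val
        for el, val in residual.items()
        if not math.isclose(val, 0.0, abs_tol=1e-9)
    }


def balance_violations(model: MetabolicModel) -> dict[str, dict[str, float]]:
    """Map reaction id → nonzero residuals, for every internal formula-complete reaction.

    Boundary reactions and reactions touching formula-less metabolites are
    skipped (the latter cannot be checked, by design they are also barred
    from mass-balance-constrained computations).
    """
    violations: dict[str, dict[str, float]] = {}
    for rxn in model.reactions.values():
        if rxn.is_boundary:
            continue
        if any(model.metabolites[mid].formula is None for mid in rxn.stoich):
            continue
        residual = check_reaction_mass_balance(model, rxn.id)
        if residual:
            violations[rxn.id] = residual
    return violations
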