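"""Random element-balanced networks and planted-gap instances.

The generator guarantees elemental balance by construction: every metabolite
formula is a positive integer combination a*X + b*Y of two random building
blocks (X carbon-bearing, Y nitrogen-bearing), so the mass matrix has rank 2
and its kernel is exactly the set of conversions conserving the block
coordinates (a, b). Reactions are sampled as small integer kernel vectors:
a backbone pathway substrate -> intermediates -> product (so the network has
a nonzero objective optimum), plus random decoy conversions over random
metabolite triples.

Gibbs formation energies are assigned as a linear function of the block
coordinates plus a per-metabolite offset. The linear part cancels on every
balanced conversion, so a reaction's standard energy equals the offset
difference — which the generator orders along the backbone to make the
planted reaction exergonic in its forward direction (otherwise the
thermodynamic constraint would make recovery tests vacuous).

Planted instances remove one backbone reaction whose loss provably lowers
the optimum; the capacitance search over its metabolites must then restore
the objective (not necessarily with the identical support — balanced
alternatives may exist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import sympy

from .flux_analysis import solve_fba
from .formulas import ElementVector
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticSpec",
    "PlantedInstance",
    "SyntheticError",
    "random_balanced_network",
    "plant_capacitance_instance",
]

_BIG = 1000.0


class SyntheticError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    """Generator parameters (seed is mandatory; same seed = identical model)."""

    seed: int
    n_internal: int = 10
    n_reactions: int = 10
    element_alphabet: tuple[str, ...] = ("C", "H", "O", "N")
    max_coeff: int = 3
    uptake_bound: float = 5.0
    plant_gap: bool = False

    def __post_init__(self) -> None:
        if self.n_internal < 5:
            raise ValueError("n_internal must be >= 5 (backbone needs 5 metabolites)")
        if self.max_coeff < 1:
            raise ValueError("max_coeff must be >= 1")


@dataclass
class PlantedInstance:
    model: MetabolicModel  # network with the key reaction removed
    truth: dict[str, int]  # net conversion of the removed reaction
    full_tau: float  # optimum of the unbroken network
    broken_tau: float  # optimum after removal (strictly smaller)
    removed_id: str = ""


_BACKBONE = ("sub", "int1", "int2", "byp", "prod")


def _blocks(rng: np.random.Generator, alphabet: Sequence[str]) -> tuple[dict, dict]:
    """Two random building-block element vectors; X carbonaceous, Y nitrogenous."""
    x = {"C": int(rng.integers(1, 3)), "H": int(rng.integers(1, 5)), "O": int(rng.integers(0, 3))}
    y = {"N": 1, "H": int(rng.integers(0, 4)), "O": int(rng.integers(0, 2))}
    x = {el: c for el, c in x.items() if c and el in alphabet}
    y = {el: c for el, c in y.items() if c and el in alphabet}
    if not x:
        x = {alphabet[0]: 1}
    if not y:
        y = {alphabet[-1]: 1}
    return x, y


def _formula(x: dict, y: dict, a: int, b: int) -> ElementVector:
    counts: dict[str, int] = {}
    for el, c in x.items():
        counts[el] = counts.get(el, 0) + a * c
    for el, c in y.items():
        counts[el] = counts.get(el, 0) + b * c
    return ElementVector(counts)


def _integer_kernel_vector(
    coords: np.ndarray, rng: np.random.Generator, max_coeff: int
) -> Optional[np.ndarray]:
    """A small nonzero integer vector in the kernel of a 2 x k coordinate matrix."""
    mat = sympy.Matrix(coords.astype(int))
    basis = mat.nullspace()
    if not basis:
        return None
    vecs = []
    for v in basis:
        denominators = [term.q for term in v]
        scaled = v * math.lcm(*denominators)
        ints = np.array([int(t) for t in scaled], dtype=np.int64)
        g = math.gcd(*(abs(int(t)) for t in ints if t)) or 1
        vecs.append(ints // g)
    for _ in range(20):
        weights = rng.integers(-1, 2, size=len(vecs))
        combo = sum(int(w) * v for w, v in zip(weights, vecs))
        combo = np.asarray(combo, dtype=np.int64)
        if np.any(combo) and np.max(np.abs(combo)) <= max_coeff:
            g = math.gcd(*(abs(int(t)) for t in combo if t)) or 1
            return combo // g
    return None


def random_balanced_network(spec: SyntheticSpec) -> MetabolicModel:
    """Generate a model whose every internal reaction is elementally balanced.

    Layout: a 4-reaction backbone

        B1: sub -> int1 + byp
        B2: int1 -> int2          (isomerization; the default planted gap)
        B3: int2 + byp -> prod
        B4: 2 int1 -> alt         (a dead-end branch metabolite)

    with substrate uptake bounded by ``uptake_bound``, product export as the
    objective, plus ``n_reactions - 4`` random decoy conversions sampled from
    the mass-matrix kernel over random metabolite triples.
    """
    rng = np.random.default_rng(spec.seed)
    x, y = _blocks(rng, spec.element_alphabet)

    # backbone coordinates: sub = int1 + byp; int2 isomer of int1; prod = int2 + byp
    coords: dict[str, tuple[int, int]] = {}
    int1 = (int(rng.integers(1, 3)), int(rng.integers(0, 2)))
    byp = (int(rng.integers(1, 3)), int(rng.integers(0, 2)))
    coords["sub"] = (int1[0] + byp[0], int1[1] + byp[1])
    coords["int1"] = int1
    coords["int2"] = int1
    coords["byp"] = byp
    coords["prod"] = coords["sub"]
    coords["alt"] = (2 * int1[0], 2 * int1[1])
    n_extra = max(0, spec.n_internal - len(coords))
    extra_ids = [f"x{i}" for i in range(n_extra)]
    for mid in extra_ids:
        coords[mid] = (int(rng.integers(1, 4)), int(rng.integers(0, 3)))

    # Gibbs offsets: linear part cancels on balanced conversions, so reaction
    # energies equal offset differences; backbone offsets descend.
    gx, gy = -40.0, -25.0
    offsets = {mid: float(rng.uniform(-5, 5)) for mid in coords}
    offsets["sub"] = float(rng.uniform(5, 10))
    offsets["int1"] = offsets["sub"] - float(rng.uniform(1, 5))
    offsets["byp"] = -float(rng.uniform(1, 5))
    offsets["int2"] = offsets["int1"] - float(rng.uniform(1, 5))
    offsets["prod"] = offsets["int2"] + offsets["byp"] - float(rng.uniform(1, 5))
    offsets["alt"] = 2 * offsets["int1"] - float(rng.uniform(1, 5))

    metabolites = [
        Metabolite(
            id=mid,
            name=mid,
            compartment="c",
            is_internal=True,
            formula=_formula(x, y, a, b),
            gibbs_formation=a * gx + b * gy + offsets[mid],
        )
        for mid, (a, b) in coords.items()
    ]

    reactions = [
        Reaction("B1", {"sub": -1, "int1": 1, "byp": 1}, 0.0, _BIG),
        Reaction("B2", {"int1": -1, "int2": 1}, 0.0, _BIG),
        Reaction("B3", {"int2": -1, "byp": -1, "prod": 1}, 0.0, _BIG),
        Reaction("B4", {"int1": -2, "alt": 1}, 0.0, _BIG),
    ]
    all_ids = list(coords)
    coord_mat = np.array([[coords[m][0] for m in all_ids], [coords[m][1] for m in all_ids]])
    n_decoys = max(0, spec.n_reactions - len(reactions))
    attempts = 0
    while n_decoys > 0 and attempts < 50 * spec.n_reactions:
        attempts += 1
        triple = rng.choice(len(all_ids), size=min(3, len(all_ids)), replace=False)
        vec = _integer_kernel_vector(coord_mat[:, triple], rng, spec.max_coeff)
        if vec is None:
            continue
        stoich = {all_ids[j]: int(c) for j, c in zip(triple, vec) if c}
        if len(stoich) < 2:
            continue
        rid = f"D{len(reactions) - 3}"
        reversible = bool(rng.random() < 0.3)
        reactions.append(Reaction(rid, stoich, -_BIG if reversible else 0.0, _BIG))
        n_decoys -= 1

    reactions += [
        Reaction("EX_sub", {"sub": -1.0}, -spec.uptake_bound, 0.0, is_boundary=True),
        Reaction("EX_prod", {"prod": -1.0}, 0.0, _BIG, is_boundary=True),
        Reaction("EX_alt", {"alt": -1.0}, 0.0, _BIG, is_boundary=True),
    ]
    return MetabolicModel(
        metabolites, reactions, {"EX_prod": 1.0}, name=f"synthetic-{spec.seed}"
    )


def plant_capacitance_instance(
    spec: SyntheticSpec, max_tries: int = 25
) -> PlantedInstance:
    """Remove one backbone reaction and record its conversion as ground truth.

    Alternates between the isomerization B2 (2-metabolite truth) and the
    condensation B3 (3-metabolite truth) by seed parity. The instance is only
    returned once its invariants hold: the unbroken optimum is positive, the
    removal strictly lowers it (decoys may otherwise provide a bypass — such
    draws are re-rolled with a shifted seed), and re-adding the truth
    restores the optimum.
    """
    removed = "B2" if spec.seed % 2 == 0 else "B3"
    last_reason = ""
    for trial in range(max_tries):
        shifted = SyntheticSpec(
            seed=int(spec.seed + 7919 * trial) % (2**31),
            n_internal=spec.n_internal,
            n_reactions=spec.n_reactions,
            element_alphabet=spec.element_alphabet,
            max_coeff=spec.max_coeff,
            uptake_bound=spec.uptake_bound,
            plant_gap=True,
        )
        model = random_balanced_network(shifted)
        full = solve_fba(model)
        if not full.optimal or full.tau_star <= 1e-6:
            last_reason = "unbroken network has zero optimum"
            continue
        truth = {m: int(c) for m, c in model.reactions[removed].stoich.items()}
        broken = MetabolicModel(
            list(model.metabolites.values()),
            [r for r in model.reactions.values() if r.id != removed],
            dict(model.objective),
            model.name + f"-minus-{removed}",
        )
        broken_fba = solve_fba(broken)
        if not broken_fba.optimal or broken_fba.tau_star >= full.tau_star - 1e-6:
            last_reason = "removal does not lower the optimum (decoy bypass)"
            continue
        restored = solve_fba(
            broken.with_reaction(Reaction(removed, truth, 0.0, _BIG))
        )
        if restored.tau_star < full.tau_star - 1e-6:  # pragma: no cover - sanity
            last_reason = "re-adding the truth did not restore the optimum"
            continue
        return PlantedInstance(
            model=broken,
            truth=truth,
            full_tau=full.tau_star,
            broken_tau=broken_fba.tau_star,
            removed_id=removed,
        )
    raise SyntheticError(
        f"could not construct a planted instance in {max_tries} tries: {last_reason}"
    )
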