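"""Decompose a net conversion over a database of known enzymatic reactions.

A capacitance r (defined over the model's m internal metabolites) is a net
conversion of a reaction set R when there are coefficient vectors alpha, beta
with

    A alpha + B beta = r        (the net conversion equals r)
    C beta = 0                  (additional metabolites strictly cancel)

where A collects the database columns touching only the model's internal
metabolites, and [B; C] the columns involving m' additional metabolites (C
holds their rows). Irreversible database reactions constrain their
coefficient to be nonnegative. The default solution minimizes the L1 norm of
the coefficients (a standard sparsity proxy); infeasibility is certified by a
Farkas vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import (
    IncompleteAnnotationError,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "ReactionDatabase",
    "DecompositionResult",
    "build_database",
    "decompose",
    "verify_decomposition",
]


@dataclass
class ReactionDatabase:
    """Known-reaction stoichiometry split into internal-only and coupled blocks."""

    internal_ids: tuple[str, ...]  # the model's m internal metabolites (row order)
    external_ids: tuple[str, ...]  # m' additional metabolites
    A: np.ndarray  # (m, p)
    B: np.ndarray  # (m, q)
    C: np.ndarray  # (m', q)
    a_meta: tuple[tuple[str, bool], ...]  # (reaction id, reversible) per A column
    b_meta: tuple[tuple[str, bool], ...]  # per [B; C] column
    gibbs_internal: dict[str, float] = field(default_factory=dict)
    gibbs_external: dict[str, float] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.A.shape[1]

    @property
    def q(self) -> int:
        return self.B.shape[1]


@dataclass
class DecompositionResult:
    alpha: dict[str, float]
    beta: dict[str, float]
    feasible: bool
    residual_norm: float
    support: tuple[str, ...]
    certificate: Optional[dict[str, float]] = None  # Farkas dual ray on balance rows
    thermo_violations: tuple[str, ...] = ()


def _column_balance(
    stoich: Mapping[str, float], formulas: Mapping[str, Mapping[str, int]]
) -> dict[str, float]:
    residual: dict[str, float] = {}
    for mid, coef in stoich.items():
        for el, count in formulas[mid].items():
            residual[el] = residual.get(el, 0.0) + coef * count
    return {el: v for el, v in residual.items() if abs(v) > 1e-9}


def build_database(
    reactions: Sequence[Reaction],
    model: MetabolicModel,
    extra_metabolites: Sequence[Metabolite] = (),
    gibbs_external: Mapping[str, float] | None = None,
) -> ReactionDatabase:
    """Partition database reactions into the A and [B; C] blocks.

    ``extra_metabolites`` supplies formulas (and optionally Gibbs energies)
    for species the database reactions use beyond the model's metabolites.
    Every column must be elementally balanced over the extended metabolite
    set; unbalanced or unmapped columns are rejected with a report.
    """
    internal_ids = model.internal_metabolite_ids
    internal_set = set(internal_ids)
    extra = {m.id: m for m in extra_metabolites}
    formulas: dict[str, Mapping[str, int]] = {}
    for mid, met in model.metabolites.items():
        if met.formula is not None:
            formulas[mid] = met.formula
    for mid, met in extra.items():
        if met.formula is not None:
            formulas[mid] = met.formula

    a_cols: list[tuple[str, bool, dict[str, float]]] = []
    b_cols: list[tuple[str, bool, dict[str, float]]] = []
    external_ids: list[str] = []
    for rxn in reactions:
        unmapped = [
            mid
            for mid in rxn.stoich
            if mid not in model.metabolites and mid not in extra
        ]
        if unmapped:
            raise ModelError(
                f"database reaction {rxn.id!r} uses unmapped metabolites: {unmapped}"
            )
        missing = [mid for mid in rxn.stoich if mid not in formulas]
        if missing:
            raise IncompleteAnnotationError(
                f"database reaction {rxn.id!r}: no formulas for {missing}"
            )
        residual = _column_balance(rxn.stoich, formulas)
        if residual:
            raise ModelError(
                f"database reaction {rxn.id!r} is not elementally balanced: {residual}"
            )
        outside = [mid for mid in rxn.stoich if mid not in internal_set]
        if outside:
            for mid in outside:
                if mid not in external_ids:
                    external_ids.append(mid)
            b_cols.append((rxn.id, rxn.reversible, dict(rxn.stoich)))
        else:
            a_cols.append((rxn.id, rxn.reversible, dict(rxn.stoich)))

    m = len(internal_ids)
    row = {mid: i for i, mid in enumerate(internal_ids)}
    ext_row = {mid: i for i, mid in enumerate(external_ids)}
    A = np.zeros((m, len(a_cols)))
    for j, (_, _, stoich) in enumerate(a_cols):
        for mid, coef in stoich.items():
            A[row[mid], j] = coef
    B = np.zeros((m, len(b_cols)))
    C = np.zeros((len(external_ids), len(b_cols)))
    for j, (_, _, stoich) in enumerate(b_cols):
        for mid, coef in stoich.items():
            if mid in row:
                B[row[mid], j] = coef
            else:
                C[ext_row[mid], j] = coef
    gibbs_ext = dict(gibbs_external or {})
    for mid, met in extra.items():
        if met.gibbs_formation is not None:
            gibbs_ext.setdefault(mid, met.gibbs_formation)
    return ReactionDatabase(
        internal_ids=tuple(internal_ids),
        external_ids=tuple(external_ids),
        A=A,
        B=B,
        C=C,
        a_meta=tuple((rid, rev) for rid, rev, _ in a_cols),
        b_meta=tuple((rid, rev) for rid, rev, _ in b_cols),
        gibbs_internal=model.gibbs_vector(),
        gibbs_external=gibbs_ext,
    )


def _farkas_certificate(
    E: np.ndarray, b: np.ndarray, nonneg: np.ndarray
) -> Optional[np.ndarray]:
    """A vector y with y^T E <= 0 (on cone columns), = 0 (on free columns),
    y^T b > 0 — proof that {E z = b, z_nonneg >= 0} is empty."""
    rows, cols = E.shape
    A_ub_rows = []
    A_eq_rows = []
    for j in range(cols):
        if nonneg[j]:
            A_ub_rows.append(E[:, j])
        else:
            A_eq_rows.append(E[:, j])
    res = linprog(
        -b,
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.zeros(len(A_ub_rows)) if A_ub_rows else None,
        A_eq=np.array(A_eq_rows) if A_eq_rows else None,
        b_eq=np.zeros(len(A_eq_rows)) if A_eq_rows else None,
        bounds=[(-1, 1)] * rows,
        method="highs",
    )
    if res.status == 0 and -res.fun > 1e-9:
        return res.x
    return None


def decompose(
    r_int: Mapping[str, float],
    db: ReactionDatabase,
    minimize_support: bool = False,
    enforce_thermo: bool = False,
    tol: float = 1e-8,
) -> DecompositionResult:
    """Express a conversion as a combination of database reactions.

    Solves the feasibility LP with an L1 objective on the coefficients.
    Irreversible columns are restricted to nonnegative coefficients. With
    ``enforce_thermo``, a reversible column whose standard reaction energy is
    strictly positive (negative) is additionally restricted to backward-only
    (forward-only) use; without it, direction-energy violations are only
    reported in ``thermo_violations``. ``minimize_support`` re-solves with an
    exact minimum-support MILP over the L1 solution's value (rarely needed;
    L1 is the standard proxy).
    """
    unknown = set(r_int) - set(db.internal_ids)
    if unknown:
        raise ModelError(
            f"conversion uses metabolites outside the database's internal set: "
            f"{sorted(unknown)}"
        )
    m = len(db.internal_ids)
    r = np.zeros(m)
    for i, mid in enumerate(db.internal_ids):
        r[i] = float(r_int.get(mid, 0.0))

    p, q = db.p, db.q
    E = np.vstack(
        [
            np.hstack([db.A, db.B]),
            np.hstack([np.zeros((db.C.shape[0], p)), db.C]),
        ]
    )
    b = np.concatenate([r, np.zeros(db.C.shape[0])])
    meta = list(db.a_meta) + list(db.b_meta)

    def column_dg(j: int) -> Optional[float]:
        gibbs = {**db.gibbs_internal, **db.gibbs_external}
        ids = list(db.internal_ids) + list(db.external_ids)
        col = E[:, j]
        total = 0.0
        for i, mid in enumerate(ids):
            if col[i] == 0:
                continue
            if mid not in gibbs:
                return None
            total += gibbs[mid] * col[i]
        return total

    lo = np.zeros(p + q)
    hi = np.full(p + q, np.inf)
    for j, (_, reversible) in enumerate(meta):
        if reversible:
            lo[j] = -np.inf
        if enforce_thermo:
            dg = column_dg(j)
            if dg is not None and dg > tol:
                hi[j] = 0.0  # forward use would be endergonic
                if not reversible:
                    hi[j] = 0.0
                    lo[j] = 0.0
            elif dg is not None and dg < -tol and reversible:
                lo[j] = 0.0  # backward use would be endergonic

    nonneg = lo >= 0  # cone columns for the Farkas certificate

    # L1 objective via positive/negative split: z = z+ - z-
    n = p + q
    A_eq = np.hstack([E, -E])
    c = np.ones(2 * n)
    bounds = []
    for j in range(n):
        bounds.append((0, hi[j] if np.isfinite(hi[j]) else None))
    for j in range(n):
        neg_cap = -lo[j] if np.isfinite(lo[j]) else None
        bounds.append((0, neg_cap))
    res = linprog(c, A_eq=A_eq, b_eq=b, bounds=bounds, method="highs")
    if res.status == 2:
        ray = _farkas_certificate(E, b, nonneg)
        cert = None
        if ray is not None:
            ids = list(db.internal_ids) + list(db.external_ids)
            cert = {mid: float(y) for mid, y in zip(ids, ray) if abs(y) > 1e-9}
        return DecompositionResult({}, {}, False, float("nan"), (), certificate=cert)
    if res.status != 0:
        raise ModelError(f"decomposition LP failed: {res.message}")
    z = res.x[:n] - res.x[n:]

    if minimize_support:
        z = _min_support(E, b, lo, hi, z, tol)

    residual = E @ z - b
    alpha = {
        rid: float(z[j]) for j, (rid, _) in enumerate(db.a_meta) if abs(z[j]) > tol
    }
    beta = {
        rid: float(z[p + j])
        for j, (rid, _) in enumerate(db.b_meta)
        if abs(z[p + j]) > tol
    }
    violations = []
    if not enforce_thermo:
        for j, (rid, _) in enumerate(meta):
            if abs(z[j]) <= tol:
                continue
            dg = column_dg(j)
            if dg is not None and np.sign(z[j]) * dg > tol:
                violations.append(rid)
    return DecompositionResult(
        alpha=alpha,
        beta=beta,
        feasible=True,
        residual_norm=float(np.max(np.abs(residual))) if residual.size else 0.0,
        support=tuple(sorted(alpha) + sorted(beta)),
        thermo_violations=tuple(violations),
    )


def _min_support(
    E: np.ndarray,
    b: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    warm: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Exact minimum-support refinement (MILP with big-M indicators)."""
    from scipy.optimize import Bounds, LinearConstraint, milp

    from ._util import silence_native_output

    n = E.shape[1]
    big = max(10.0 * np.max(np.abs(warm)), 10.0)
    # variables: z (n) | y (n) binary
    A_eq = np.hstack([E, np.zeros((E.shape[0], n))])
    rows = []
    for j in range(n):
        row = np.zeros(2 * n)
        row[j] = 1.0
        row[n + j] = -big
        rows.append(row)
        row = np.zeros(2 * n)
        row[j] = -1.0
        row[n + j] = -big
        rows.append(row)
    lb = np.concatenate([np.maximum(lo, -big), np.zeros(n)])
    ub = np.concatenate([np.minimum(hi, big), np.ones(n)])
    obj = np.concatenate([np.zeros(n), np.ones(n)])
    with silence_native_output():
        res = milp(
            c=obj,
            constraints=[
                LinearConstraint(A_eq, b, b),
                LinearConstraint(np.array(rows), -np.inf, 0.0),
            ],
            integrality=np.concatenate([np.zeros(n), np.ones(n)]),
            bounds=Bounds(lb, ub),
            options={"mip_rel_gap": 0.0},
        )
    if res.status == 0 and res.x is not None:
        return res.x[:n]
    return warm


def verify_decomposition(
    r_int: Mapping[str, float],
    db: ReactionDatabase,
    result: DecompositionResult,
    max_denominator: int = 1_000_000,
) -> dict[str, float]:
    """Recompute both residuals, exactly in rationals for integer inputs.

    Coefficients are rationalized by continued fractions before the exact
    matrix products; returns {"net_residual": ..., "internal_residual": ...}
    as the maximum absolute entries of A alpha + B beta - r and C beta.
    """
    if not result.feasible:
        raise ModelError("cannot verify an infeasible decomposition")

    def rat(x: float) -> Fraction:
        return Fraction(x).limit_denominator(max_denominator)

    alpha = {rid: rat(v) for rid, v in result.alpha.items()}
    beta = {rid: rat(v) for rid, v in result.beta.items()}
    net: dict[str, Fraction] = {
        mid: -rat(float(r_int.get(mid, 0.0))) for mid in db.internal_ids
    }
    internal_res: dict[str, Fraction] = {mid: Fraction(0) for mid in db.external_ids}
    for j, (rid, _) in enumerate(db.a_meta):
        coef = alpha.get(rid, Fraction(0))
        if coef:
            for i, mid in enumerate(db.internal_ids):
                if db.A[i, j]:
                    net[mid] += coef * rat(db.A[i, j])
    for j, (rid, _) in enumerate(db.b_meta):
        coef = beta.get(rid, Fraction(0))
        if coef:
            for i, mid in enumerate(db.internal_ids):
                if db.B[i, j]:
                    net[mid] += coef * rat(db.B[i, j])
            for i, mid in enumerate(db.external_ids):
                if db.C[i, j]:
                    internal_res[mid] += coef * rat(db.C[i, j])
    net_residual = max((abs(v) for v in net.values()), default=Fraction(0))
    ext_residual = max((abs(v) for v in internal_res.values()), default=Fraction(0))
    return {
        "net_residual": float(net_residual),
        "internal_residual": float(ext_residual),
    }
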