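"""LP analyses on a metabolic model: FBA, FVA, blocked/essential reactions.

All linear programs go through scipy's HiGHS interface with deterministic
settings. The polyhedron throughout is

    P = { v : S v = 0,  v_min <= v <= v_max }

with S restricted to internal-metabolite rows. FBA maximizes the linear
objective c^T v over P; flux variability minimizes/maximizes each flux over
P intersected with { c^T v >= gamma * tau_star }.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FbaResult",
    "FvaRecord",
    "EssentialityRecord",
    "FluxAnalysisError",
    "solve_fba",
    "detect_blocked",
    "flux_variability",
    "classify_reactions",
    "essential_reactions",
    "tau_upper_bound",
]

#: classification tolerance on flux magnitudes (LP noise floor)
DEFAULT_TOL = 1e-6


class FluxAnalysisError(RuntimeError):
    pass


@dataclass
class FbaResult:
    tau_star: float
    flux: dict[str, float]
    status: str  # optimal | infeasible | unbounded
    duals: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaRecord:
    reaction_id: str
    min_flux: float
    max_flux: float
    at_optimality_fraction: float


@dataclass
class EssentialityRecord:
    reaction_id: str
    is_essential: bool
    alpha: Optional[float] = None  # tightest coupling coefficient c^T v <= alpha * v_i


def _finite(bounds: np.ndarray) -> np.ndarray:
    out = bounds.astype(float).copy()
    return out


def _lp(
    c_max: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
):
    """Maximize c_max^T x; returns (status, value, x, eq_marginals)."""
    res = linprog(
        -c_max,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq if A_eq.size else None,
        b_eq=b_eq if A_eq.size else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 0:
        marginals = res.eqlin.marginals if A_eq.size else np.zeros(0)
        return "optimal", -res.fun, res.x, marginals
    if res.status == 2:
        return "infeasible", np.nan, None, None
    if res.status == 3:
        return "unbounded", np.inf, None, None
    raise FluxAnalysisError(f"LP solver failure: {res.message}")  # pragma: no cover


def solve_fba(model: MetabolicModel) -> FbaResult:
    """Maximize the model objective over P.

    Returns the optimum tau_star, one optimal flux vector, and the dual
    values (shadow prices) of the internal-metabolite balance rows, signed so
    that a positive dual means relaxing that metabolite's balance by one unit
    of free production increases the objective.
    """
    if not model.objective:
        raise FluxAnalysisError("model has an empty objective")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    status, val, x, marginals = _lp(c, S, np.zeros(S.shape[0]), lb, ub)
    if status != "optimal":
        return FbaResult(np.nan if status == "infeasible" else np.inf, {}, status, {})
    flux = dict(zip(model.reaction_ids, map(float, x)))
    duals = {
        mid: float(m) for mid, m in zip(model.internal_metabolite_ids, marginals)
    }
    return FbaResult(float(val) + 0.0, flux, "optimal", duals)  # +0.0 normalizes -0.0


def _range_lp(model: MetabolicModel, extra_ub=None):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S, lb, ub, extra_ub


def flux_variability(
    model: MetabolicModel,
    optimality_fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> list[FvaRecord]:
    """Per-reaction flux range over P ∩ {c^T v >= gamma * tau_star}.

    ``optimality_fraction`` (gamma) = 1 restricts to the optimal face — the
    set of all optimal FBA flux distributions; gamma = 0 makes the objective
    constraint inactive whenever tau_star >= 0 (the blocked-reaction probe).
    """
    if not 0.0 <= optimality_fraction <= 1.0:
        raise ValueError("optimality_fraction must lie in [0, 1]")
    fba = solve_fba(model)
    if not fba.optimal:
        raise FluxAnalysisError(f"FBA did not solve: status {fba.status}")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    # c^T v >= gamma tau*  ->  -c^T v <= -gamma tau*
    A_ub = -c.reshape(1, -1)
    b_ub = np.array([-optimality_fraction * fba.tau_star])
    b_eq = np.zeros(S.shape[0])
    ids = list(reactions) if reactions is not None else list(model.reaction_ids)
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    records = []
    for rid in ids:
        j = index[rid]
        e = np.zeros(len(index))
        e[j] = 1.0
        lo_status, lo, _, _ = _lp(-e, S, b_eq, lb, ub, A_ub, b_ub)
        hi_status, hi, _, _ = _lp(e, S, b_eq, lb, ub, A_ub, b_ub)
        if lo_status == "infeasible" or hi_status == "infeasible":
            raise FluxAnalysisError(f"FVA subproblem infeasible for reaction {rid!r}")
        lo = -lo if lo_status == "optimal" else -np.inf
        hi = hi if hi_status == "optimal" else np.inf
        records.append(FvaRecord(rid, float(lo), float(hi), optimality_fraction))
    return records


def detect_blocked(model: MetabolicModel, tol: float = DEFAULT_TOL) -> set[str]:
    """Reactions unable to carry flux anywhere in P (max |v_i| = 0)."""
    records = flux_variability(model, optimality_fraction=0.0)
    return {
        r.reaction_id
        for r in records
        if abs(r.min_flux) <= tol and abs(r.max_flux) <= tol
    }


def classify_reactions(
    records: Sequence[FvaRecord], tol: float = DEFAULT_TOL
) -> dict[str, str]:
    """Label each reaction from its optimal-face flux range.

    * ``excluded`` — zero flux in every optimal flux distribution,
    * ``indispensable`` — nonzero flux in every optimal flux distribution
      (the range excludes 0),
    * ``variable`` — everything else.
    """
    labels = {}
    for rec in records:
        if abs(rec.min_flux) <= tol and abs(rec.max_flux) <= tol:
            labels[rec.reaction_id] = "excluded"
        elif rec.min_flux - tol > 0 or rec.max_flux + tol < 0:
            labels[rec.reaction_id] = "indispensable"
        else:
            labels[rec.reaction_id] = "variable"
    return labels


def _tightest_alpha(model: MetabolicModel, j: int) -> Optional[float]:
    """sup { c^T v / v_j : v in P, v_j > 0 } by Charnes-Cooper transform.

    Homogenize with t >= 0: maximize c^T u subject to S u = 0, u_j = 1,
    lb*t <= u <= ub*t (each finite bound becomes one inequality row).
    Returns None when the ratio is unbounded or the face {v_j > 0} is empty.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    c = model.objective_array()
    # variables: u (n), t (1)
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    ej = np.zeros((1, n + 1))
    ej[0, j] = 1.0
    A_eq = np.vstack([A_eq, ej])
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = 1.0
    rows = []
    for k in range(n):
        if np.isfinite(lb[k]):  # lb[k]*t - u_k <= 0
            row = np.zeros(n + 1)
            row[k] = -1.0
            row[n] = lb[k]
            rows.append(row)
        if np.isfinite(ub[k]):  # u_k - ub[k]*t <= 0
            row = np.zeros(n + 1)
            row[k] = 1.0
            row[n] = -ub[k]
            rows.append(row)
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.zeros(len(rows)) if rows else None
    cc = np.concatenate([c, [0.0]])
    var_lb = np.full(n + 1, -np.inf)
    var_ub = np.full(n + 1, np.inf)
    var_lb[n] = 0.0
    status, val, _, _ = _lp(cc, A_eq, b_eq, var_lb, var_ub, A_ub, b_ub)
    if status != "optimal":
        return None
    return float(val)


def essential_reactions(
    model: MetabolicModel,
    tol: float = DEFAULT_TOL,
    compute_alpha: bool = False,
) -> list[EssentialityRecord]:
    """Reactions whose flux bounds the objective from above.

    A reaction i is essential for the objective tau when forcing v_i = 0
    collapses the optimum to 0 — equivalently, there is a coupling
    coefficient alpha^i > 0 with c^T v <= alpha^i v_i on P. Blocked reactions
    are never essential. The tightest alpha (a fractional program, solved by
    Charnes-Cooper transformation) is computed only on request.
    """
    fba = solve_fba(model)
    if not fba.optimal or fba.tau_star <= tol:
        raise FluxAnalysisError(
            "essentiality is defined only for models with tau_star > 0"
        )
    blocked = detect_blocked(model, tol)
    records = []
    scale = max(1.0, abs(fba.tau_star))
    for j, rid in enumerate(model.reaction_ids):
        if rid in blocked:
            records.append(EssentialityRecord(rid, False))
            continue
        rxn = model.reactions[rid]
        if rxn.lower_bound > 0 or rxn.upper_bound < 0:
            pinned_tau = None  # flux can never vanish; the reaction is trivially coupled
        else:
            pinned = model.with_bounds(rid, 0.0, 0.0)
            res = solve_fba(pinned)
            pinned_tau = res.tau_star if res.optimal else 0.0
        is_essential = pinned_tau is None or pinned_tau <= tol * scale
        alpha = None
        if is_essential and compute_alpha:
            alpha = _tightest_alpha(model, j)
            if alpha is not None and alpha <= 0:
                alpha = None
        records.append(EssentialityRecord(rid, is_essential, alpha))
    return records


def tau_upper_bound(
    model: MetabolicModel, records: Sequence[EssentialityRecord] | None = None
) -> float:
    """Upper bound on tau_star from the essential reactions.

    Each essential reaction i satisfies c^T v <= alpha^i v_i <= alpha^i
    v_i^max, so tau_star <= min_i alpha^i * v_i^max. The bound is +inf when
    an essential reaction has an unbounded upper flux bound (reported, not
    raised). When every essential reaction attains its upper bound in some
    optimal flux distribution, the bound is tight and equals tau_star.
    """
    if records is None:
        records = essential_reactions(model, compute_alpha=True)
    essentials = [r for r in records if r.is_essential]
    if not essentials:
        raise FluxAnalysisError("no essential reactions: the bound is undefined")
    bound = np.inf
    for rec in essentials:
        vmax = model.reactions[rec.reaction_id].upper_bound
        if not np.isfinite(vmax) or rec.alpha is None:
            continue
        bound = min(bound, rec.alpha * vmax)
    return float(bound)
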