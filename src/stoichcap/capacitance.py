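"""Stoichiometric capacitance: the yield-maximizing synthetic reaction MILP.

A stoichiometric capacitance is a sparse net conversion r of internal
metabolites that is (i) elementally balanced (M r = 0), (ii) thermodynamically
feasible (T^T r <= 0, with T the standard Gibbs formation energies), involves
(iii-iv) at most mu metabolites, (v) only metabolites from an allowed subset
E — and whose addition to the network maximally increases the FBA objective.

Because carrying both a stoichiometry r and a flux w through the added
reaction would make the problem bilinear, the MILP optimizes the flux-scaled
net-production vector rho = w * r directly:

    max  c^T v
    s.t. S v + rho = 0                       (steady state with the addition)
         M rho = 0                           (i)   elemental balance
         T^T rho <= 0                        (ii)  thermodynamic feasibility
         -lam * x_i <= rho_i <= lam * x_i    (iii) big-M support indicators
         sum_i x_i <= mu                     (iv)  sparsity
         x_i = 0 for i not in E              (v)   allowed subset
         v_min <= v <= v_max,  x binary

Conditions (i), (ii) and the support conditions are invariant under positive
scaling of rho, so they constrain the underlying conversion r verbatim; lam
acts as the upper bound on the (per-metabolite scaled) flux through the added
reaction. The reported stoichiometry is the integerization of rho, canonical
up to sign (written in its exergonic direction) with coprime coefficients.

Optima are rarely unique. For deterministic output the solve is staged
lexicographically: maximize c^T v, then minimize the support size sum x_i,
then minimize sum |rho_i|.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from ._util import silence_native_output
from .flux_analysis import solve_fba
from .model import MetabolicModel, Reaction, build_mass_matrix

__all__ = [
    "CapacitanceConfig",
    "Capacitance",
    "CapacitanceError",
    "IntegerizationError",
    "find_capacitance",
    "brute_force_capacitance",
    "integerize",
    "augment_model",
    "enumerate_capacitances",
]


class CapacitanceError(RuntimeError):
    pass


class IntegerizationError(CapacitanceError):
    """No small rational stoichiometry reproduces the solved conversion."""


@dataclass
class CapacitanceConfig:
    """Search parameters.

    mu
        Maximum number of metabolites the conversion may involve (default 4,
        the genome-scale screening setting).
    lam
        Upper bound lambda on the flux-scaled net production of each involved
        metabolite (also the big-M constant). The achieved objective increase
        generally depends on lambda; it is always reported alongside.
    allowed_set
        Metabolite ids the conversion may touch (condition v). None = every
        internal metabolite that carries the required annotations.
    thermo_enabled
        Enforce T^T rho <= 0. None (default) enables it exactly when at least
        one internal metabolite carries a Gibbs formation energy.
    """

    mu: int = 4
    lam: float = 1000.0
    allowed_set: Optional[frozenset[str]] = None
    thermo_enabled: Optional[bool] = None
    support_tol: float = 1e-6
    max_alternatives: int = 5
    min_optimum_fraction: float = 0.999
    time_limit: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.allowed_set is not None:
            self.allowed_set = frozenset(self.allowed_set)


@dataclass
class Capacitance:
    """A solved stoichiometric capacitance.

    ``rho`` is the flux-scaled net conversion the MILP actually added;
    ``r_int`` the canonical integer stoichiometry (coprime coefficients,
    written in the exergonic direction), or None when integerization failed;
    ``delta_g`` the standard reaction energy T^T r_int in kJ/mol (None when
    thermodynamic data were not used).
    """

    rho: dict[str, float]
    r_int: Optional[dict[str, int]]
    support: frozenset[str]
    tau_star_r: float
    baseline_tau: float
    delta_g: Optional[float] = None
    increase_percent: float = 0.0
    suboptimal: bool = False

    @property
    def is_trivial(self) -> bool:
        return not self.support


def _eligible_metabolites(
    model: MetabolicModel, config: CapacitanceConfig
) -> tuple[list[str], bool]:
    """Internal metabolites the conversion may involve, and the thermo flag.

    Metabolites lacking a formula (or, with thermodynamics on, a Gibbs
    formation energy) are forced out of the support, with a warning listing
    them when they were explicitly requested.
    """
    gibbs = model.gibbs_vector()
    thermo = config.thermo_enabled
    if thermo is None:
        thermo = bool(gibbs)
    candidates = list(model.internal_metabolite_ids)
    if config.allowed_set is not None:
        unknown = config.allowed_set - set(candidates)
        if unknown:
            raise CapacitanceError(
                f"allowed_set contains non-internal or unknown metabolites: "
                f"{sorted(unknown)}"
            )
        candidates = [m for m in candidates if m in config.allowed_set]
    dropped = [
        m
        for m in candidates
        if model.metabolites[m].formula is None or (thermo and m not in gibbs)
    ]
    if dropped and config.allowed_set is not None:
        warnings.warn(
            "metabolites excluded from the capacitance support for missing "
            f"formula or Gibbs energy: {dropped}",
            stacklevel=3,
        )
    eligible = [m for m in candidates if m not in dropped]
    return eligible, thermo


def _solve_staged_milp(
    model: MetabolicModel,
    eligible: Sequence[str],
    thermo: bool,
    config: CapacitanceConfig,
    extra_cuts: Sequence[frozenset[str]] = (),
) -> tuple[float, np.ndarray, bool]:
    """Lexicographic MILP solve; returns (tau, rho over eligible, suboptimal)."""
    S = model.stoichiometric_matrix()
    m, n = S.shape
    k = len(eligible)
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    internal_index = {mid: i for i, mid in enumerate(model.internal_metabolite_ids)}

    # variable layout: v (n) | rho (k) | x (k)
    nv = n + 2 * k
    constraints: list[LinearConstraint] = []

    # S v + rho = 0
    A = np.zeros((m, nv))
    A[:, :n] = S
    for col, mid in enumerate(eligible):
        A[internal_index[mid], n + col] = 1.0
    constraints.append(LinearConstraint(A, 0.0, 0.0))

    if k:
        mass = build_mass_matrix(model)
        mass_cols = {mid: mass.metabolite_ids.index(mid) for mid in eligible}
        Mr = np.zeros((mass.matrix.shape[0], nv))
        for col, mid in enumerate(eligible):
            Mr[:, n + col] = mass.matrix[:, mass_cols[mid]]
        constraints.append(LinearConstraint(Mr, 0.0, 0.0))

        if thermo:
            gibbs = model.gibbs_vector()
            t_row = np.zeros((1, nv))
            for col, mid in enumerate(eligible):
                t_row[0, n + col] = gibbs[mid]
            constraints.append(LinearConstraint(t_row, -np.inf, 0.0))

        # |rho_i| <= lam * x_i
        big = np.zeros((2 * k, nv))
        for col in range(k):
            big[col, n + col] = 1.0
            big[col, n + k + col] = -config.lam
            big[k + col, n + col] = -1.0
            big[k + col, n + k + col] = -config.lam
        constraints.append(LinearConstraint(big, -np.inf, 0.0))

        card = np.zeros((1, nv))
        card[0, n + k :] = 1.0
        constraints.append(LinearConstraint(card, -np.inf, float(config.mu)))

        for cut in extra_cuts:
            row = np.zeros((1, nv))
            for col, mid in enumerate(eligible):
                if mid in cut:
                    row[0, n + k + col] = 1.0
            constraints.append(LinearConstraint(row, -np.inf, len(cut) - 1.0))

    var_lb = np.concatenate([lb, -config.lam * np.ones(k), np.zeros(k)])
    var_ub = np.concatenate([ub, config.lam * np.ones(k), np.ones(k)])
    integrality = np.concatenate([np.zeros(n + k), np.ones(k)])

    options: dict = {"mip_rel_gap": 0.0}
    if config.time_limit is not None:
        options["time_limit"] = config.time_limit

    def solve(obj_min: np.ndarray, extra: Sequence[LinearConstraint], nvar: int):
        def widen(lc: LinearConstraint) -> LinearConstraint:
            A = np.asarray(lc.A, dtype=float)
            if A.shape[1] < nvar:
                A = np.hstack([A, np.zeros((A.shape[0], nvar - A.shape[1]))])
            return LinearConstraint(A, lc.lb, lc.ub)

        with silence_native_output():
            res = milp(
                c=obj_min,
                constraints=[widen(lc) for lc in list(constraints) + list(extra)],
                integrality=np.concatenate([integrality, np.zeros(nvar - nv)]),
                bounds=Bounds(
                    np.concatenate([var_lb, np.zeros(nvar - nv)]),
                    np.concatenate([var_ub, np.full(nvar - nv, np.inf)]),
                ),
                options=options,
            )
        return res

    # stage 1: maximize c^T v
    obj1 = np.zeros(nv)
    obj1[:n] = -c
    res1 = solve(obj1, [], nv)
    if res1.status not in (0, 1) or res1.x is None:
        raise CapacitanceError(f"capacitance MILP failed: {res1.message}")
    suboptimal = res1.status == 1  # time limit with incumbent
    tau = float(c @ res1.x[:n])
    if k == 0:
        return tau, np.zeros(0), suboptimal

    slack = 1e-7 * max(1.0, abs(tau))
    row_tau = np.zeros((1, nv))
    row_tau[0, :n] = c
    keep_tau = LinearConstraint(row_tau, tau - slack, np.inf)

    # stage 2: minimize support size at the optimum
    obj2 = np.zeros(nv)
    obj2[n + k :] = 1.0
    res2 = solve(obj2, [keep_tau], nv)
    if res2.status not in (0, 1) or res2.x is None:
        return tau, res1.x[n : n + k], suboptimal
    cardinality = float(np.round(res2.x[n + k :].sum()))
    row_card = np.zeros((1, nv))
    row_card[0, n + k :] = 1.0
    keep_card = LinearConstraint(row_card, -np.inf, cardinality)

    # stage 3: minimize sum |rho| via epigraph variables s_i >= |rho_i|
    nv3 = nv + k
    abs_rows = np.zeros((2 * k, nv3))
    for col in range(k):
        abs_rows[col, n + col] = 1.0
        abs_rows[col, nv + col] = -1.0
        abs_rows[k + col, n + col] = -1.0
        abs_rows[k + col, nv + col] = -1.0
    obj3 = np.zeros(nv3)
    obj3[nv:] = 1.0
    res3 = solve(
        obj3,
        [keep_tau, keep_card, LinearConstraint(abs_rows, -np.inf, 0.0)],
        nv3,
    )
    if res3.status not in (0, 1) or res3.x is None:
        return tau, res2.x[n : n + k], suboptimal
    return tau, res3.x[n : n + k], suboptimal


def _assemble(
    model: MetabolicModel,
    eligible: Sequence[str],
    thermo: bool,
    config: CapacitanceConfig,
    tau: float,
    rho_vec: np.ndarray,
    baseline: float,
    suboptimal: bool = False,
) -> Capacitance:
    rho = {
        mid: float(val)
        for mid, val in zip(eligible, rho_vec)
        if abs(val) > config.support_tol
    }
    support = frozenset(rho)
    r_int: Optional[dict[str, int]] = None
    delta_g: Optional[float] = None
    if support:
        try:
            r_int = _kernel_integerize(model, rho)
        except IntegerizationError:
            warnings.warn(
                "conversion could not be reduced to small integers; reporting "
                "the raw flux-scaled vector only",
                stacklevel=3,
            )
        if r_int is not None:
            _verify_integer_balance(model, r_int)
            gibbs = model.gibbs_vector()
            if all(mid in gibbs for mid in r_int):
                delta_g = float(sum(gibbs[mid] * coef for mid, coef in r_int.items()))
                if thermo and delta_g > 1e-9:  # pragma: no cover - guarded by MILP
                    raise CapacitanceError(
                        f"solver returned an endergonic conversion (dG={delta_g})"
                    )
    if baseline > config.support_tol:
        increase = 100.0 * (tau - baseline) / baseline
    else:
        increase = math.inf if tau > config.support_tol else 0.0
    return Capacitance(
        rho=rho,
        r_int=r_int,
        support=support,
        tau_star_r=tau,
        baseline_tau=baseline,
        delta_g=delta_g,
        increase_percent=increase,
        suboptimal=suboptimal,
    )


def find_capacitance(
    model: MetabolicModel, config: CapacitanceConfig | None = None
) -> Capacitance:
    """Solve the capacitance MILP for one model.

    With mu = 0 or an empty allowed set the MILP collapses to plain FBA
    (rho = 0 is always feasible, so the result is never worse than the
    baseline optimum).
    """
    config = config or CapacitanceConfig()
    baseline = solve_fba(model)
    if not baseline.optimal:
        raise CapacitanceError(f"baseline FBA not solvable: {baseline.status}")
    eligible, thermo = _eligible_metabolites(model, config)
    tau, rho_vec, subopt = _solve_staged_milp(model, eligible, thermo, config)
    return _assemble(model, eligible, thermo, config, tau, rho_vec, baseline.tau_star, subopt)


def enumerate_capacitances(
    model: MetabolicModel, config: CapacitanceConfig | None = None
) -> list[Capacitance]:
    """Alternative capacitances by iterated no-good cuts on the support.

    After each solve, the constraint sum_{i in support} x_i <= |support| - 1
    excludes the found support set, and the MILP is re-solved. Enumeration
    stops at ``max_alternatives``, at a trivial (empty-support) solution, or
    when the optimum drops below ``min_optimum_fraction`` of the first one.
    """
    config = config or CapacitanceConfig()
    baseline = solve_fba(model)
    if not baseline.optimal:
        raise CapacitanceError(f"baseline FBA not solvable: {baseline.status}")
    eligible, thermo = _eligible_metabolites(model, config)
    found: list[Capacitance] = []
    cuts: list[frozenset[str]] = []
    first_tau: Optional[float] = None
    while len(found) < config.max_alternatives:
        tau, rho_vec, subopt = _solve_staged_milp(
            model, eligible, thermo, config, extra_cuts=cuts
        )
        cap = _assemble(
            model, eligible, thermo, config, tau, rho_vec, baseline.tau_star, subopt
        )
        if cap.is_trivial:
            if not found:
                found.append(cap)
            break
        if first_tau is None:
            first_tau = cap.tau_star_r
        elif cap.tau_star_r < config.min_optimum_fraction * first_tau:
            break
        found.append(cap)
        cuts.append(cap.support)
    return found


# ----------------------------------------------------------------- integerize
def integerize(
    rho: Mapping[str, float] | Sequence[float],
    tol: float = 1e-5,
    max_denominator: int = 10_000,
) -> dict[str, int] | list[int]:
    """Smallest integer vector proportional to ``rho``.

    Each entry is rationalized against the largest-magnitude entry by
    continued fractions (denominator cap ``max_denominator``), brought to the
    common denominator and reduced by the gcd. Exact proportionality within
    relative ``tol`` is verified post hoc; failure raises
    :class:`IntegerizationError`.
    """
    keys: Optional[list[str]] = None
    if isinstance(rho, Mapping):
        keys = list(rho)
        values = [float(rho[k]) for k in keys]
    else:
        values = [float(v) for v in rho]
    if not values or not any(abs(v) > 0 for v in values):
        raise IntegerizationError("cannot integerize an all-zero vector")
    scale = max(abs(v) for v in values)
    fractions = [Fraction(v / scale).limit_denominator(max_denominator) for v in values]
    denominator = math.lcm(*(f.denominator for f in fractions))
    ints = [int(f * denominator) for f in fractions]
    g = math.gcd(*(abs(i) for i in ints if i)) or 1
    ints = [i // g for i in ints]
    # post-hoc proportionality check
    norm_rho = sum(abs(v) for v in values)
    norm_int = sum(abs(i) for i in ints)
    s = norm_rho / norm_int
    for v, i in zip(values, ints):
        if abs(v - s * i) > tol * scale * max(1.0, abs(i)):
            raise IntegerizationError(
                f"no rational approximation within tolerance (entry {v} vs {s * i})"
            )
    if keys is not None:
        return {k: i for k, i in zip(keys, ints) if i != 0}
    return ints


def _kernel_integerize(
    model: MetabolicModel, rho: Mapping[str, float], tol: float = 1e-5
) -> dict[str, int]:
    """Integerize a conversion exactly within the mass-matrix kernel.

    The MILP guarantees that rho lies (numerically) in the kernel of the mass
    matrix restricted to its support, but an L1-minimal rho can mix several
    kernel directions, and per-entry rounding of such a mixture need not stay
    balanced. Here the exact rational kernel basis of the support columns is
    computed (sympy), rho is expressed in that basis, the *coordinates* are
    rationalized, and the integer vector is reassembled — elementally balanced
    by construction. Raises :class:`IntegerizationError` when rho is too far
    from every small rational kernel member.
    """
    import sympy

    support = sorted(rho)
    if not support:
        raise IntegerizationError("cannot integerize an all-zero vector")
    mass = build_mass_matrix(model)
    cols = [mass.metabolite_ids.index(mid) for mid in support]
    sub = sympy.Matrix(mass.matrix[:, cols].astype(int))
    basis = sub.nullspace()
    if not basis:
        raise IntegerizationError(
            "conversion support admits no balanced conversion (empty kernel)"
        )
    int_basis = []
    for vec in basis:
        denom = math.lcm(*(term.q for term in vec))
        ints = [int(term * denom) for term in vec]
        g = math.gcd(*(abs(i) for i in ints if i)) or 1
        int_basis.append([i // g for i in ints])
    K = np.array(int_basis, dtype=float).T  # (|support|, kernel_dim)
    target = np.array([rho[mid] for mid in support])
    w, *_ = np.linalg.lstsq(K, target, rcond=None)
    scale = max(abs(v) for v in target)
    if np.max(np.abs(K @ w - target)) > tol * scale:
        raise IntegerizationError("conversion does not lie in the balanced kernel")
    w_frac = [Fraction(float(wi) / scale).limit_denominator(10_000) for wi in w]
    exact = [
        sum(Fraction(int(K[i, j])) * w_frac[j] for j in range(K.shape[1]))
        for i in range(K.shape[0])
    ]
    if all(f == 0 for f in exact):
        raise IntegerizationError("rationalized conversion collapsed to zero")
    denom = math.lcm(*(f.denominator for f in exact))
    ints = [int(f * denom) for f in exact]
    g = math.gcd(*(abs(i) for i in ints if i)) or 1
    ints = [i // g for i in ints]
    # proportionality to rho within tolerance
    norm_int = sum(abs(i) for i in ints)
    s = sum(abs(v) for v in target) / norm_int
    for v, i in zip(target, ints):
        if abs(v - s * i) > max(10 * tol * scale, tol * scale * abs(i)):
            raise IntegerizationError(
                f"no small rational kernel member matches the conversion "
                f"(entry {v} vs {s * i})"
            )
    return {mid: i for mid, i in zip(support, ints) if i != 0}


def _verify_integer_balance(model: MetabolicModel, r_int: Mapping[str, int]) -> None:
    """Exact integer elemental balance of a conversion; raises on violation."""
    residual: dict[str, int] = {}
    for mid, coef in r_int.items():
        met = model.metabolites.get(mid)
        if met is None or met.formula is None:
            raise CapacitanceError(f"metabolite {mid!r} missing or without formula")
        for el, count in met.formula.items():
            residual[el] = residual.get(el, 0) + int(coef) * count
    bad = {el: v for el, v in residual.items() if v != 0}
    if bad:
        raise CapacitanceError(f"conversion not elementally balanced: {bad}")


def augment_model(
    model: MetabolicModel,
    r_int: Mapping[str, int | float],
    flux_bound: float,
    reaction_id: str = "SC",
) -> MetabolicModel:
    """Copy of the model with the conversion added as a forward-only reaction.

    The conversion must be elementally balanced and touch only internal
    metabolites; bounds are [0, flux_bound] — by convention the integer
    stoichiometry is already written in its exergonic direction.
    """
    r = {mid: coef for mid, coef in r_int.items() if coef != 0}
    if not r:
        raise CapacitanceError("refusing to add an empty conversion")
    internal = set(model.internal_metabolite_ids)
    outside = set(r) - internal
    if outside:
        raise CapacitanceError(f"conversion touches non-internal metabolites: {sorted(outside)}")
    _verify_integer_balance(model, {m: int(c) for m, c in r.items()})
    return model.with_reaction(Reaction(reaction_id, r, 0.0, flux_bound))


# ---------------------------------------------------------------- brute force
def brute_force_capacitance(
    model: MetabolicModel,
    config: CapacitanceConfig | None = None,
    coeff_range: int = 2,
    guard: int = 10_000_000,
) -> Capacitance:
    """Exhaustive-enumeration oracle for the capacitance MILP.

    Enumerates every integer conversion with coefficients in
    [-coeff_range, coeff_range] over the eligible metabolites, keeps the
    chemically and thermodynamically feasible ones with support <= mu, scores
    each by augmenting the model (flux bound lambda / max|r_i|, matching the
    per-component rho bound of the MILP) and solving FBA, and returns the
    best. Intended for small instances only; the candidate count is guarded.
    """
    config = config or CapacitanceConfig()
    baseline = solve_fba(model)
    if not baseline.optimal:
        raise CapacitanceError(f"baseline FBA not solvable: {baseline.status}")
    eligible, thermo = _eligible_metabolites(model, config)
    k = len(eligible)
    n_candidates = (2 * coeff_range + 1) ** k
    if n_candidates > guard:
        raise CapacitanceError(
            f"enumeration of {n_candidates} candidates exceeds the guard; "
            "use a smaller allowed set or coefficient range"
        )
    mass = build_mass_matrix(model)
    cols = {mid: mass.metabolite_ids.index(mid) for mid in eligible}
    M = mass.matrix[:, [cols[mid] for mid in eligible]]
    gibbs = model.gibbs_vector()
    t_vec = np.array([gibbs.get(mid, 0.0) for mid in eligible])

    best: tuple[float, int, int] | None = None  # (-tau, support, sum|r|) for min-compare
    best_r: dict[str, int] | None = None
    best_tau = baseline.tau_star
    seen: set[tuple[int, ...]] = set()
    for combo in itertools.product(range(-coeff_range, coeff_range + 1), repeat=k):
        arr = np.array(combo, dtype=np.int64)
        support = int(np.count_nonzero(arr))
        if support == 0 or support > config.mu:
            continue
        g = math.gcd(*(abs(int(v)) for v in combo if v))
        canonical = tuple(int(v) // g for v in combo)
        if canonical in seen:
            continue
        seen.add(canonical)
        arr = np.array(canonical, dtype=np.int64)
        if np.any(M @ arr != 0):
            continue
        if thermo and float(t_vec @ arr) > 1e-9:
            continue
        r = {mid: int(v) for mid, v in zip(eligible, arr) if v}
        flux_bound = config.lam / max(abs(v) for v in r.values())
        tau = solve_fba(augment_model(model, r, flux_bound)).tau_star
        key = (-tau, support, int(np.abs(arr).sum()))
        if tau > best_tau + 1e-9 and (best is None or key < best):
            best, best_r, best_tau = key, r, tau
        elif best is not None and abs(tau - best_tau) <= 1e-9 and key < best:
            best, best_r = key, r
    if best_r is None:
        return Capacitance(
            rho={},
            r_int=None,
            support=frozenset(),
            tau_star_r=baseline.tau_star,
            baseline_tau=baseline.tau_star,
            increase_percent=0.0,
        )
    delta_g = (
        float(sum(gibbs[mid] * coef for mid, coef in best_r.items()))
        if all(mid in gibbs for mid in best_r)
        else None
    )
    if baseline.tau_star > config.support_tol:
        increase = 100.0 * (best_tau - baseline.tau_star) / baseline.tau_star
    else:
        increase = math.inf if best_tau > config.support_tol else 0.0
    return Capacitance(
        rho={m: float(c) for m, c in best_r.items()},
        r_int=best_r,
        support=frozenset(best_r),
        tau_star_r=best_tau,
        baseline_tau=baseline.tau_star,
        delta_g=delta_g,
        increase_percent=increase,
    )
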