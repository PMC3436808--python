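import numpy as np
import pytest

from stoichcap.flux_analysis import (
    FluxAnalysisError,
    classify_reactions,
    detect_blocked,
    essential_reactions,
    flux_variability,
    solve_fba,
    tau_upper_bound,
)
from stoichcap.formulas import parse_formula
from stoichcap.model import MetabolicModel, Metabolite, Reaction
from stoichcap.synthetic import SyntheticSpec, random_balanced_network

from conftest import make_chain


class TestFba:
    def test_chain_optimum_and_duals(self, chain):
        result = solve_fba(chain)
        assert result.optimal
        assert result.tau_star == pytest.approx(5.0)
        assert result.flux["CONV"] == pytest.approx(5.0)
        # one free unit of either intermediate converts to one unit of product
        assert result.duals["A"] == pytest.approx(1.0)
        assert result.duals["B"] == pytest.approx(1.0)

    def test_all_zero_bounds(self):
        model = make_chain(uptake=0.0)
        clamped = MetabolicModel(
            list(model.metabolites.values()),
            [Reaction(r.id, r.stoich, 0.0, 0.0, r.is_boundary) for r in model.reactions.values()],
            dict(model.objective),
        )
        result = solve_fba(clamped)
        assert result.tau_star == pytest.approx(0.0)
        assert all(abs(v) < 1e-9 for v in result.flux.values())

    def test_krebs_glucose_objective_is_zero(self, krebs):
        assert solve_fba(krebs).tau_star == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_hold_at_optimum(self, krebs):
        result = solve_fba(krebs)
        S = krebs.stoichiometric_matrix()
        v = np.array([result.flux[r] for r in krebs.reaction_ids])
        lb, ub = krebs.bounds_arrays()
        assert np.allclose(S @ v, 0, atol=1e-7)
        assert np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)

    def test_infeasible_status(self):
        model = MetabolicModel(
            [Metabolite("A")],
            [Reaction("SRC", {"A": 1.0}, 2.0, 5.0, is_boundary=True)],
            {"SRC": 1.0},
        )
        assert solve_fba(model).status == "infeasible"

    def test_unbounded_status(self):
        model = MetabolicModel(
            [Metabolite("A")],
            [
                Reaction("F", {"A": 1.0}, -np.inf, np.inf),
                Reaction("G", {"A": -1.0}, -np.inf, np.inf),
            ],
            {"F": 1.0},
        )
        assert solve_fba(model).status == "unbounded"

    def test_empty_objective_rejected(self, chain):
        chain = MetabolicModel(
            list(chain.metabolites.values()), list(chain.reactions.values()), {}
        )
        with pytest.raises(FluxAnalysisError):
            solve_fba(chain)


class TestBlocked:
    def test_dead_end_is_blocked(self, chain):
        model = MetabolicModel(
            list(chain.metabolites.values()) + [Metabolite("D", formula=parse_formula("C6H12O6"))],
            list(chain.reactions.values()) + [Reaction("DEAD", {"A": -1, "D": 1}, 0, 1000)],
            dict(chain.objective),
        )
        assert detect_blocked(model) == {"DEAD"}

    def test_active_path_unblocked(self, chain):
        assert detect_blocked(chain) == set()

    def test_matches_per_reaction_probe_on_synthetic(self):
        model = random_balanced_network(SyntheticSpec(seed=5))
        blocked = detect_blocked(model)
        # independent probe: maximize/minimize each flux over the plain polyhedron
        from scipy.optimize import linprog

        S = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        expected = set()
        for j, rid in enumerate(model.reaction_ids):
            e = np.zeros(len(model.reaction_ids))
            e[j] = 1.0
            hi = -linprog(-e, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs").fun
            lo = linprog(e, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=np.column_stack([lb, ub]), method="highs").fun
            if abs(hi) <= 1e-6 and abs(lo) <= 1e-6:
                expected.add(rid)
        assert blocked == expected


class TestFva:
    def test_unique_optimum_pins_all_fluxes(self, chain):
        records = flux_variability(chain, optimality_fraction=1.0)
        for rec in records:
            assert rec.min_flux == pytest.approx(5.0, abs=1e-7)
            assert rec.max_flux == pytest.approx(5.0, abs=1e-7)

    def test_gamma_zero_equals_unconstrained_ranges(self, chain):
        with_constraint = flux_variability(chain, optimality_fraction=0.0)
        for rec in with_constraint:
            assert rec.min_flux == pytest.approx(0.0, abs=1e-7)
            assert rec.max_flux == pytest.approx(5.0, abs=1e-7)

    def test_parallel_duplicate_splits_flux(self, chain):
        model = chain.with_reaction(Reaction("CONV2", {"A": -1, "B": 1}, 0, 1000))
        records = {r.reaction_id: r for r in flux_variability(model, 1.0)}
        for rid in ("CONV", "CONV2"):
            assert records[rid].min_flux == pytest.approx(0.0, abs=1e-7)
            assert records[rid].max_flux == pytest.approx(5.0, abs=1e-7)
        for rid in ("UP", "EXP"):
            assert records[rid].min_flux == pytest.approx(5.0, abs=1e-7)

    def test_optimal_flux_lies_within_ranges(self, krebs):
        result = solve_fba(krebs)
        for rec in flux_variability(krebs, 1.0):
            assert rec.min_flux - 1e-6 <= result.flux[rec.reaction_id] <= rec.max_flux + 1e-6

    def test_invalid_gamma(self, chain):
        with pytest.raises(ValueError):
            flux_variability(chain, optimality_fraction=1.5)


class TestClassification:
    @pytest.mark.parametrize(
        "lo, hi, label",
        [
            (0.0, 0.0, "excluded"),
            (5.0, 5.0, "indispensable"),
            (-4.0, -2.0, "indispensable"),
            (0.0, 5.0, "variable"),
            (-1.0, 1.0, "variable"),
        ],
    )
    def test_labels(self, lo, hi, label):
        from stoichcap.flux_analysis import FvaRecord

        assert classify_reactions([FvaRecord("r", lo, hi, 1.0)])["r"] == label

    def test_partition(self, krebs):
        labels = classify_reactions(flux_variability(krebs, 1.0))
        assert set(labels) == set(krebs.reaction_ids)
        assert set(labels.values()) <= {"excluded", "indispensable", "variable"}


class TestEssentiality:
    def test_chain_all_essential_alpha_one(self, chain):
        records = essential_reactions(chain, compute_alpha=True)
        assert all(r.is_essential for r in records)
        assert all(r.alpha == pytest.approx(1.0) for r in records)

    def test_bypass_removes_essentiality(self, chain):
        model = chain.with_reaction(Reaction("CONV2", {"A": -1, "B": 1}, 0, 1000))
        flags = {r.reaction_id: r.is_essential for r in essential_reactions(model)}
        assert flags == {"UP": True, "CONV": False, "CONV2": False, "EXP": True}

    def test_matches_zero_forcing_oracle_on_synthetic(self):
        model = random_balanced_network(SyntheticSpec(seed=21))
        base = solve_fba(model).tau_star
        assert base > 0
        records = {r.reaction_id: r.is_essential for r in essential_reactions(model)}
        blocked = detect_blocked(model)
        for rid in model.reaction_ids:
            if rid in blocked:
                assert not records[rid]
                continue
            pinned = solve_fba(model.with_bounds(rid, 0.0, 0.0))
            expected = (not pinned.optimal) or pinned.tau_star <= 1e-6 * max(1, base)
            assert records[rid] == expected, rid

    def test_requires_positive_optimum(self, krebs):
        with pytest.raises(FluxAnalysisError):
            essential_reactions(krebs)


class TestTauUpperBound:
    def test_chain_bound_is_tight(self, chain):
        records = essential_reactions(chain, compute_alpha=True)
        bound = tau_upper_bound(chain, records)
        assert bound == pytest.approx(solve_fba(chain).tau_star)

    def test_alpha_two_arithmetic(self):
        # A -> 2 B doubles the objective per unit of uptake; uptake capped at 3
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("UP", {"A": 1}, 0, 3, is_boundary=True),
            Reaction("DOUBLE", {"A": -1, "B": 2}, 0, 1000),
            Reaction("EXP", {"B": -1}, 0, 1000, is_boundary=True),
        ]
        model = MetabolicModel(mets, rxns, {"EXP": 1.0})
        records = {r.reaction_id: r for r in essential_reactions(model, compute_alpha=True)}
        assert records["UP"].alpha == pytest.approx(2.0)
        assert tau_upper_bound(model, list(records.values())) == pytest.approx(6.0)
        assert solve_fba(model).tau_star == pytest.approx(6.0)

    def test_bound_never_below_optimum_on_synthetic(self):
        for seed in (2, 9, 33):
            model = random_balanced_network(SyntheticSpec(seed=seed))
            tau = solve_fba(model).tau_star
            if tau <= 1e-6:
                continue
            records = essential_reactions(model, compute_alpha=True)
            if not any(r.is_essential for r in records):
                continue
            assert tau_upper_bound(model, records) >= tau - 1e-6


class TestMonotonicity:
    def test_relaxing_bounds_never_decreases_optimum(self):
        rng = np.random.default_rng(0)
        for seed in (1, 4, 7):
            model = random_balanced_network(SyntheticSpec(seed=seed))
            tau = solve_fba(model).tau_star
            relaxed = model
            for rid in rng.choice(model.reaction_ids, size=3, replace=False):
                rxn = model.reactions[rid]
                relaxed = relaxed.with_bounds(
                    rid, rxn.lower_bound - 5.0, rxn.upper_bound + 5.0
                )
            assert solve_fba(relaxed).tau_star >= tau - 1e-8
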