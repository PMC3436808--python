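import math

import numpy as np
import pytest

from stoichcap.capacitance import (
    CapacitanceConfig,
    CapacitanceError,
    IntegerizationError,
    augment_model,
    brute_force_capacitance,
    enumerate_capacitances,
    find_capacitance,
    integerize,
)
from stoichcap.fixtures import KREBS_CAPACITANCE_METABOLITES
from stoichcap.flux_analysis import solve_fba
from stoichcap.model import build_mass_matrix
from stoichcap.synthetic import SyntheticSpec, plant_capacitance_instance

GLYOXYLATE_SHUNT_SUM = {
    "accoa": -1,
    "icit": -1,
    "h2o": -1,
    "coa": 1,
    "mal": 1,
    "succ": 1,
}


def krebs_config(**kwargs) -> CapacitanceConfig:
    defaults = dict(mu=6, allowed_set=KREBS_CAPACITANCE_METABOLITES)
    defaults.update(kwargs)
    return CapacitanceConfig(**defaults)


def assert_valid_capacitance(model, cap, config):
    """The invariants every returned capacitance must satisfy."""
    assert cap.tau_star_r >= cap.baseline_tau - 1e-6
    if cap.is_trivial:
        return
    assert len(cap.support) <= config.mu
    if config.allowed_set is not None:
        assert cap.support <= config.allowed_set
    assert cap.r_int is not None
    # exact integer elemental balance
    mass = build_mass_matrix(model)
    residual = {}
    for mid, coef in cap.r_int.items():
        for el, count in model.metabolites[mid].formula.items():
            residual[el] = residual.get(el, 0) + coef * count
    assert all(v == 0 for v in residual.values()), residual
    # coprime integer stoichiometry
    assert math.gcd(*(abs(c) for c in cap.r_int.values())) == 1
    if cap.delta_g is not None:
        assert cap.delta_g <= 1e-9


class TestIntegerize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([-0.5, 1.0, 0.5], [-1, 2, 1]),
            ([2.0, -4.0, 2.0], [1, -2, 1]),
            ([3.0], [1]),
            ([1 / 3, 2 / 3], [1, 2]),
        ],
    )
    def test_examples(self, raw, expected):
        assert integerize(raw) == expected

    def test_dict_form_drops_zeros(self):
        assert integerize({"a": -2.5, "b": 5.0, "c": 0.0}) == {"a": -1, "b": 2}

    def test_all_zero_rejected(self):
        with pytest.raises(IntegerizationError):
            integerize([0.0, 0.0])

    def test_unapproximable_vector_flagged(self):
        with pytest.raises(IntegerizationError):
            integerize([1.0, 0.123456789], tol=1e-9, max_denominator=10)


class TestAugment:
    def test_augmentation_enables_glucose_synthesis(self, krebs):
        augmented = augment_model(krebs, GLYOXYLATE_SHUNT_SUM, flux_bound=1000.0)
        assert solve_fba(augmented).tau_star > 1.0
        # original untouched
        assert "SC" not in krebs.reactions

    def test_zero_vector_refused(self, krebs):
        with pytest.raises(CapacitanceError):
            augment_model(krebs, {}, 10.0)

    def test_unbalanced_conversion_refused(self, krebs):
        with pytest.raises(CapacitanceError, match="balanced"):
            augment_model(krebs, {"h2o": -1, "co2": 1}, 10.0)

    def test_augmentation_never_decreases_optimum(self, krebs):
        base = solve_fba(krebs).tau_star
        augmented = augment_model(krebs, {"cit": -1, "icit": 1}, 10.0, reaction_id="X")
        assert solve_fba(augmented).tau_star >= base - 1e-9


class TestFindCapacitance:
    def test_krebs_worked_example(self, krebs):
        config = krebs_config()
        cap = find_capacitance(krebs, config)
        assert cap.baseline_tau == pytest.approx(0.0, abs=1e-7)
        assert cap.tau_star_r > 1.0
        assert_valid_capacitance(krebs, cap, config)
        assert math.isinf(cap.increase_percent)
        # the conversion it reports genuinely enables glucose synthesis
        scale = 1000.0 / max(abs(v) for v in cap.r_int.values())
        assert solve_fba(augment_model(krebs, cap.r_int, scale)).tau_star > 1.0

    def test_mu_zero_reduces_to_fba(self, krebs):
        cap = find_capacitance(krebs, krebs_config(mu=0))
        assert cap.is_trivial
        assert cap.tau_star_r == pytest.approx(cap.baseline_tau, abs=1e-6)
        assert cap.increase_percent == 0.0

    def test_empty_allowed_set_reduces_to_fba(self, krebs):
        cap = find_capacitance(krebs, krebs_config(allowed_set=frozenset()))
        assert cap.is_trivial

    def test_brute_force_range_one_finds_glyoxylate_shunt_sum(self, krebs):
        cap = brute_force_capacitance(krebs, krebs_config(), coeff_range=1)
        assert cap.r_int == GLYOXYLATE_SHUNT_SUM
        assert cap.delta_g == pytest.approx(-71.3, abs=0.1)
        assert cap.tau_star_r > 1.0

    def test_milp_matches_brute_force_on_krebs(self, krebs):
        config = krebs_config()
        milp_cap = find_capacitance(krebs, config)
        brute_cap = brute_force_capacitance(krebs, config, coeff_range=2)
        assert milp_cap.tau_star_r == pytest.approx(brute_cap.tau_star_r, abs=1e-6)

    def test_unknown_allowed_metabolite_rejected(self, krebs):
        with pytest.raises(CapacitanceError, match="ghost"):
            find_capacitance(krebs, krebs_config(allowed_set=frozenset({"ghost"})))

    def test_lambda_scale_invariance(self):
        # with a small lambda the conversion's flux cap binds; doubling it
        # must never lower the achievable objective
        inst = plant_capacitance_instance(SyntheticSpec(seed=12))
        allowed = frozenset(inst.truth)
        small = find_capacitance(
            inst.model, CapacitanceConfig(mu=len(inst.truth), lam=1.0, allowed_set=allowed)
        )
        double = find_capacitance(
            inst.model, CapacitanceConfig(mu=len(inst.truth), lam=2.0, allowed_set=allowed)
        )
        assert double.tau_star_r >= small.tau_star_r - 1e-6
        assert small.tau_star_r < inst.full_tau  # the cap genuinely binds


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [100, 101, 102, 103, 104])
    def test_milp_equals_enumeration_on_planted_networks(self, seed):
        inst = plant_capacitance_instance(SyntheticSpec(seed=seed))
        allowed = frozenset(list(inst.model.internal_metabolite_ids)[:6])
        config = CapacitanceConfig(mu=4, allowed_set=allowed)
        milp_cap = find_capacitance(inst.model, config)
        brute_cap = brute_force_capacitance(inst.model, config, coeff_range=2)
        assert milp_cap.tau_star_r == pytest.approx(brute_cap.tau_star_r, abs=1e-6)
        assert_valid_capacitance(inst.model, milp_cap, config)

    def test_enumeration_guard(self, krebs):
        with pytest.raises(CapacitanceError, match="guard"):
            brute_force_capacitance(
                krebs, CapacitanceConfig(mu=4, thermo_enabled=False), coeff_range=3
            )


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_objective_restored(self, seed):
        inst = plant_capacitance_instance(SyntheticSpec(seed=seed))
        config = CapacitanceConfig(mu=len(inst.truth), allowed_set=frozenset(inst.truth))
        cap = find_capacitance(inst.model, config)
        assert cap.tau_star_r >= inst.full_tau - 1e-6
        assert_valid_capacitance(inst.model, cap, config)

    def test_mu_below_truth_support_yields_no_fix(self):
        # isomerization gap needs two metabolites; mu=1 admits no balanced
        # conversion at all (a single metabolite cannot balance), which the
        # brute-force oracle confirms
        inst = plant_capacitance_instance(SyntheticSpec(seed=0))
        assert len(inst.truth) == 2
        config = CapacitanceConfig(mu=1, allowed_set=frozenset(inst.truth))
        cap = find_capacitance(inst.model, config)
        brute = brute_force_capacitance(inst.model, config, coeff_range=2)
        assert cap.tau_star_r == pytest.approx(inst.broken_tau, abs=1e-6)
        assert brute.is_trivial


class TestEnumerate:
    def test_single_alternative_equals_find(self, krebs):
        config = krebs_config(max_alternatives=1)
        [only] = enumerate_capacitances(krebs, config)
        assert only.r_int == find_capacitance(krebs, config).r_int

    def test_krebs_has_multiple_distinct_supports(self, krebs):
        config = krebs_config(max_alternatives=4)
        caps = enumerate_capacitances(krebs, config)
        assert len(caps) >= 2
        supports = [c.support for c in caps]
        assert len(set(supports)) == len(supports)
        for cap in caps:
            assert_valid_capacitance(krebs, cap, config)
            scale = 1000.0 / max(abs(v) for v in cap.r_int.values())
            assert solve_fba(augment_model(krebs, cap.r_int, scale)).tau_star > 1.0

    def test_trivial_model_enumerates_once(self, krebs):
        caps = enumerate_capacitances(krebs, krebs_config(mu=0, max_alternatives=3))
        assert len(caps) == 1
        assert caps[0].is_trivial
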