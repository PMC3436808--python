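import numpy as np
import pytest

from stoichcap.decomposition import (
    DecompositionResult,
    build_database,
    decompose,
    verify_decomposition,
)
from stoichcap.fixtures import krebs_reaction_database
from stoichcap.formulas import parse_formula
from stoichcap.model import (
    IncompleteAnnotationError,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

GLYOXYLATE_SHUNT_SUM = {
    "accoa": -1,
    "icit": -1,
    "h2o": -1,
    "coa": 1,
    "mal": 1,
    "succ": 1,
}


@pytest.fixture(scope="module")
def krebs_db(request):
    from stoichcap.fixtures import krebs_fixture

    model = krebs_fixture()
    extra, reactions = krebs_reaction_database()
    return model, build_database(reactions, model, extra)


class TestBuildDatabase:
    def test_glyoxylate_reactions_go_to_coupled_block(self, krebs_db):
        _, db = krebs_db
        # glyoxylate appears in both ICL and MAS but is not an internal
        # metabolite of the model, so both columns couple to one extra species
        assert db.p == 0
        assert db.q == 2
        assert db.external_ids == ("gly",)
        assert [rid for rid, _ in db.b_meta] == ["ICL", "MAS"]

    def test_internal_only_reaction_lands_in_A(self):
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        aconitase = Reaction("ACONT_DB", {"cit": -1, "icit": 1}, 0, 1000)
        db = build_database([aconitase], model)
        assert db.p == 1 and db.q == 0

    def test_unbalanced_column_rejected(self):
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        bogus = Reaction("BAD", {"h2o": -1, "o2": 1}, 0, 1000)
        with pytest.raises(ModelError, match="BAD"):
            build_database([bogus], model)

    def test_unmapped_metabolite_rejected(self, krebs_db):
        model, _ = krebs_db
        stray = Reaction("STRAY", {"icit": -1, "unknown_met": 1}, 0, 1000)
        with pytest.raises(ModelError, match="unknown_met"):
            build_database([stray], model)

    def test_missing_formula_rejected(self):
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        bare = Metabolite("bare", is_internal=False)
        rxn = Reaction("R", {"icit": -1, "bare": 1}, 0, 1000)
        with pytest.raises(IncompleteAnnotationError):
            build_database([rxn], model, [bare])


class TestDecompose:
    def test_glyoxylate_shunt_sum_is_icl_plus_mas(self, krebs_db):
        _, db = krebs_db
        result = decompose(GLYOXYLATE_SHUNT_SUM, db)
        assert result.feasible
        assert result.alpha == {}
        assert result.beta["ICL"] == pytest.approx(1.0)
        assert result.beta["MAS"] == pytest.approx(1.0)
        assert result.residual_norm <= 1e-8

    def test_glyoxylate_cancels_exactly(self, krebs_db):
        _, db = krebs_db
        result = decompose(GLYOXYLATE_SHUNT_SUM, db)
        report = verify_decomposition(GLYOXYLATE_SHUNT_SUM, db, result)
        assert report == {"net_residual": 0.0, "internal_residual": 0.0}

    def test_single_reaction_recovered_with_unit_coefficient(self):
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        db = build_database(
            [
                Reaction("ACONT_DB", {"cit": -1, "icit": 1}, 0, 1000),
                Reaction("FUM_DB", {"fum": -1, "h2o": -1, "mal": 1}, 0, 1000),
            ],
            model,
        )
        result = decompose({"cit": -1, "icit": 1}, db, minimize_support=True)
        assert result.feasible
        assert result.alpha == {"ACONT_DB": pytest.approx(1.0)}
        assert result.residual_norm <= 1e-10

    def test_constructed_combination_recovered_exactly(self):
        """r assembled from known database columns must decompose with zero residual."""
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        columns = [
            Reaction("CS_DB", {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1}, 0, 1000),
            Reaction("ACONT_DB", {"cit": -1, "icit": 1}, -1000, 1000),
            Reaction("FUM_DB", {"fum": -1, "h2o": -1, "mal": 1}, 0, 1000),
        ]
        db = build_database(columns, model)
        weights = {"CS_DB": 1, "ACONT_DB": 2, "FUM_DB": 1}
        r: dict[str, float] = {}
        for rxn in columns:
            for mid, coef in rxn.stoich.items():
                r[mid] = r.get(mid, 0) + weights[rxn.id] * coef
        r = {mid: c for mid, c in r.items() if c}
        result = decompose(r, db)
        assert result.feasible
        assert result.residual_norm <= 1e-8
        report = verify_decomposition(r, db, result)
        assert report["net_residual"] == 0.0

    def test_irreversible_columns_constrain_sign(self):
        from stoichcap.fixtures import krebs_fixture

        model = krebs_fixture()
        forward_only = Reaction("ACONT_DB", {"cit": -1, "icit": 1}, 0, 1000)
        db = build_database([forward_only], model)
        backwards = decompose({"cit": 1, "icit": -1}, db)
        assert not backwards.feasible

    def test_infeasible_conversion_yields_farkas_certificate(self, krebs_db):
        model, db = krebs_db
        # a balanced conversion outside the span of {ICL, MAS}
        alien = {"accoa": -2, "coa": 2, "mal": -1, "succ": 2, "h2o": -1}
        result = decompose(alien, db)
        assert not result.feasible
        assert result.certificate is not None
        # certificate: y^T r > 0 while y^T col <= 0 for every usable column
        ids = list(db.internal_ids) + list(db.external_ids)
        y = np.array([result.certificate.get(mid, 0.0) for mid in ids])
        r_vec = np.array([alien.get(mid, 0.0) for mid in db.internal_ids] + [0.0] * len(db.external_ids))
        assert y @ r_vec > 1e-9
        E = np.vstack([np.hstack([db.A, db.B]), np.hstack([np.zeros((db.C.shape[0], db.p)), db.C])])
        assert np.all(y @ E <= 1e-9)

    def test_dimension_guard(self, krebs_db):
        _, db = krebs_db
        with pytest.raises(ModelError):
            decompose({"not_a_model_metabolite": 1}, db)

    def test_element_balance_closure(self, krebs_db):
        # balanced columns + feasible decomposition => the net conversion is
        # itself in the mass-matrix kernel (redundant cross-check)
        model, db = krebs_db
        result = decompose(GLYOXYLATE_SHUNT_SUM, db)
        assert result.feasible
        residual: dict[str, float] = {}
        for mid, coef in GLYOXYLATE_SHUNT_SUM.items():
            for el, count in model.metabolites[mid].formula.items():
                residual[el] = residual.get(el, 0.0) + coef * count
        assert all(abs(v) < 1e-9 for v in residual.values())


class TestVerify:
    def test_perturbed_coefficient_flagged(self, krebs_db):
        _, db = krebs_db
        result = decompose(GLYOXYLATE_SHUNT_SUM, db)
        tampered = DecompositionResult(
            alpha=dict(result.alpha),
            beta={**result.beta, "ICL": result.beta["ICL"] + 0.1},
            feasible=True,
            residual_norm=result.residual_norm,
            support=result.support,
        )
        report = verify_decomposition(GLYOXYLATE_SHUNT_SUM, db, tampered)
        assert report["net_residual"] > 0 or report["internal_residual"] > 0

    def test_zero_conversion_zero_support(self, krebs_db):
        _, db = krebs_db
        empty = DecompositionResult({}, {}, True, 0.0, ())
        report = verify_decomposition({}, db, empty)
        assert report == {"net_residual": 0.0, "internal_residual": 0.0}

    def test_infeasible_result_not_verifiable(self, krebs_db):
        _, db = krebs_db
        with pytest.raises(ModelError):
            verify_decomposition({}, db, DecompositionResult({}, {}, False, float("nan"), ()))
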