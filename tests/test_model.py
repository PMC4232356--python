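import math

import numpy as np
import pytest

import efmin as ef
from efmin.model import ModelError, from_json, from_tsv, to_json


class TestStructure:
    def test_toy_dimensions(self, toy):
        assert toy.n == 9
        assert toy.m == 5
        assert toy.stoichiometric_matrix().shape == (5, 9)

    def test_matrix_entries_follow_declaration_order(self, toy):
        S = toy.stoichiometric_matrix()
        mets = [m.id for m in toy.internal_metabolites]
        # r5: C -> B has exactly one -1 and one +1 in its column
        col = S[:, toy.reaction_ids.index("r5")]
        assert sorted(col) == [-1, 0, 0, 0, 1]
        assert col[mets.index("C")] == -1
        assert col[mets.index("B")] == 1

    def test_external_metabolites_excluded(self, toy):
        S = toy.stoichiometric_matrix()
        # r1 consumes only the external substrate and produces internal A
        col = S[:, toy.reaction_ids.index("r1")]
        assert list(col) == [1, 0, 0, 0, 0]

    def test_exchange_only_model_has_zero_rows(self):
        mets = [ef.Metabolite("x_ext", internal=False)]
        rxns = [ef.Reaction("ex1", {"x_ext": 1.0})]
        m = ef.MetabolicModel(mets, rxns, "ex1")
        assert m.stoichiometric_matrix().shape == (0, 1)

    def test_matrix_deterministic(self, toy):
        assert np.array_equal(toy.stoichiometric_matrix(), toy.stoichiometric_matrix())


class TestValidation:
    def test_missing_biomass_rejected(self, toy):
        with pytest.raises(ModelError, match="biomass"):
            ef.MetabolicModel(list(toy.metabolites), list(toy.reactions), "nope")

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelError, match="unknown metabolites"):
            ef.MetabolicModel(
                [ef.Metabolite("A")], [ef.Reaction("r", {"A": -1, "ghost": 1})], "r"
            )

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelError, match="empty stoichiometry"):
            ef.MetabolicModel([ef.Metabolite("A")], [ef.Reaction("r", {})], "r")

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ModelError, match="bound"):
            ef.MetabolicModel(
                [ef.Metabolite("A")],
                [ef.Reaction("r", {"A": 1}, lower_bound=2.0, upper_bound=1.0)],
                "r",
            )

    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(ModelError, match="irreversible"):
            ef.MetabolicModel(
                [ef.Metabolite("A")],
                [ef.Reaction("r", {"A": 1}, reversible=False, lower_bound=-1.0)],
                "r",
            )


class TestBounds:
    def test_defaults_by_reversibility(self):
        rev = ef.Reaction("a", {"A": 1}, reversible=True)
        irr = ef.Reaction("b", {"A": 1}, reversible=False)
        assert (rev.lower_bound, rev.upper_bound) == (-math.inf, math.inf)
        assert (irr.lower_bound, irr.upper_bound) == (0.0, math.inf)

    def test_thermodynamic_bounds_big_m(self, toy):
        capped = toy.apply_thermodynamic_bounds(big=1e6)
        for r in capped.reactions:
            assert (r.lower_bound, r.upper_bound) == (0.0, 1e6)

    def test_reversible_unbounded_both_ways(self):
        m = ef.MetabolicModel(
            [ef.Metabolite("A")], [ef.Reaction("r", {"A": 1}, reversible=True)], "r"
        )
        out = m.apply_thermodynamic_bounds()
        assert out.reactions[0].lower_bound == -math.inf
        assert out.reactions[0].upper_bound == math.inf

    def test_measured_finite_bounds_kept(self, toy_bounded):
        out = toy_bounded.apply_thermodynamic_bounds(big=1e6)
        assert out.reaction("r1").upper_bound == 1.0
        out2 = toy_bounded.apply_thermodynamic_bounds(big=1e6, keep_finite=False)
        assert out2.reaction("r1").upper_bound == 1e6


class TestIO:
    def test_json_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.json"
        ef.write_model(toy, path)
        back = ef.load_model(path)
        assert back.reaction_ids == toy.reaction_ids
        assert [m.id for m in back.metabolites] == [m.id for m in toy.metabolites]
        assert [m.internal for m in back.metabolites] == [m.internal for m in toy.metabolites]
        for a, b in zip(back.reactions, toy.reactions):
            assert (a.stoichiometry, a.reversible, a.lower_bound, a.upper_bound, a.gpr) == (
                b.stoichiometry, b.reversible, b.lower_bound, b.upper_bound, b.gpr
            )

    def test_tsv_round_trip_structure(self, toy):
        lines = []
        for r in toy.reactions:
            stoich = ";".join(
                f"{'@' if not next(m for m in toy.metabolites if m.id == k).internal else ''}{k}:{v}"
                for k, v in r.stoichiometry.items()
            )
            lines.append(f"{r.id}\t0\t{r.gpr}\t{stoich}")
        m = from_tsv("\n".join(lines), biomass="r9")
        assert m.n == 9 and m.m == 5
        assert np.array_equal(m.stoichiometric_matrix(), toy.stoichiometric_matrix())

    def test_parse_error_names_record(self):
        with pytest.raises(ModelError, match="r1"):
            from_tsv("r1\t0\tg1\tA;bad")

    def test_bad_json_is_format_error(self):
        with pytest.raises(ModelError, match="JSON"):
            from_json("{not json")

    def test_unknown_suffix(self, tmp_path):
        p = tmp_path / "model.bin"
        p.write_text("x")
        with pytest.raises(ModelError, match="suffix"):
            ef.load_model(p)


class TestSbml:
    def test_sbml_ingestion_matches_json(self, toy, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("toy")
        cmets = {}
        for met in toy.metabolites:
            if met.internal:
                cmets[met.id] = cobra.Metabolite(met.id, compartment="c")
        for r in toy.reactions:
            cr = cobra.Reaction(r.id, lower_bound=0.0, upper_bound=1000.0)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {cmets[k]: v for k, v in r.stoichiometry.items() if k in cmets}
            )
            cr.gene_reaction_rule = r.gpr
        cm.objective = "r9"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cm, str(path))
        loaded = ef.load_model(path)
        assert loaded.biomass_reaction_id == "r9"
        assert set(loaded.reaction_ids) == set(toy.reaction_ids)
        assert loaded.reaction("r3").gpr == "g3"
        assert np.array_equal(
            loaded.stoichiometric_matrix(), toy.stoichiometric_matrix()
        )
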