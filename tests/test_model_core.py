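"""Model containers, I/O round trips, media application, class inference."""

import json

import pytest

from rhizoflux import (
    MediaCondition,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_media,
    fba,
)
from rhizoflux.bruteforce import gpr_truth_table
from rhizoflux.io import (
    load_json_model,
    load_model,
    read_media_tsv,
    write_json_model,
    write_model,
)
from rhizoflux.model import infer_reaction_class


class TestContainers:
    def test_duplicate_ids_rejected(self, chain3):
        model, _ = chain3
        with pytest.raises(ValueError):
            model.add_metabolite(Metabolite("A_e"))
        with pytest.raises(ValueError):
            model.add_reaction(Reaction("EX_A", stoichiometry={"A_e": -1.0}))

    def test_reaction_requires_known_metabolites_and_stoichiometry(self, chain3):
        model, _ = chain3
        with pytest.raises(KeyError):
            model.add_reaction(Reaction("RX", stoichiometry={"nope": -1.0}))
        with pytest.raises(ValueError):
            model.add_reaction(Reaction("RY", stoichiometry={}))

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValueError):
            Reaction("R", stoichiometry={"m": 1.0}, lower_bound=1.0, upper_bound=0.0)

    def test_counts_on_fixture(self, chain3):
        model, _ = chain3
        assert len(model.metabolites) == 3
        assert len(model.reactions) == 4
        assert len(model.genes) == 1


class TestClassInference:
    @pytest.mark.parametrize(
        "rid,stoich,explicit,expected",
        [
            ("EX_glc", {"glc_e": -1}, None, "exchange"),
            ("DM_atp", {"atp_c": -1}, None, "demand"),
            ("SK_sym", {"sym_c": -1}, None, "sink"),
            ("weird_boundary", {"x_c": -1}, None, "exchange"),
            ("R1", {"a": -1, "b": 1}, None, "enzymatic"),
            ("R1", {"a": -1, "b": 1}, "transport", "transport"),
            ("EX_like", {"a": -1, "b": 1}, "spontaneous", "spontaneous"),
        ],
    )
    def test_precedence(self, rid, stoich, explicit, expected):
        assert infer_reaction_class(rid, stoich, explicit=explicit) == expected


class TestRoundTrips:
    @pytest.mark.parametrize("dialect,suffix", [("cobra-json", ".json"), ("sbml", ".xml")])
    def test_write_load_preserves_everything(self, symbiosis, tmp_path, dialect, suffix):
        model, _ = symbiosis
        path = tmp_path / f"toy{suffix}"
        write_model(model, path, dialect)
        back = load_model(path, dialect)
        assert set(back.reactions) == set(model.reactions)
        assert set(back.metabolites) == set(model.metabolites)
        assert back.genes == model.genes
        assert back.objective_id == model.objective_id
        for rid, rxn in model.reactions.items():
            other = back.reactions[rid]
            assert other.stoichiometry == rxn.stoichiometry
            assert other.lower_bound == pytest.approx(rxn.lower_bound)
            assert other.upper_bound == pytest.approx(rxn.upper_bound)
            assert other.reaction_class == rxn.reaction_class
            assert gpr_truth_table(other.gpr) == gpr_truth_table(rxn.gpr)

    def test_missing_objective_is_an_error(self, chain3, tmp_path):
        model, _ = chain3
        path = tmp_path / "m.json"
        write_json_model(model, path)
        doc = json.loads(path.read_text())
        for rxn in doc["reactions"]:
            rxn["objective_coefficient"] = 0.0
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="objective"):
            load_json_model(path)

    def test_unknown_gpr_gene_warns_and_registers(self, chain3, tmp_path):
        model, _ = chain3
        path = tmp_path / "m.json"
        write_json_model(model, path)
        doc = json.loads(path.read_text())
        doc["reactions"][2]["gene_reaction_rule"] = "g1 or ghost"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="ghost"):
            back = load_json_model(path)
        assert "ghost" in back.genes


class TestMedia:
    def test_listed_exchange_opened_others_closed(self, chain3):
        model, _ = chain3
        out = apply_media(model, MediaCondition({"EX_A": 5.0}), close_others=True)
        assert out.reactions["EX_A"].lower_bound == -5.0

    def test_close_others_zeroes_unlisted_uptake(self, symbiosis):
        model, _ = symbiosis
        out = apply_media(model, MediaCondition({"EX_succ": 1.38}), close_others=True)
        assert out.reactions["EX_succ"].lower_bound == -1.38
        assert out.reactions["EX_W"].lower_bound == 0.0  # was -1
        assert out.reactions["EX_W"].upper_bound > 0  # secretion stays open

    def test_empty_media_closes_all_carbon_objective_zero(self, chain3):
        model, _ = chain3
        out = apply_media(model, MediaCondition({}), close_others=True)
        assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_exchange_rejected(self, chain3):
        model, _ = chain3
        with pytest.raises(KeyError, match="EX_nope"):
            apply_media(model, MediaCondition({"EX_nope": 1.0}))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            MediaCondition({"EX_A": -1.0})

    def test_media_never_changes_stoichiometry(self, symbiosis):
        model, _ = symbiosis
        out = apply_media(model, MediaCondition({"EX_succ": 2.0}))
        for rid in model.reactions:
            assert out.reactions[rid].stoichiometry == model.reactions[rid].stoichiometry

    def test_media_tsv_reader(self, tmp_path):
        path = tmp_path / "media.tsv"
        path.write_text(
            "exchange_id\tuptake_rate\n# a comment\nEX_succ\t1.38\nEX_mal\t1.44\n"
        )
        media = read_media_tsv(path, label="symbiosis")
        assert media.uptakes == {"EX_succ": 1.38, "EX_mal": 1.44}
        assert media.label == "symbiosis"
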