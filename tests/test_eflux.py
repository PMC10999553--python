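"""E-Flux expression mapping, bound scaling and homolog re-keying."""

import pytest

from rhizoflux import (
    UNCONSTRAINED,
    ExpressionProfile,
    HomologMap,
    eflux_transform,
    fba,
    map_homologs,
    reaction_expression,
)
from rhizoflux import synth
from rhizoflux.eflux import read_expression_tsv, read_homolog_tsv
from rhizoflux.gpr import parse_gpr


class TestReactionExpression:
    @pytest.mark.parametrize(
        "rule,abundances,expected",
        [
            ("g1 and g2", {"g1": 4, "g2": 10}, 4),
            ("g1 or g2", {"g1": 4, "g2": 10}, 14),
            ("g1 and (g2 or g3)", {"g1": 9, "g2": 2, "g3": 5}, 7),
            ("g1 and g2 and g3", {"g1": 3, "g2": 1, "g3": 2}, 1),
        ],
    )
    def test_min_sum_aggregation(self, rule, abundances, expected):
        profile = ExpressionProfile(abundances)
        assert reaction_expression(parse_gpr(rule), profile) == expected

    def test_or_max_alternative(self):
        profile = ExpressionProfile({"g1": 4, "g2": 10})
        assert reaction_expression(parse_gpr("g1 or g2"), profile, or_rule="max") == 10

    def test_empty_gpr_is_unconstrained(self):
        assert reaction_expression(parse_gpr(""), ExpressionProfile({})) == UNCONSTRAINED

    def test_missing_gene_defaults_to_unconstrained(self):
        profile = ExpressionProfile({"g1": 5})
        # unmeasured AND-partner cannot undercut the measured subunit
        assert reaction_expression(parse_gpr("g1 and gX"), profile) == 5
        # unmeasured isozyme makes the OR capacity unbounded
        assert reaction_expression(parse_gpr("g1 or gX"), profile) == UNCONSTRAINED

    def test_negative_abundances_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfile({"g1": -1.0})


class TestEfluxTransform:
    def test_uniform_profile_leaves_objective_unchanged(self):
        model, truth = synth.make_chain_model(3, 10.0)
        profile = synth.make_expression_profile(model, "uniform")
        out = eflux_transform(model, profile)
        assert fba(out).objective_value == pytest.approx(truth["optimum"], abs=1e-6)

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 1.0])
    def test_planted_rate_limiting_gene_scales_objective(self, fraction):
        model, truth = synth.make_chain_model(2, 10.0)
        profile = synth.make_expression_profile(
            model, "single_limited", gene="g2", fraction=fraction
        )
        out = eflux_transform(model, profile)
        assert fba(out).objective_value == pytest.approx(
            fraction * truth["optimum"], abs=1e-6
        )

    def test_zero_abundance_gene_closes_reaction(self, chain3):
        model, _ = chain3
        model = model.copy()
        model.genes.add("g_spare")  # keep e_max finite and positive
        model.reactions["T_A"].gpr = parse_gpr("g_spare")
        out = eflux_transform(model, ExpressionProfile({"g1": 0.0, "g_spare": 5.0}))
        assert out.reactions["R1"].lower_bound == out.reactions["R1"].upper_bound == 0.0
        assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_profile_is_an_error(self, chain3):
        model, _ = chain3
        with pytest.raises(ValueError, match="zero"):
            eflux_transform(model, ExpressionProfile({"g1": 0.0}))

    def test_never_widens_a_bound(self):
        model, _ = synth.make_symbiosis_toy()
        profile = synth.make_expression_profile(model, "random", seed=7)
        clamped = eflux_transform(model, synth.make_expression_profile(model, "uniform"))
        out = eflux_transform(model, profile)
        for rid in model.reactions:
            assert abs(out.reactions[rid].lower_bound) <= abs(
                clamped.reactions[rid].lower_bound
            ) + 1e-9
            assert abs(out.reactions[rid].upper_bound) <= abs(
                clamped.reactions[rid].upper_bound
            ) + 1e-9

    def test_profile_scale_invariance(self):
        model, _ = synth.make_chain_model(2, 10.0)
        profile = synth.make_expression_profile(model, "single_limited", gene="g1",
                                                fraction=0.4)
        a = eflux_transform(model, profile)
        b = eflux_transform(model, profile.scaled(37.5))
        for rid in model.reactions:
            assert a.reactions[rid].lower_bound == pytest.approx(
                b.reactions[rid].lower_bound, abs=1e-9
            )
            assert a.reactions[rid].upper_bound == pytest.approx(
                b.reactions[rid].upper_bound, abs=1e-9
            )

    def test_transformed_objective_never_exceeds_original(self):
        model, truth = synth.make_symbiosis_toy()
        profile = synth.make_expression_profile(model, "random", seed=11)
        out = eflux_transform(model, profile)
        assert fba(out).objective_value <= truth["optimum"] + 1e-9


class TestHomologMapping:
    def test_simple_pair_re_keys_abundance(self):
        homologs = HomologMap({"a": ("x", 95.0)})
        mapped, report = map_homologs(ExpressionProfile({"a": 7.0}), homologs)
        assert mapped.abundances == {"x": 7.0}
        assert report["unmapped_sources"] == []

    def test_below_threshold_hit_dropped(self):
        homologs = HomologMap({"a": ("x", 85.0)}, min_ratio=90.0)
        mapped, report = map_homologs(ExpressionProfile({"a": 7.0}), homologs)
        assert mapped.abundances == {}
        assert report["dropped_below_threshold"] == ["a"]
        assert report["unmapped_sources"] == ["a"]

    def test_duplicate_target_keeps_highest_ratio(self):
        homologs = HomologMap({"a": ("x", 92.0), "b": ("x", 96.0)})
        mapped, report = map_homologs(
            ExpressionProfile({"a": 3.0, "b": 8.0}), homologs
        )
        assert mapped.abundances == {"x": 8.0}
        assert report["duplicate_losers"] == ["a"]

    def test_synthetic_map_drop_set_matches_planted_truth(self, symbiosis):
        model, _ = symbiosis
        homologs, truth = synth.make_homolog_map(model, seed=5)
        donor_profile = ExpressionProfile(
            {src: 1.0 for src in homologs.pairs}, "donor"
        )
        mapped, report = map_homologs(donor_profile, homologs)
        assert report["dropped_below_threshold"] == truth["dropped_sources"]
        assert len(mapped.abundances) == len(model.genes) - len(truth["dropped_sources"])


class TestTabularReaders:
    def test_expression_tsv_averages_replicates(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\trep1\trep2\trep3\ng1\t1\t2\t3\ng2\t10\t10\t10\n")
        profile = read_expression_tsv(path)
        assert profile.abundances == {"g1": 2.0, "g2": 10.0}

    def test_homolog_tsv_reader(self, tmp_path):
        path = tmp_path / "bbh.tsv"
        path.write_text("source_id\ttarget_id\tbbh_ratio\na\tx\t95.5\nb\ty\t88.0\n")
        homologs = read_homolog_tsv(path)
        assert homologs.pairs == {"a": ("x", 95.5), "b": ("y", 88.0)}
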