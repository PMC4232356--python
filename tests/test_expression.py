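import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import efmin as ef
from efmin.expression import BoolOp, Gene, GprParseError, gpr_genes


class TestParser:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("A AND B", BoolOp("and", (Gene("A"), Gene("B")))),
            ("(A AND B) OR C", BoolOp("or", (BoolOp("and", (Gene("A"), Gene("B"))), Gene("C")))),
            # AND binds tighter than OR without parentheses
            ("A AND B OR C", BoolOp("or", (BoolOp("and", (Gene("A"), Gene("B"))), Gene("C")))),
            ("a and (b or c)", BoolOp("and", (Gene("a"), BoolOp("or", (Gene("b"), Gene("c")))))),
            ("G1", Gene("G1")),
        ],
    )
    def test_parse_structure(self, rule, expected):
        assert ef.parse_gpr(rule) == expected

    def test_empty_rule_is_none(self):
        assert ef.parse_gpr("") is None
        assert ef.parse_gpr("   ") is None

    @pytest.mark.parametrize("bad", ["A AND", "(A OR B", "A B", "OR A", "A AND ) B"])
    def test_errors_report_position(self, bad):
        with pytest.raises(GprParseError, match="position"):
            ef.parse_gpr(bad)

    def test_precedence_matches_cobra_parser(self):
        """Mixed-precedence rules must agree with the SBML-fbc convention as
        implemented by cobrapy's GPR parser (Boolean semantics)."""
        from cobra.core.gene import GPR

        rules = ["A and B or C", "A or B and C", "A and B or C and D", "A or B or C and D"]
        for rule in rules:
            mine = ef.parse_gpr(rule)
            theirs = GPR.from_string(rule)
            genes = sorted(gpr_genes(mine))
            for bits in range(2 ** len(genes)):
                assign = {g: bool(bits >> i & 1) for i, g in enumerate(genes)}
                off = {g for g, on in assign.items() if not on}
                mine_val = ef.evaluate_gpr(mine, {g: float(v) for g, v in assign.items()})
                assert bool(mine_val) == theirs.eval(off)


def _enumerate_leaf_sets(tree):
    """Truth-tree oracle: OR of AND-clauses; value = max over clauses of min."""
    if isinstance(tree, Gene):
        return [{tree.name}]
    if tree.op == "or":
        out = []
        for c in tree.children:
            out.extend(_enumerate_leaf_sets(c))
        return out
    combos = [set()]
    for c in tree.children:
        combos = [a | b for a in combos for b in _enumerate_leaf_sets(c)]
    return combos


_gene_names = st.sampled_from([f"g{i}" for i in range(6)])
_trees = st.recursive(
    _gene_names.map(Gene),
    lambda kids: st.tuples(
        st.sampled_from(["and", "or"]), st.lists(kids, min_size=2, max_size=3)
    ).map(lambda t: BoolOp(t[0], tuple(t[1]))),
    max_leaves=16,
)


class TestEvaluate:
    def test_and_is_min_or_is_max(self):
        vals = {"A": 0.8, "B": 0.2}
        assert ef.evaluate_gpr(ef.parse_gpr("A AND B"), vals) == 0.2
        assert ef.evaluate_gpr(ef.parse_gpr("A OR B"), vals) == 0.8

    def test_missing_gene_ignored_by_default(self):
        vals = {"B": 0.5}
        assert ef.evaluate_gpr(ef.parse_gpr("A OR B"), vals) == 0.5
        assert ef.evaluate_gpr(ef.parse_gpr("A AND B"), vals) == 0.5

    def test_missing_poisons_and_when_propagating(self):
        vals = {"B": 0.5}
        assert ef.evaluate_gpr(ef.parse_gpr("A AND B"), vals, missing="propagate") is None
        assert ef.evaluate_gpr(ef.parse_gpr("A OR B"), vals, missing="propagate") == 0.5

    def test_all_missing_is_missing(self):
        assert ef.evaluate_gpr(ef.parse_gpr("A AND (B OR C)"), {}) is None

    @settings(max_examples=200, derandomize=True)
    @given(_trees, st.integers(0, 2**31 - 1))
    def test_matches_truth_tree_enumeration(self, tree, seed):
        rng = np.random.default_rng(seed)
        values = {g: float(rng.uniform()) for g in gpr_genes(tree)}
        expected = max(min(values[g] for g in clause) for clause in _enumerate_leaf_sets(tree))
        assert ef.evaluate_gpr(tree, values) == pytest.approx(expected)


class TestMapping:
    def test_normalization_divides_by_max(self, toy):
        profile = ef.ExpressionProfile({"g1": 4.0, "g3": 2.0})
        rexpr = ef.map_expression(toy, profile)
        assert rexpr.g["r1"] == 1.0
        assert rexpr.g["r3"] == 0.5
        assert "r2" not in rexpr.g  # unmeasured

    def test_single_gene_normalizes_to_one(self, toy):
        rexpr = ef.map_expression(toy, ef.ExpressionProfile({"g5": 123.0}))
        assert rexpr.g == {"r5": 1.0}

    def test_empty_profile_warns_all_missing(self, toy):
        with pytest.warns(UserWarning, match="no reaction"):
            rexpr = ef.map_expression(toy, ef.ExpressionProfile({}))
        assert rexpr.g == {}

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ef.ExpressionProfile({"g1": -1.0})

    def test_profile_tsv_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("g1\t1.0\ng1\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            ef.ExpressionProfile.from_tsv(p)

    def test_profile_tsv_header_optional(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene\tvalue\ng1\t1.5\ng2\t0\n")
        prof = ef.ExpressionProfile.from_tsv(p)
        assert prof.values == {"g1": 1.5, "g2": 0.0}


class TestWeights:
    def test_efmin_weight_is_one_minus_g(self, toy):
        rexpr = ef.ReactionExpression(toy.reaction_ids, {"r3": 0.3})
        w = ef.compute_weights(rexpr, "efmin")
        assert w["r3"] == pytest.approx(0.7)
        assert w["r2"] == 1.0  # no data -> full penalty

    def test_gimme_weights_below_cutoff_only(self, toy):
        rexpr = ef.ReactionExpression(toy.reaction_ids, {"r3": 0.03, "r4": 0.5})
        w = ef.compute_weights(rexpr, "gimme", g_cutoff=0.05)
        assert w["r3"] == pytest.approx(0.02)
        assert w["r4"] == 0.0
        assert w["r2"] == 0.05  # no data -> cutoff

    def test_fully_expressed_reaction_unpenalized_both_modes(self, toy):
        rexpr = ef.ReactionExpression(toy.reaction_ids, {"r3": 1.0})
        assert ef.compute_weights(rexpr, "efmin")["r3"] == 0.0
        assert ef.compute_weights(rexpr, "gimme", g_cutoff=0.05)["r3"] == 0.0

    def test_invalid_cutoff_rejected(self, toy):
        rexpr = ef.ReactionExpression(toy.reaction_ids, {})
        with pytest.raises(ValueError, match="cutoff"):
            ef.compute_weights(rexpr, "gimme", g_cutoff=0.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["efmin", "gimme"]))
    def test_monotone_expression_never_raises_weights(self, seed, mode):
        """Raising any gene's expression can only lower (or keep) every weight."""
        toy = ef.build_toy_network()
        rng = np.random.default_rng(seed)
        base_vals = {f"g{i}": float(rng.uniform(0.1, 0.9)) for i in range(1, 10)}
        gene = f"g{int(rng.integers(1, 10))}"
        bumped_vals = dict(base_vals)
        bumped_vals[gene] = base_vals[gene] + float(rng.uniform(0.0, 0.1))
        # common normalization scale so weights are comparable
        top = max(bumped_vals.values())
        base = ef.ReactionExpression(toy.reaction_ids, {f"r{i}": base_vals[f"g{i}"] / top for i in range(1, 10)})
        bump = ef.ReactionExpression(toy.reaction_ids, {f"r{i}": bumped_vals[f"g{i}"] / top for i in range(1, 10)})
        w0 = ef.compute_weights(base, mode)
        w1 = ef.compute_weights(bump, mode)
        for rid in toy.reaction_ids:
            assert w1.w[rid] <= w0.w[rid] + 1e-12
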