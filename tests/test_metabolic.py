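"""GPR grammar, the min/sum activity algebra, and Monte-Carlo regulation."""

import numpy as np
import pandas as pd
import pytest

from chemonet.core_data import MetabolicModelSpec, ReactionSpec
from chemonet.gpr import And, Gene, GPRParseError, Or, parse_gpr
from chemonet.metabolic import estimate_reaction_regulation, summarize_subsystems


def random_rule(rng, genes, depth=0, max_depth=3):
    """Independent random GPR generator for oracle checks."""
    if depth >= max_depth or rng.random() < 0.35:
        return rng.choice(genes)
    op = " and " if rng.random() < 0.5 else " or "
    k = rng.integers(2, 4)
    parts = [random_rule(rng, genes, depth + 1, max_depth) for _ in range(k)]
    parts = [f"({p})" if (" " in p and rng.random() < 0.7) else p for p in parts]
    joined = op.join(f"({p})" if " " in p else p for p in parts)
    return joined


def eval_bruteforce(rule: str, activity: dict) -> float:
    """Oracle: evaluate via Python eval after rewriting and/or to min/sum."""

    def rewrite(node):
        if isinstance(node, Gene):
            return activity[node.gene_id]
        vals = [rewrite(c) for c in node.children]
        return min(vals) if isinstance(node, And) else sum(vals)

    return rewrite(parse_gpr(rule))


class TestParser:
    def test_and_binds_tighter_than_or(self):
        tree = parse_gpr("A and B or C")
        assert isinstance(tree, Or)
        assert isinstance(tree.children[0], And)
        assert tree.children[1] == Gene("C")

    def test_parentheses_override_precedence(self):
        tree = parse_gpr("(A or B) and C")
        assert isinstance(tree, And)
        assert isinstance(tree.children[0], Or)

    def test_keywords_case_insensitive(self):
        assert parse_gpr("A AND b Or c") == parse_gpr("A and b or c")

    def test_dangling_operator_position(self):
        with pytest.raises(GPRParseError) as err:
            parse_gpr("A and")
        assert err.value.position == 5

    def test_unbalanced_parentheses(self):
        with pytest.raises(GPRParseError, match="unbalanced|unexpected"):
            parse_gpr("(A or B")

    def test_roundtrip_print_parse_idempotent(self, rng):
        genes = [f"G{i}" for i in range(8)]
        for _ in range(100):
            rule = random_rule(rng, genes)
            tree = parse_gpr(rule)
            assert parse_gpr(tree.to_string()) == tree


class TestEvaluation:
    def test_and_is_min(self):
        assert parse_gpr("A and B").evaluate({"A": 0.5, "B": 2.0}) == 0.5

    def test_or_is_sum(self):
        assert parse_gpr("A or B").evaluate({"A": 2.0, "B": 4.0}) == 6.0

    def test_matches_bruteforce_oracle_exactly(self, rng):
        """min/sum algebra equals an independent recursive evaluation on 200 rules."""
        genes = [f"G{i}" for i in range(8)]
        for _ in range(200):
            rule = random_rule(rng, genes, max_depth=4)
            activity = {g: float(rng.uniform(0, 5)) for g in genes}
            tree = parse_gpr(rule)
            assert tree.evaluate(activity) == eval_bruteforce(rule, activity)

    def test_vectorized_evaluation_matches_scalar(self, rng):
        genes = ["A", "B", "C"]
        tree = parse_gpr("(A or B) and C")
        mat = {g: rng.uniform(0.1, 3.0, size=50) for g in genes}
        vec = tree.evaluate(mat)
        for k in range(50):
            assert vec[k] == tree.evaluate({g: mat[g][k] for g in genes})


def make_model(rules, subsystems=None):
    genes = sorted({g for r in rules if r for g in parse_gpr(r).gene_ids()})
    reactions = [
        ReactionSpec(f"R{i}", rule, (subsystems or {}).get(i, "S"))
        for i, rule in enumerate(rules)
    ]
    return MetabolicModelSpec(reactions=reactions, genes=genes)


def contrasts(**kv):
    return pd.DataFrame(
        {"mean_diff": {g: v[0] for g, v in kv.items()}, "se": {g: v[1] for g, v in kv.items()}}
    )


class TestRegulation:
    def test_or_rule_deterministic_at_zero_se(self):
        model = make_model(["A or B"])
        res = estimate_reaction_regulation(model, contrasts(A=(1.0, 0.0), B=(1.0, 0.0)), seed=0)
        row = res.table.loc["R0"]
        assert row["log2_reg"] == pytest.approx(1.0, abs=1e-12)
        assert row["sd"] == 0.0
        assert row["p"] == pytest.approx(2.0 / 1001.0)

    def test_and_rule_takes_scarcest_subunit(self):
        model = make_model(["A and B"])
        res = estimate_reaction_regulation(model, contrasts(A=(-1.0, 0.0), B=(-0.5, 0.0)), seed=0)
        assert res.table.loc["R0", "log2_reg"] == pytest.approx(-1.0, abs=1e-12)

    def test_all_zero_effects_give_exact_null(self, rng):
        rules = ["A and B", "A or (B and C)", "C"]
        model = make_model(rules)
        res = estimate_reaction_regulation(
            model, contrasts(A=(0.0, 0.0), B=(0.0, 0.0), C=(0.0, 0.0)), seed=1
        )
        assert (res.table["log2_reg"] == 0.0).all()
        assert (res.table["p"] == 1.0).all()
        assert (res.table["status"] == "unchanged").all()

    def test_se_to_zero_limit_converges_to_deterministic(self):
        model = make_model(["(A or B) and C"])
        exact = estimate_reaction_regulation(
            model, contrasts(A=(0.7, 0.0), B=(-0.2, 0.0), C=(0.4, 0.0)), seed=5
        ).table.loc["R0", "log2_reg"]
        tiny = estimate_reaction_regulation(
            model, contrasts(A=(0.7, 1e-8), B=(-0.2, 1e-8), C=(0.4, 1e-8)), seed=5
        ).table.loc["R0", "log2_reg"]
        assert abs(tiny - exact) < 1e-6

    def test_point_regulation_monotone_in_gene_effect(self):
        model = make_model(["(A and B) or C"])
        base = estimate_reaction_regulation(
            model, contrasts(A=(0.2, 0.0), B=(0.5, 0.0), C=(-0.3, 0.0)), seed=0
        ).table.loc["R0", "log2_reg"]
        for gene in "ABC":
            kv = {"A": (0.2, 0.0), "B": (0.5, 0.0), "C": (-0.3, 0.0)}
            kv[gene] = (kv[gene][0] + 0.8, 0.0)
            bumped = estimate_reaction_regulation(model, contrasts(**kv), seed=0).table.loc[
                "R0", "log2_reg"
            ]
            assert bumped >= base - 1e-12

    def test_missing_gene_neutral_vs_strict(self, caplog):
        model = make_model(["A and B"])
        only_a = contrasts(A=(1.0, 0.0))
        res = estimate_reaction_regulation(model, only_a, seed=0)
        assert res.neutral_genes == ["B"]
        assert res.table.loc["R0", "log2_reg"] == pytest.approx(0.0)  # min(2, 1) = 1
        with pytest.raises(KeyError):
            estimate_reaction_regulation(model, only_a, seed=0, missing_policy="strict")

    def test_empty_gpr_skipped_and_reported(self):
        model = make_model(["A or B", ""])
        res = estimate_reaction_regulation(model, contrasts(A=(0.5, 0.0), B=(0.5, 0.0)), seed=0)
        assert res.skipped == ["R1"]
        assert list(res.table.index) == ["R0"]

    def test_ci_brackets_point_estimate(self, rng):
        model = make_model(["A or B", "A and C", "(B or C) and A"])
        res = estimate_reaction_regulation(
            model,
            contrasts(A=(0.5, 0.2), B=(-0.4, 0.1), C=(0.1, 0.3)),
            seed=7,
        )
        t = res.table
        assert (t["ci_low"] <= t["log2_reg"] + 1e-9).all()
        assert (t["log2_reg"] <= t["ci_high"] + 1e-9).all()

    def test_seed_determinism(self):
        model = make_model(["A or B"])
        c = contrasts(A=(0.3, 0.2), B=(0.1, 0.2))
        a = estimate_reaction_regulation(model, c, seed=42).table
        b = estimate_reaction_regulation(model, c, seed=42).table
        pd.testing.assert_frame_equal(a, b)

    def test_draws_below_100_rejected(self):
        model = make_model(["A"])
        with pytest.raises(ValueError):
            estimate_reaction_regulation(model, contrasts(A=(0.0, 0.0)), n_draws=50)


class TestSubsystemSummary:
    def test_fractions(self):
        table = pd.DataFrame(
            {
                "subsystem": ["S1", "S1", "S2", "S2", "S3"],
                "status": ["activated", "unchanged", "inhibited", "inhibited", "activated"],
            },
            index=[f"R{i}" for i in range(5)],
        )
        out = summarize_subsystems(table)
        assert out.loc["S1", "frac_activated"] == 0.5
        assert out.loc["S2", "frac_inhibited"] == 1.0
        assert out.loc["S3", "frac_activated"] == 1.0
        assert ((out["frac_activated"] + out["frac_inhibited"]) <= 1.0).all()

    def test_all_unchanged_gives_zero_fractions(self):
        table = pd.DataFrame(
            {"subsystem": ["S", "S"], "status": ["unchanged", "unchanged"]}, index=["R0", "R1"]
        )
        out = summarize_subsystems(table)
        assert (out[["frac_activated", "frac_inhibited"]] == 0).all().all()
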