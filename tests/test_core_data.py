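"""Containers, transforms and plain-text I/O."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemonet.core_data import (
    DataValidationError,
    ExpressionCohort,
    GeneSetCollection,
    collapse_probes,
    log2_transform,
    read_expression_matrix,
    read_gmt,
    read_metabolic_model,
    write_expression_matrix,
    zscore_genes,
)


class TestLog2Transform:
    @pytest.mark.parametrize("raw,expected", [(0.0, 0.0), (3.0, 2.0), (1023.0, 10.0)])
    def test_known_values(self, raw, expected):
        out = log2_transform(np.array([[raw]]))
        assert out[0, 0] == pytest.approx(expected)

    def test_negative_entry_names_cell(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["GENE1"], columns=["s1", "s2"])
        with pytest.raises(DataValidationError, match="GENE1.*s2"):
            log2_transform(df)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=30), min_size=1, max_size=20))
    def test_inverts_exp2_minus_one(self, xs):
        x = np.array([xs])
        back = log2_transform(2.0**x - 1.0)
        assert np.allclose(back, x, atol=1e-9)


class TestCollapseProbes:
    def test_geometric_mean_and_passthrough(self):
        mat = pd.DataFrame(
            {"s1": [2.0, 8.0, 5.0, 1.0, 1.0, 1.0]},
            index=["p1", "p2", "p3", "p4", "p5", "p6"],
        )
        mapping = {"p1": "GA", "p2": "GA", "p3": "GB", "p4": "GC", "p5": "GC", "p6": "GC"}
        out = collapse_probes(mat, mapping)
        assert out.loc["GA", "s1"] == pytest.approx(4.0)
        assert out.loc["GB", "s1"] == pytest.approx(5.0)
        assert out.loc["GC", "s1"] == pytest.approx(1.0)

    def test_zero_probe_gives_zero_not_error(self):
        mat = pd.DataFrame({"s1": [0.0, 9.0]}, index=["p1", "p2"])
        out = collapse_probes(mat, {"p1": "G", "p2": "G"})
        assert out.loc["G", "s1"] == 0.0

    def test_unmapped_probe_rejected(self):
        mat = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(DataValidationError, match="unmapped"):
            collapse_probes(mat, {})

    def test_permutation_invariant_in_probe_order(self, rng):
        mat = pd.DataFrame(rng.uniform(0.5, 10, size=(6, 4)), index=[f"p{i}" for i in range(6)])
        mapping = {f"p{i}": "G1" if i < 3 else "G2" for i in range(6)}
        perm = rng.permutation(6)
        shuffled = mat.iloc[perm]
        a = collapse_probes(mat, mapping)
        b = collapse_probes(shuffled, mapping)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestZscore:
    def _cohort(self, rows, genes):
        values = pd.DataFrame(rows, index=genes, columns=[f"s{i}" for i in range(len(rows[0]))])
        return ExpressionCohort(cohort_id="c", values=values)

    def test_hand_zscore(self):
        scaled, params = zscore_genes(self._cohort([[1.0, 2.0, 3.0]], ["G"]), ["G"])
        assert np.allclose(scaled.loc["G"], [-1.0, 0.0, 1.0])
        assert params.loc["G", "mean"] == 2.0 and params.loc["G", "sd"] == 1.0

    def test_idempotent_on_standardized_rows(self, rng):
        row = rng.normal(size=50)
        row = (row - row.mean()) / row.std(ddof=1)
        scaled, _ = zscore_genes(self._cohort([row], ["G"]), ["G"])
        assert np.allclose(scaled.loc["G"], row, atol=1e-12)

    def test_constant_gene_rejected(self):
        with pytest.raises(DataValidationError, match="G"):
            zscore_genes(self._cohort([[5.0, 5.0, 5.0]], ["G"]), ["G"])

    def test_case_insensitive_lookup(self):
        scaled, _ = zscore_genes(self._cohort([[1.0, 2.0, 3.0]], ["CxCl9"]), ["CXCL9"])
        assert list(scaled.index) == ["CxCl9"]


class TestExpressionIO:
    def test_roundtrip_bit_identical(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"g{i}" for i in range(5)],
                          columns=["s1", "s2", "s3"])
        path = tmp_path / "expr.tsv"
        write_expression_matrix(df, path)
        back = read_expression_matrix(path)
        assert (back.to_numpy() == df.to_numpy()).all()
        assert list(back.index) == list(df.index)

    def test_transposed_flag(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tg1\tg2\ns1\t1.0\t2.0\ns2\t3.0\t4.0\n")
        df = read_expression_matrix(path, transposed=True)
        assert df.shape == (2, 2)
        assert df.loc["g2", "s1"] == 2.0

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(DataValidationError, match="duplicate header"):
            read_expression_matrix(path)

    def test_ragged_row_reports_line(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t1\n")
        with pytest.raises(DataValidationError, match=":3"):
            read_expression_matrix(path)


class TestGmt:
    def test_single_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\tB\n")
        coll = read_gmt(p)
        assert coll["S1"] == ["A", "B"]

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\nS1\tdesc\tB\n")
        with pytest.raises(DataValidationError, match="duplicate"):
            read_gmt(p)

    def test_short_line_rejected_with_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\nS2\tdesc\n")
        with pytest.raises(DataValidationError, match=":2"):
            read_gmt(p)

    def test_empty_set_rejected_at_construction(self):
        with pytest.raises(DataValidationError):
            GeneSetCollection(sets={"S": []})


class TestMetabolicModelIO:
    def _write(self, tmp_path, reactions, genes):
        doc = {"reactions": reactions, "genes": [{"id": g} for g in genes]}
        p = tmp_path / "model.json"
        p.write_text(json.dumps(doc))
        return p

    def test_toy_model_roundtrip(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                {"id": "R1", "gene_reaction_rule": "A and B", "subsystem": "S1"},
                {"id": "R2", "gene_reaction_rule": "A or C", "subsystem": "S2"},
                {"id": "R3", "gene_reaction_rule": "C", "subsystem": "S1"},
            ],
            ["A", "B", "C"],
        )
        model = read_metabolic_model(p)
        assert len(model.reactions) == 3
        assert model.subsystems == ["S1", "S2"]

    def test_empty_rule_retained_and_flagged(self, tmp_path):
        p = self._write(tmp_path, [{"id": "R1", "gene_reaction_rule": "", "subsystem": ""}], ["A"])
        model = read_metabolic_model(p)
        assert not model.reactions[0].has_gpr

    def test_malformed_rule_names_reaction(self, tmp_path):
        p = self._write(tmp_path, [{"id": "RX", "gene_reaction_rule": "A and", "subsystem": ""}], ["A"])
        with pytest.raises(DataValidationError, match="RX"):
            read_metabolic_model(p)

    def test_unknown_gene_rejected(self, tmp_path):
        p = self._write(tmp_path, [{"id": "R1", "gene_reaction_rule": "A and Z", "subsystem": ""}], ["A"])
        with pytest.raises(DataValidationError, match="unknown genes"):
            read_metabolic_model(p)
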