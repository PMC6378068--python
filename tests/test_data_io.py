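"""Format readers/writers: parsing rules, normalization, round trips."""

import pytest

from netpharm import (
    CompoundTargetEdge,
    DiseaseGeneList,
    EdgeSource,
    FormatError,
    GeneSet,
    GeneSetCollection,
    Namespace,
    PipelineConfig,
    ValidationError,
    read_compound_table,
    read_edge_list,
    read_gene_list,
    read_gmt,
)
from netpharm.data_io import (
    parse_numeric,
    write_compound_table,
    write_edge_list,
    write_gene_list,
    write_gmt,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestCompoundTable:
    def test_parses_adme_columns(self, tmp_path):
        path = _write(
            tmp_path / "c.tsv",
            "mol_id\tname\tob\tdl\tcaco2\n" "MOL000006\tLuteolin\t36.16\t0.25\t0.19\n",
        )
        hl = read_compound_table(path, herb_code="PHP")
        (rec,) = hl.compounds
        assert (rec.ob, rec.dl, rec.caco2) == (36.16, 0.25, 0.19)
        assert rec.herb_sources == {"PHP"}

    def test_parenthesized_cell_is_negative(self):
        assert parse_numeric("(2.22)") == -2.22
        assert parse_numeric(" -0.27 ") == -0.27

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        path = _write(tmp_path / "c.tsv", "mol_id\tname\tob\tdl\tcaco2\n")
        assert len(read_compound_table(path, herb_code="X")) == 0

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path / "c.tsv", "mol_id\tname\tob\tdl\nA\ta\t1\t0.2\n")
        with pytest.raises(FormatError, match="caco2"):
            read_compound_table(path, herb_code="X")

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = _write(
            tmp_path / "c.tsv",
            "mol_id\tname\tob\tdl\tcaco2\nA\ta\toops\t0.2\t0.1\n",
        )
        with pytest.raises(FormatError, match="line 2"):
            read_compound_table(path, herb_code="X")

    def test_duplicate_mol_id_rejected(self, tmp_path):
        path = _write(
            tmp_path / "c.tsv",
            "mol_id\tname\tob\tdl\tcaco2\nA\ta\t31\t0.2\t0.1\nA\tb\t32\t0.3\t0.2\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_compound_table(path, herb_code="X")

    def test_descriptor_columns_collected(self, tmp_path):
        path = _write(
            tmp_path / "c.tsv",
            "mol_id\tname\tob\tdl\tcaco2\tdesc_mw\tdesc_alogp\n"
            "A\ta\t31\t0.2\t0.1\t300.5\t2.1\n",
        )
        (rec,) = read_compound_table(path, herb_code="X").compounds
        assert rec.descriptors == {"mw": 300.5, "alogp": 2.1}

    def test_round_trip_identity(self, tmp_path, representative_table):
        out = tmp_path / "again.tsv"
        write_compound_table(representative_table.compounds, out)
        again = read_compound_table(out, herb_code="WPX")
        assert again.compounds == representative_table.compounds


class TestEdgeList:
    def test_symbols_uppercased(self, tmp_path):
        path = _write(
            tmp_path / "e.tsv",
            "mol_id\tgene_symbol\tsource\tconfidence\nMOL000098\tptgs2\tcurated\t\n",
        )
        (edge,) = read_edge_list(path)
        assert edge.gene_symbol == "PTGS2"
        assert edge.source is EdgeSource.CURATED

    def test_duplicate_pair_keeps_max_confidence(self, tmp_path):
        path = _write(
            tmp_path / "e.tsv",
            "mol_id\tgene_symbol\tsource\tconfidence\n"
            "A\tG1\tpredicted\t0.5\nA\tG1\tpredicted\t0.7\n",
        )
        (edge,) = read_edge_list(path)
        assert edge.confidence == 0.7

    def test_predicted_without_confidence_rejected(self, tmp_path):
        path = _write(
            tmp_path / "e.tsv",
            "mol_id\tgene_symbol\tsource\tconfidence\nA\tG1\tpredicted\t\n",
        )
        with pytest.raises(ValidationError, match="confidence"):
            read_edge_list(path)

    def test_confidence_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            CompoundTargetEdge("A", "G1", EdgeSource.PREDICTED, 1.2)

    def test_round_trip(self, tmp_path):
        edges = [
            CompoundTargetEdge("A", "G1", EdgeSource.CURATED, None),
            CompoundTargetEdge("B", "G2", EdgeSource.PREDICTED, 0.55),
        ]
        out = tmp_path / "e.tsv"
        write_edge_list(edges, out)
        assert read_edge_list(out) == edges


class TestGmt:
    def test_direct_parse_and_dedup(self, tmp_path):
        path = _write(
            tmp_path / "s.gmt",
            "hsa05200\tPathways in cancer\tTP53\tAKT1\ttp53\n",
        )
        coll = read_gmt(path, namespace=Namespace.KEGG)
        (gs,) = coll.sets
        assert gs.genes == {"TP53", "AKT1"}

    def test_short_line_reports_line_number(self, tmp_path):
        path = _write(tmp_path / "s.gmt", "ok\tdesc\tG1\nbad\tdesc\n")
        with pytest.raises(FormatError, match="line 2"):
            read_gmt(path)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert len(read_gmt(_write(tmp_path / "s.gmt", ""))) == 0

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            namespace=Namespace.OTHER,
            sets=[GeneSet("S1", "one", frozenset({"A", "B"})),
                  GeneSet("S2", "two", frozenset({"C"}))],
        )
        out = tmp_path / "s.gmt"
        write_gmt(coll, out)
        again = read_gmt(out)
        assert {(g.set_id, g.genes) for g in again.sets} == {
            (g.set_id, g.genes) for g in coll.sets
        }


class TestGeneList:
    def test_normalizes_and_skips_comments(self, tmp_path):
        path = _write(tmp_path / "g.txt", "# header\ntp53\n CASP3 \n\n")
        assert read_gene_list(path, "gpl").genes == {"TP53", "CASP3"}

    def test_only_comments_is_valid_empty(self, tmp_path):
        path = _write(tmp_path / "g.txt", "# nothing\n")
        assert read_gene_list(path, "gpl").genes == frozenset()

    def test_round_trip(self, tmp_path):
        gl = DiseaseGeneList("gpl", frozenset({"TP53", "CASP3", "PTGS2"}))
        out = tmp_path / "g.txt"
        write_gene_list(gl, out)
        assert read_gene_list(out, "gpl").genes == gl.genes


class TestConfig:
    def test_yaml_round_trip_and_hash(self, tmp_path):
        cfg = PipelineConfig(whitelist={"A": "why"}, modules={"hsa05200": ["apoptosis"]})
        path = tmp_path / "c.yaml"
        cfg.to_yaml(path)
        again = PipelineConfig.from_yaml(path)
        assert again == cfg
        assert again.config_hash == cfg.config_hash
        assert PipelineConfig(fdr_max=0.05).config_hash != cfg.config_hash

    def test_fdr_bounds_enforced(self):
        with pytest.raises(ValidationError):
            PipelineConfig(fdr_max=0.0)
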