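"""Catalog I/O, ortholog matrix assembly and reference ordering."""

import pytest

from genescape.catalog import (
    GeneRecord,
    SpeciesPanel,
    build_ortho_matrix,
    dedup_records,
    order_by_reference,
    read_catalog,
    write_catalog,
    write_fasta,
)
from genescape.errors import AmbiguityError, CatalogFormatError, ConfigError

from conftest import toy_records


class TestGeneRecord:
    def test_symbol_uppercased_and_required(self):
        assert GeneRecord("gg", "slc2a4", "chr17", 5, "t", 100).symbol == "SLC2A4"
        with pytest.raises(CatalogFormatError):
            GeneRecord("gg", "", "chr1", 0)

    def test_position_present_iff_placed(self):
        rec = GeneRecord("gg", "A", "PU", None, "t", 100)
        assert rec.position is None
        with pytest.raises(CatalogFormatError):
            GeneRecord("gg", "A", "PU", 10)
        with pytest.raises(CatalogFormatError):
            GeneRecord("gg", "A", "chr1", None)

    def test_length_must_match_sequence(self):
        GeneRecord("gg", "A", "chr1", 1, "t", 4, transcript_seq="ACGT")
        with pytest.raises(CatalogFormatError):
            GeneRecord("gg", "A", "chr1", 1, "t", 5, transcript_seq="ACGT")


class TestReadWrite:
    def test_round_trip_preserves_fields(self, tmp_path):
        records = toy_records() + [GeneRecord("human", "D4", "PU", None, "t4", 80, gc_percent=61.5)]
        path = tmp_path / "cat.tsv"
        write_catalog(records, path)
        back = read_catalog(path)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert (rt.species, rt.symbol, rt.chromosome, rt.position) == (
                orig.species, orig.symbol, orig.chromosome, orig.position)
            assert rt.transcript_length == orig.transcript_length
            assert rt.gc_percent == orig.gc_percent

    def test_pu_row_with_empty_position(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "species\tsymbol\tchromosome\tposition\ttranscript_id\ttranscript_length\n"
            "gg\tENO3\tPU\t\tt1\t1300\n"
        )
        (rec,) = read_catalog(path)
        assert rec.position is None and rec.chromosome == "PU"

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("species\tsymbol\tchromosome\tposition\ttranscript_id\nx\ty\tchr1\t1\tt\n")
        with pytest.raises(CatalogFormatError, match="transcript_length"):
            read_catalog(path)

    def test_fasta_join_consistency(self, tmp_path):
        seq = "AC" * 850
        rec = GeneRecord("gg", "SLC2A4", "chr17", 5, "t", 1700, transcript_seq=seq)
        write_catalog([rec], tmp_path / "cat.tsv")
        write_fasta([rec], tmp_path / "t.fasta", "transcript")
        (back,) = read_catalog(tmp_path / "cat.tsv", transcript_fasta=tmp_path / "t.fasta")
        assert back.transcript_seq == seq and back.transcript_length == 1700

    def test_conflicting_duplicates_require_policy(self, tmp_path):
        header = "species\tsymbol\tchromosome\tposition\ttranscript_id\ttranscript_length\n"
        path = tmp_path / "cat.tsv"
        path.write_text(header + "gg\tA\tchr1\t1\tt1\t900\ngg\tA\tchr1\t1\tt2\t1200\n")
        with pytest.raises(AmbiguityError):
            read_catalog(path)
        recs = read_catalog(path, dedup="longest")
        assert len(recs) == 1 and recs[0].transcript_length == 1200

    def test_unknown_dedup_policy(self):
        with pytest.raises(ConfigError):
            dedup_records([], policy="shortest")


class TestOrthoMatrix:
    def test_common_set_inclusion_rule(self, small_panel):
        records = [
            # in reference + one non-avian, no birds: retained (the "missing gene" case)
            GeneRecord("human", "LOSTY", "chr1", 1, "t", 100),
            GeneRecord("turtle", "LOSTY", "chr1", 1, "t", 110),
            # only in birds: dropped from the common vertebrate set
            GeneRecord("chicken", "BIRDY", "chr1", 2, "t", 100),
            GeneRecord("tit", "BIRDY", "chr1", 2, "t", 100),
            GeneRecord("goose", "BIRDY", "chr1", 2, "t", 100),
        ]
        m = build_ortho_matrix(records, small_panel)
        assert m.genes == ["LOSTY"]
        assert int(m.presence.loc["LOSTY"].sum()) == 2
        m_all = build_ortho_matrix(records, small_panel, restrict_common=False)
        assert m_all.genes == ["BIRDY", "LOSTY"]

    def test_common_set_never_drops_reference_plus_nonavian(self, small_panel):
        records = [
            GeneRecord("human", "KEEP", "chr1", 1, "t", 100),
            GeneRecord("gar", "KEEP", "chr1", 1, "t", 100),
        ]
        assert build_ortho_matrix(records, small_panel).genes == ["KEEP"]

    def test_duplicate_dedup_longest(self, small_panel):
        records = [
            GeneRecord("human", "A", "chr1", 1, "t", 100),
            GeneRecord("turtle", "A", "chr1", 1, "t", 100),
            GeneRecord("chicken", "A", "chr1", 1, "t1", 900),
            GeneRecord("chicken", "A", "chr1", 1, "t2", 1200),
        ]
        m = build_ortho_matrix(records, small_panel)
        assert m.lengths.loc["A", "chicken"] == 1200.0

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigError):
            SpeciesPanel(reference="human", avian=("human",), non_avian=())


class TestReferenceOrder:
    def test_sort_by_chromosome_then_position(self, small_panel):
        records = [
            GeneRecord("human", "A", "chr1", 100, "t", 100),
            GeneRecord("human", "B", "chr1", 50, "t", 100),
            GeneRecord("human", "C", "chr2", 10, "t", 100),
            GeneRecord("turtle", "A", "chr1", 1, "t", 100),
            GeneRecord("turtle", "B", "chr1", 1, "t", 100),
            GeneRecord("turtle", "C", "chr1", 1, "t", 100),
        ]
        m = build_ortho_matrix(records, small_panel)
        order = order_by_reference(m, [r for r in records if r.species == "human"])
        assert order.ranks == {"B": 0, "A": 1, "C": 2}

    def test_genes_missing_from_reference_dropped(self, small_panel):
        records = []
        for i in range(10):
            records.append(GeneRecord("turtle", f"G{i}", "chr1", i, "t", 100))
            records.append(GeneRecord("human", f"G{i}", "chr1", i * 10, "t", 100))
        m = build_ortho_matrix(records, small_panel)
        ref = [r for r in records if r.species == "human" and r.symbol not in {"G3", "G7"}]
        order = order_by_reference(m, ref)
        assert order.size == 8 and "G3" not in order.ranks

    def test_pu_genes_ranked_last(self, small_panel):
        records = [
            GeneRecord("human", "P1", "PU", None, "t", 100),
            GeneRecord("human", "A", "chr1", 1, "t", 100),
            GeneRecord("human", "B", "chr1", 2, "t", 100),
            GeneRecord("human", "C", "chr2", 1, "t", 100),
        ]
        for r in list(records):
            records.append(GeneRecord("gar", r.symbol, "chr1", 1, "t", 100))
        m = build_ortho_matrix(records, small_panel)
        order = order_by_reference(m, [r for r in records if r.species == "human"])
        assert order.ranks["P1"] == 3
        assert order.unplaced == ["P1"]
        assert order.chromosome_bounds[-1] == ("PU", 3, 4)

    def test_ranks_dense_and_idempotent(self, default_sim):
        from genescape.catalog import build_ortho_matrix

        m = build_ortho_matrix(default_sim.records, default_sim.panel)
        ref = default_sim.records_for("REF1")
        o1 = order_by_reference(m, ref)
        o2 = order_by_reference(m, ref)
        assert o1.symbols == o2.symbols
        assert sorted(o1.ranks.values()) == list(range(o1.size))
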