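"""Alignment I/O, functional typing, filtering, partitioning, summaries."""

import math

import pytest

from trnacif.trna_io import (
    CladeMap,
    FilterRules,
    FormatError,
    MappingError,
    SprinzlAlignment,
    TRNAGeneRecord,
    TypingError,
    assign_functional_types,
    complement_summary,
    filter_predictions,
    leave_one_out_sets,
    partition_by_clade,
    prune_columns,
    read_aligned_genes,
    summary_from_counts,
    write_aligned_genes,
)

from conftest import make_gene


# ---------------------------------------------------------------------------
# reading / writing

class TestReadWrite:
    def test_tabular_round_trip(self, tiny_alignment, tmp_path):
        p = tmp_path / "aln.tsv"
        write_aligned_genes(tiny_alignment, p, format="tabular")
        back = read_aligned_genes(p, format="tabular")
        assert back.coordinates == tiny_alignment.coordinates
        assert back.genes == tiny_alignment.genes

    def test_stockholm_round_trip(self, tiny_alignment, tmp_path):
        p = tmp_path / "aln.sto"
        write_aligned_genes(tiny_alignment, p, format="stockholm")
        back = read_aligned_genes(p, format="stockholm")
        assert back.coordinates == tiny_alignment.coordinates
        assert back.genes == tiny_alignment.genes

    def test_dna_input_normalized_to_rna(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "#coordinates\t1 2 3\n"
            "gene_id\tgenome_id\taligned_seq\n"
            "g1|t1\tg1\tatT\n"
        )
        aln = read_aligned_genes(p)
        assert aln.genes[0].aligned_seq == "AUU"

    def test_ambiguity_codes_become_gaps(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "#coordinates\t1 2 3\ngene_id\tgenome_id\taligned_seq\ng|t\tg\tANR\n"
        )
        assert read_aligned_genes(p).genes[0].aligned_seq == "A--"

    def test_length_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "aln.sto"
        p.write_text(
            "# STOCKHOLM 1.0\n#=GF SPRINZL 1 2 3 4\ng1|t1 ACG\n//\n"
        )
        with pytest.raises(FormatError, match="length 3"):
            read_aligned_genes(p, format="stockholm")

    def test_unknown_symbol_names_gene_and_column(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "#coordinates\t1 2 3\ngene_id\tgenome_id\taligned_seq\ng|t\tg\tA?G\n"
        )
        with pytest.raises(FormatError, match=r"g\|t.*column 1"):
            read_aligned_genes(p)

    def test_missing_coordinate_row_rejected(self, tmp_path):
        p = tmp_path / "aln.sto"
        p.write_text("# STOCKHOLM 1.0\ng1|t1 ACG\n//\n")
        with pytest.raises(FormatError, match="SPRINZL"):
            read_aligned_genes(p, format="stockholm")

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(FormatError, match="unique"):
            SprinzlAlignment(("1", "1"), [])


# ---------------------------------------------------------------------------
# functional typing

class TestFunctionalTyping:
    @pytest.mark.parametrize(
        "anticodon,expected",
        [("GAA", "F"), ("UGC", "A"), ("GCC", "G"), ("CCA", "W"), ("GUG", "H")],
    )
    def test_anticodon_maps_via_standard_code(self, anticodon, expected):
        aln = SprinzlAlignment(
            ("1",), [make_gene("g|t", "g", "A", anticodon=anticodon)]
        )
        typed = assign_functional_types(aln)
        assert typed.genes[0].functional_type == expected

    def test_explicit_label_kept_regardless_of_policy(self):
        aln = SprinzlAlignment(
            ("1",), [make_gene("g|t", "g", "A", ftype="X", anticodon="CAU")]
        )
        for policy in ("labels_required", "default_M", "default_J"):
            assert assign_functional_types(aln, policy).genes[0].functional_type == "X"

    def test_cau_without_label_requires_policy(self):
        aln = SprinzlAlignment(("1",), [make_gene("g|t", "g", "A", anticodon="CAU")])
        with pytest.raises(TypingError, match="CAU"):
            assign_functional_types(aln, "labels_required")
        assert assign_functional_types(aln, "default_M").genes[0].functional_type == "M"
        assert assign_functional_types(aln, "default_J").genes[0].functional_type == "J"

    def test_stop_decoding_anticodon_rejected(self):
        # anticodon UUA -> codon UAA (stop)
        aln = SprinzlAlignment(("1",), [make_gene("g|t", "g", "A", anticodon="UUA")])
        with pytest.raises(TypingError, match="stop"):
            assign_functional_types(aln)

    def test_unknown_class_symbol_rejected(self):
        with pytest.raises(TypingError):
            make_gene("g|t", "g", "A", ftype="B")


# ---------------------------------------------------------------------------
# prediction filtering

class TestFilterPredictions:
    def test_anticodon_whitelist(self):
        genes = [
            make_gene("a", "g", "A", anticodon="GAA"),
            make_gene("b", "g", "A", anticodon="UGC"),
            make_gene("c", "g", "A", anticodon="AAA"),
        ]
        aln = SprinzlAlignment(("1",), genes)
        kept, log = filter_predictions(
            aln, FilterRules(anticodon_whitelist={"GAA", "UGC"})
        )
        assert [g.gene_id for g in kept.genes] == ["a", "b"]
        assert log == [("c", "anticodon_whitelist")]

    def test_no_rules_is_identity(self, tiny_alignment):
        kept, log = filter_predictions(tiny_alignment, FilterRules())
        assert kept.genes == tiny_alignment.genes and log == []

    def test_intron_blacklist_removes_flagged_isotype(self):
        genes = [
            make_gene("a", "g", "A", ftype="L", intron=True),
            make_gene("b", "g", "A", ftype="F", intron=True),
            make_gene("c", "g", "A", ftype="L", intron=False),
        ]
        aln = SprinzlAlignment(("1",), genes)
        kept, log = filter_predictions(
            aln, FilterRules(intron_isotype_blacklist={"L"})
        )
        assert [g.gene_id for g in kept.genes] == ["b", "c"]
        assert log == [("a", "intron_isotype_blacklist")]

    def test_config_file_round_trip(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("anticodon_whitelist: [gaa, TGC]\n")
        rules = FilterRules.from_config(cfg)
        assert rules.anticodon_whitelist == {"GAA", "UGC"}

    def test_malformed_config_rejected(self, tmp_path):
        cfg = tmp_path / "rules.yaml"
        cfg.write_text("- just\n- a list\n")
        with pytest.raises(ValueError, match="key-value"):
            FilterRules.from_config(cfg)


# ---------------------------------------------------------------------------
# column pruning

class TestPruneColumns:
    def _aln_with_gap_column(self, n_gaps, n_genes=100):
        genes = []
        for i in range(n_genes):
            c2 = "-" if i < n_gaps else "G"
            genes.append(make_gene(f"g{i}|t", f"g{i}", f"A{c2}C", "L"))
        return SprinzlAlignment(("1", "2", "3"), genes)

    def test_column_at_threshold_removed(self):
        pruned = prune_columns(self._aln_with_gap_column(99), gap_threshold=0.99)
        assert pruned.coordinates == ("1", "3")

    def test_column_below_threshold_retained(self):
        pruned = prune_columns(self._aln_with_gap_column(98), gap_threshold=0.99)
        assert pruned.coordinates == ("1", "2", "3")

    def test_drop_coordinates_removed(self, tiny_alignment):
        pruned = prune_columns(tiny_alignment, drop_coordinates={"20a", "21"})
        assert pruned.coordinates == ("1", "2", "3")
        assert pruned.genes[0].aligned_seq == "ACG"

    def test_idempotent_at_fixed_threshold(self):
        once = prune_columns(self._aln_with_gap_column(99), gap_threshold=0.99)
        twice = prune_columns(once, gap_threshold=0.99)
        assert once == twice

    def test_all_columns_removed_is_error(self):
        aln = SprinzlAlignment(("1",), [make_gene("g|t", "g", "-")])
        with pytest.raises(FormatError, match="every"):
            prune_columns(aln, gap_threshold=0.5)


# ---------------------------------------------------------------------------
# clade partitioning and leave-one-out sets

class TestPartition:
    def test_small_clades_excluded_with_report(self):
        genes = [make_gene(f"gA{i}|t{j}", f"gA{i}", "A", "L")
                 for i in range(3) for j in range(50)]
        genes += [make_gene(f"gB{i}|t{j}", f"gB{i}", "A", "L")
                  for i in range(2) for j in range(50)]
        aln = SprinzlAlignment(("1",), genes)
        cmap = CladeMap(
            {f"gA{i}": "A" for i in range(3)} | {f"gB{i}": "B" for i in range(2)},
            min_gene_count=120,
        )
        part = partition_by_clade(aln, cmap)
        assert set(part.clade_genes) == {"A"}
        assert part.excluded == {"B": 100}

    def test_aliases_fuse_clades(self):
        cmap = CladeMap({"g1": "B2", "g2": "B3"}, min_gene_count=1,
                        aliases={"B2": "B2+3", "B3": "B2+3"})
        genes = [make_gene("g1|t", "g1", "A", "L"), make_gene("g2|t", "g2", "A", "L")]
        part = partition_by_clade(SprinzlAlignment(("1",), genes), cmap)
        assert set(part.clade_genes) == {"B2+3"}
        assert len(part.clade_genes["B2+3"]) == 2

    def test_unmapped_genome_is_error(self, tiny_alignment):
        cmap = CladeMap({"g1": "A"}, min_gene_count=1)
        with pytest.raises(MappingError, match="g2"):
            partition_by_clade(tiny_alignment, cmap)

    def test_query_only_genomes_skipped(self, tiny_alignment):
        cmap = CladeMap({"g1": "A", "g2": "A"}, min_gene_count=1)
        part = partition_by_clade(tiny_alignment, cmap, query_only={"g3"})
        assert {g.genome_id for g in part.clade_genes["A"]} == {"g1", "g2"}

    def test_empty_clade_map_is_error(self, tiny_alignment):
        with pytest.raises(MappingError, match="empty"):
            partition_by_clade(tiny_alignment, CladeMap({}, min_gene_count=1))

    def test_partition_union_preserves_gene_multiset(
        self, tiny_alignment, tiny_clade_map
    ):
        part = partition_by_clade(tiny_alignment, tiny_clade_map)
        pooled = [g for genes in part.clade_genes.values() for g in genes]
        assert sorted(g.gene_id for g in pooled) == sorted(
            g.gene_id for g in tiny_alignment.genes
        )

    def test_leave_one_out_removes_only_own_clade_genes(
        self, tiny_alignment, tiny_clade_map
    ):
        part = partition_by_clade(tiny_alignment, tiny_clade_map)
        loo = leave_one_out_sets(part, "g1")
        assert {g.genome_id for g in loo["A"]} == {"g2"}
        assert loo["B"] == part.clade_genes["B"]

    def test_leave_one_out_noop_for_unknown_genome(
        self, tiny_alignment, tiny_clade_map
    ):
        part = partition_by_clade(tiny_alignment, tiny_clade_map)
        assert leave_one_out_sets(part, "nope") == part.clade_genes

    def test_leave_one_out_empties_singleton_clade(self, tiny_alignment, tiny_clade_map):
        part = partition_by_clade(tiny_alignment, tiny_clade_map)
        with pytest.raises(MappingError, match="empties"):
            leave_one_out_sets(part, "g3")


# ---------------------------------------------------------------------------
# summaries

class TestComplementSummary:
    def test_printed_count_ratios(self):
        # genes-per-genome and bases-per-gene from published-scale counts
        assert summary_from_counts(27, 1395, 101640) == {
            "genes_per_genome": 51.67,
            "bases_per_gene": 72.86,
        }
        assert summary_from_counts(11, 555, 40362) == {
            "genes_per_genome": 50.45,
            "bases_per_gene": 72.72,
        }

    def test_uniform_composition_single_gene(self):
        df = complement_summary({"g": [make_gene("g|t", "g", "ACGU", "L")]})
        row = df.loc["g"]
        assert row.bases == 4
        assert (row[["pct_A", "pct_U", "pct_G", "pct_C"]] == 25.0).all()

    def test_percentages_sum_to_100(self, tiny_alignment, tiny_clade_map):
        part = partition_by_clade(tiny_alignment, tiny_clade_map)
        df = complement_summary(part)
        sums = df[["pct_A", "pct_U", "pct_G", "pct_C"]].sum(axis=1)
        assert ((sums - 100).abs() <= 0.2).all()

    def test_gaps_not_counted_as_bases(self):
        df = complement_summary({"g": [make_gene("g|t", "g", "A--U", "L")]})
        assert df.loc["g", "bases"] == 2
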