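"""Reference database: parsing, curation, clustering, persistence."""

import numpy as np
import pytest

from conftest import oracle_infix_edit_distance, random_dna
from markerpeek.refdb import (MarkerFormatError, MarkerRecord, ReferenceDB,
                              build_reference_db, clean_records,
                              cluster_nonredundant, concat_rpob_fragments,
                              default_length_window, global_identity,
                              load_marker_fasta, parse_header)


def rec(rid, seq, gene="16S", genus="Escherichia", species="coli", **kw):
    molecule = "nucleotide" if gene in ("16S", "18S") else "protein"
    return MarkerRecord(rid, gene, molecule, genus, species, seq, **kw)


class TestLoading:
    def test_two_entries_parse(self, tmp_path):
        fa = tmp_path / "refs.fa"
        fa.write_text(">a|Escherichia|coli\nacgt\n"
                      ">b|Salmonella|enterica|LT2\nGGCC\n")
        records = load_marker_fasta(fa, "16S", "nucleotide")
        assert len(records) == 2
        assert records[0].sequence == "ACGT"  # uppercased
        assert records[1].strain == "LT2"

    def test_missing_taxonomy_is_an_error(self, tmp_path):
        fa = tmp_path / "bad.fa"
        fa.write_text(">x\nACGT\n")
        with pytest.raises(MarkerFormatError, match="x"):
            load_marker_fasta(fa, "16S", "nucleotide")

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        fa = tmp_path / "empty.fa"
        fa.write_text("")
        assert load_marker_fasta(fa, "16S", "nucleotide") == []

    def test_header_roundtrip(self):
        assert parse_header("id1|Vibrio|cholerae") == \
            ("id1", "Vibrio", "cholerae", None)

    def test_molecule_gene_consistency_enforced(self):
        with pytest.raises(MarkerFormatError):
            MarkerRecord("x", "16S", "protein", "G", "s", "MKT")
        with pytest.raises(MarkerFormatError):
            MarkerRecord("x", "recA", "nucleotide", "G", "s", "ACGT")


class TestCleaning:
    def test_exact_duplicates_collapse_to_first(self):
        records = [rec("a", "ACGT" * 30), rec("b", "ACGT" * 30),
                   rec("c", "TTTT" * 30)]
        out = clean_records(records, 0, 10**6, 1.0)
        assert [r.record_id for r in out] == ["a", "c"]

    def test_length_window_applied(self):
        records = [rec("short", "ACGTACGTAC"), rec("ok", "A" * 150)]
        out = clean_records(records, 100, 200, 1.0)
        assert [r.record_id for r in out] == ["ok"]

    def test_ambiguous_fraction_filter(self):
        out = clean_records([rec("n", "ACGTNNNNNN")], 0, 100, 0.05)
        assert out == []

    def test_empty_input(self):
        assert clean_records([], 0, 10, 0.1) == []

    def test_default_window_tracks_median(self):
        records = [rec(str(i), "A" * 100) for i in range(5)]
        lo, hi = default_length_window(records)
        assert lo == 50 and hi >= 150


class TestRpoB:
    def test_fragments_concatenated(self):
        records = [rec("bp", "M" * 400, gene="rpoB"),
                   rec("bpp", "K" * 800, gene="rpoB")]
        out = concat_rpob_fragments(records, {"bp": "bpp"})
        assert len(out) == 1
        assert len(out[0].sequence) == 1200
        assert out[0].sequence.startswith("M")

    def test_unpaired_record_passes_through(self):
        records = [rec("solo", "M" * 500, gene="rpoB")]
        assert concat_rpob_fragments(records, {}) == records

    def test_missing_partner_is_error(self):
        records = [rec("bp", "M" * 400, gene="rpoB")]
        with pytest.raises(MarkerFormatError):
            concat_rpob_fragments(records, {"bp": "absent"})

    def test_cross_taxon_pairing_is_error(self):
        records = [rec("bp", "M" * 400, gene="rpoB"),
                   rec("bpp", "K" * 800, gene="rpoB", species="enterica")]
        with pytest.raises(MarkerFormatError):
            concat_rpob_fragments(records, {"bp": "bpp"})


class TestClustering:
    def test_identical_sequences_form_one_cluster(self):
        seq = "ACGT" * 50
        reps, cmap = cluster_nonredundant([rec("a", seq), rec("b", seq)])
        assert len(reps) == 1
        assert sorted(cmap[reps[0].record_id]) == ["a", "b"]

    def test_similar_pair_plus_outlier(self, rng):
        base = random_dna(rng, 300)
        near = list(base)
        for p in rng.choice(300, 15, replace=False):  # 95% identity
            near[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[p]]
        other = random_dna(rng, 300)
        # confirm the fixture with the brute-force oracle
        sim = "".join(near)
        assert 1 - oracle_infix_edit_distance(sim, base) / 300 >= 0.95
        assert 1 - oracle_infix_edit_distance(other, base) / 300 < 0.70
        reps, cmap = cluster_nonredundant(
            [rec("a", base), rec("b", sim), rec("c", other)])
        assert len(reps) == 2
        assert sum(len(v) for v in cmap.values()) == 3

    def test_member_identity_meets_threshold(self, rng):
        # threshold soundness checked with the independent oracle
        records = []
        for i in range(6):
            base = random_dna(rng, 120)
            records.append(rec(f"r{i}", base))
            mutant = list(base)
            for p in rng.choice(120, int(rng.integers(2, 10)), replace=False):
                mutant[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[p]]
            records.append(rec(f"r{i}m", "".join(mutant)))
        reps, cmap = cluster_nonredundant(records, 0.90)
        by_id = {r.record_id: r for r in records}
        for rep_id, members in cmap.items():
            for mem in members:
                a, b = by_id[mem].sequence, by_id[rep_id].sequence
                short, long_ = (a, b) if len(a) <= len(b) else (b, a)
                ident = 1 - oracle_infix_edit_distance(short, long_) / len(short)
                assert ident >= 0.90 or mem == rep_id

    def test_partition_covers_every_record(self, rng):
        records = [rec(f"r{i}", random_dna(rng, int(rng.integers(80, 140))))
                   for i in range(20)]
        reps, cmap = cluster_nonredundant(records, 0.90)
        all_members = [m for v in cmap.values() for m in v]
        assert sorted(all_members) == sorted(r.record_id for r in records)

    def test_mixed_genes_rejected(self):
        with pytest.raises(MarkerFormatError):
            cluster_nonredundant([rec("a", "ACGT" * 30),
                                  rec("b", "M" * 100, gene="recA")])

    def test_empty_input(self):
        assert cluster_nonredundant([]) == ([], {})

    def test_identity_definition_agrees_with_oracle(self, rng):
        for _ in range(10):
            a = random_dna(rng, int(rng.integers(30, 80)))
            b = random_dna(rng, int(rng.integers(30, 80)))
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            expected = max(
                0.0, 1 - oracle_infix_edit_distance(short, long_) / len(short))
            assert global_identity(a, b) == pytest.approx(expected)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, two_species):
        records, _, db = two_species
        db.save(tmp_path / "db")
        loaded = ReferenceDB.load(tmp_path / "db")
        assert sorted(loaded.genes) == sorted(db.genes)
        for gene in db.genes:
            assert [r.record_id for r in loaded.full[gene]] == \
                [r.record_id for r in db.full[gene]]
            assert [r.sequence for r in loaded.nonredundant[gene]] == \
                [r.sequence for r in db.nonredundant[gene]]
            assert loaded.cluster_map[gene] == db.cluster_map[gene]
        # source nucleotide sequences survive the roundtrip
        assert all(r.source_nt for r in loaded.full["recA"])

    def test_build_is_deterministic(self, two_species):
        records, _, _ = two_species
        a = build_reference_db(records, clean=False)
        b = build_reference_db(records, clean=False)
        for gene in a.genes:
            assert [r.record_id for r in a.nonredundant[gene]] == \
                [r.record_id for r in b.nonredundant[gene]]
            assert a.cluster_map[gene] == b.cluster_map[gene]
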