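"""Read simulator, synthetic references and contamination series."""

import numpy as np
import pytest
from scipy import stats

from markerpeek.refdb import NUCLEOTIDE_GENES, global_identity
from markerpeek.simdata import (MixtureSpec, ReadSimProfile,
                                contamination_fractions,
                                largest_remainder_counts, make_mixture,
                                make_synthetic_references, mixture_series,
                                reconstruct_read, sample_error_positions,
                                simulate_reads, trim_reads)


class TestProfile:
    def test_negative_polynomial_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ReadSimProfile(positional_poly=(1, -5, 0, 0, 0))

    def test_defaults_are_illumina_like(self):
        p = ReadSimProfile()
        assert p.read_length == 101
        assert p.sub_to_indel_ratio == 4.0


class TestErrorPositions:
    def test_constant_polynomial_is_uniform(self):
        profile = ReadSimProfile(positional_poly=(1, 0, 0, 0, 0), seed=42)
        draws = sample_error_positions(profile, 100_000)
        counts = np.bincount(draws, minlength=101)
        _, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_quartic_polynomial_skews_to_3prime(self):
        profile = ReadSimProfile(positional_poly=(0, 0, 0, 0, 1), seed=42)
        draws = sample_error_positions(profile, 50_000)
        assert draws.mean() / 100 > 0.5

    def test_zero_draws(self):
        assert len(sample_error_positions(ReadSimProfile(), 0)) == 0


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        profile = ReadSimProfile(n_reads=50, total_error_rate=0.0, seed=1)
        reads, truth = simulate_reads(genome, profile)
        from markerpeek.alncore import revcomp
        for (rid, seq), t in zip(reads, truth.reads):
            frag = genome[t.start:t.end]
            if t.strand == "-":
                frag = revcomp(frag)
            assert seq == frag
            assert not t.subs and not t.ins and not t.dels

    def test_pre_indel_length_is_profile_length(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        profile = ReadSimProfile(n_reads=300, total_error_rate=0.05, seed=2)
        reads, truth = simulate_reads(genome, profile)
        for (rid, seq), t in zip(reads, truth.reads):
            assert t.end - t.start == 101
            assert len(seq) == 101 + len(t.ins) - len(t.dels)

    def test_truth_replay_reconstructs_reads(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        profile = ReadSimProfile(n_reads=200, total_error_rate=0.03, seed=3)
        reads, truth = simulate_reads(genome, profile, genome_id="g")
        genomes = {"g": genome}
        for (rid, seq), t in zip(reads, truth.reads):
            assert reconstruct_read(t, genomes) == seq

    def test_substitution_indel_ratio_near_four(self, rng):
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        profile = ReadSimProfile(n_reads=20_000, total_error_rate=0.01,
                                 seed=4)
        _, truth = simulate_reads(genome, profile)
        n_sub, n_indel = truth.n_substitutions(), truth.n_indels()
        ratio = n_sub / n_indel
        # 3-sigma binomial tolerance around 4:1 at this error volume
        n = n_sub + n_indel
        sigma = 3 * np.sqrt(0.8 * 0.2 / n) * 25  # d(ratio)/d(p) = 1/(1-p)^2
        assert ratio == pytest.approx(4.0, abs=sigma)

    def test_deterministic_under_seed(self):
        genome = "ACGT" * 500
        profile = ReadSimProfile(n_reads=100, total_error_rate=0.02, seed=9)
        r1, t1 = simulate_reads(genome, profile)
        r2, t2 = simulate_reads(genome, profile)
        assert r1 == r2
        assert t1 == t2

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT", ReadSimProfile())


class TestSyntheticReferences:
    def test_pairwise_divergence_near_target(self, two_species):
        records, _, _ = two_species
        for gene, recs in records.items():
            nts = [r.source_nt or r.sequence for r in recs]
            ident = global_identity(nts[0], nts[1])
            assert ident == pytest.approx(0.90, abs=0.02)

    def test_single_species_db(self):
        records, genomes = make_synthetic_references(1, 0.10, seed=5)
        assert all(len(v) == 1 for v in records.values())
        assert len(genomes) == 1

    def test_determinism(self):
        a = make_synthetic_references(2, 0.08, seed=6)
        b = make_synthetic_references(2, 0.08, seed=6)
        assert a[1] == b[1]
        assert [(r.record_id, r.sequence) for g in a[0] for r in a[0][g]] == \
            [(r.record_id, r.sequence) for g in b[0] for r in b[0][g]]

    def test_indistinguishable_divergence_rejected(self):
        with pytest.raises(ValueError, match="distinguishable"):
            make_synthetic_references(2, 0.001, seed=7)

    def test_markers_embedded_in_genomes(self, two_species):
        records, genomes, _ = two_species
        for gene, recs in records.items():
            for rec in recs:
                sp = rec.record_id.split("_")[-1]
                nt = rec.source_nt or rec.sequence
                assert nt in genomes[sp]

    def test_protein_references_are_stop_free(self, two_species):
        records, _, _ = two_species
        for gene, recs in records.items():
            if gene in NUCLEOTIDE_GENES:
                continue
            for rec in recs:
                assert "*" not in rec.sequence

    def test_16s_copy_number_is_respected(self):
        records, genomes = make_synthetic_references(
            2, 0.10, seed=8, copy_16s=[2, 1])
        seq = records["16S"][0].sequence
        assert genomes["sp0"].count(seq) == 2
        assert genomes["sp1"].count(records["16S"][1].sequence) == 1


class TestMixtures:
    def test_largest_remainder_exact(self):
        assert largest_remainder_counts([0.98, 0.02], 1000) == [980, 20]
        assert sum(largest_remainder_counts([1 / 3, 1 / 3, 1 / 3], 100)) == 100

    def test_zero_fraction_contributes_nothing(self, two_species):
        _, genomes, _ = two_species
        profile = ReadSimProfile(n_reads=200, total_error_rate=0.0, seed=10)
        spec = MixtureSpec([("sp0", 1.0), ("sp1", 0.0)])
        reads, truth = make_mixture(genomes, spec, profile)
        assert len(reads) == 200
        assert all(t.genome_id == "sp0" for t in truth.reads)

    def test_missing_genome_is_error(self, two_species):
        _, genomes, _ = two_species
        spec = MixtureSpec([("sp0", 0.5), ("ghost", 0.5)])
        with pytest.raises(KeyError):
            make_mixture(genomes, spec, ReadSimProfile())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec([("a", 0.5), ("b", 0.6)])
        with pytest.raises(ValueError):
            MixtureSpec([("a", -0.1), ("b", 1.1)])

    def test_contamination_series_has_25_points(self):
        fracs = contamination_fractions()
        assert len(fracs) == 25
        assert fracs[:6] == [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]
        assert fracs[-1] == 1.0

    def test_series_counts_match_fractions(self, two_species):
        _, genomes, _ = two_species
        profile = ReadSimProfile(n_reads=100, total_error_rate=0.0, seed=11)
        for frac, reads, truth in mixture_series(
                genomes, "sp0", "sp1", profile, fractions=[0.0, 0.05, 0.5]):
            n_contam = sum(t.genome_id == "sp1" for t in truth.reads)
            assert n_contam == round(frac * 100)


class TestTrim:
    def test_long_reads_truncated(self):
        reads = [("a", "A" * 145)]
        assert trim_reads(reads, 100) == [("a", "A" * 100)]

    def test_short_reads_unchanged(self):
        reads = [("a", "A" * 80)]
        assert trim_reads(reads, 100) == reads

    def test_length_one(self):
        assert trim_reads([("a", "ACGT")], 1) == [("a", "A")]
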