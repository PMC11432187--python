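"""SELEX read processing, 10-mer enrichment, and motif construction."""

import collections

import numpy as np
import pytest
from scipy import stats

from stalkscape import selex
from stalkscape.selex import (
    IUPAC_SETS,
    Motif,
    SelexLibrary,
    build_motif,
    count_kmers,
    dedupe_reads,
    find_seeds,
    kmer_enrichment,
    kmer_to_code,
    motif_fold_change,
    read_library,
    revcomp,
    shuffle_library,
    write_library,
)

from conftest import random_reads


def naive_kmer_counts(reads, k):
    """Quadratic substring-scan oracle, both strands."""
    counts = collections.Counter()
    for r in reads:
        for s in (r, revcomp(r)):
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
    return counts


class TestIO:
    @pytest.mark.parametrize("name", ["lib.fasta", "lib.fastq"])
    def test_round_trip(self, tmp_path, name):
        rng = np.random.default_rng(0)
        lib = SelexLibrary(random_reads(rng, 20, 50), round_index=2)
        path = tmp_path / name
        write_library(lib, path)
        back = read_library(path, round_index=2)
        assert back.reads == lib.reads


class TestDedupe:
    def test_identical_reads_collapse(self):
        lib = SelexLibrary(["ACGTACGTAC"] * 3)
        out = dedupe_reads(lib)
        assert len(out) == 1 and out.n_duplicates_removed == 2
        assert out.deduplicated

    def test_unique_library_unchanged(self):
        rng = np.random.default_rng(1)
        lib = SelexLibrary(random_reads(rng, 50, 30))
        assert dedupe_reads(lib).reads == lib.reads

    def test_duplicate_accounting(self):
        rng = np.random.default_rng(2)
        base = random_reads(rng, 40, 25)
        lib = SelexLibrary(base + base[:13])
        out = dedupe_reads(lib)
        assert len(out) == 40 and out.n_duplicates_removed == 13

    def test_unequal_lengths_rejected_with_report(self):
        lib = SelexLibrary(["ACGT", "ACGTA"])
        with pytest.raises(ValueError, match=r"\[4, 5\]"):
            dedupe_reads(lib)


class TestShuffle:
    def test_homopolymer_unchanged(self):
        lib = SelexLibrary(["AAAAAAAA", "TTTTTTTT"])
        out = shuffle_library(lib, seed=0)
        assert out.reads == lib.reads

    def test_reads_are_anagrams(self):
        rng = np.random.default_rng(3)
        lib = SelexLibrary(random_reads(rng, 30, 40))
        out = shuffle_library(lib, seed=1)
        for a, b in zip(lib.reads, out.reads):
            assert sorted(a) == sorted(b)
            assert a != b or len(set(a)) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        lib = SelexLibrary(random_reads(rng, 10, 30))
        assert shuffle_library(lib, seed=7).reads == shuffle_library(lib, seed=7).reads

    def test_dinucleotide_structure_destroyed_to_mononucleotide_null(self):
        # reads made of alternating AC: shuffling must spread dinucleotides
        # to the frequencies implied by base composition alone
        lib = SelexLibrary(["AC" * 25] * 2000)
        out = shuffle_library(lib, seed=5)
        counts = collections.Counter()
        for r in out.reads:
            for i in range(len(r) - 1):
                counts[r[i : i + 2]] += 1
        total = sum(counts.values())
        # permutation of a fixed 25A/25C composition: without-replacement
        # probabilities for same-base vs different-base dinucleotides
        p_same = 25 * 24 / (50 * 49)
        p_diff = 25 * 25 / (50 * 49)
        expected = {"AA": p_same, "CC": p_same, "AC": p_diff, "CA": p_diff}
        chi2 = sum(
            (counts[d] - total * p) ** 2 / (total * p) for d, p in expected.items()
        )
        assert stats.chi2.sf(chi2, df=3) > 1e-4

    def test_repeats_pool_shuffles(self):
        rng = np.random.default_rng(6)
        lib = SelexLibrary(random_reads(rng, 15, 20))
        out = shuffle_library(lib, seed=2, repeats=4)
        assert len(out) == 60


class TestKmerCounts:
    def test_matches_naive_substring_oracle(self):
        rng = np.random.default_rng(7)
        lib = SelexLibrary(random_reads(rng, 100, 35))
        counts, total = count_kmers(lib, k=10)
        oracle = naive_kmer_counts(lib.reads, 10)
        assert total == sum(oracle.values())
        for kmer, c in oracle.items():
            assert counts[kmer_to_code(kmer)] == c
        assert counts.sum() == total

    def test_window_count_conservation(self):
        rng = np.random.default_rng(8)
        lib = SelexLibrary(random_reads(rng, 60, 101))
        counts, total = count_kmers(lib, k=10)
        assert total == 2 * 60 * (101 - 10 + 1)

    def test_reverse_complement_symmetry_exact(self):
        rng = np.random.default_rng(9)
        lib = SelexLibrary(random_reads(rng, 40, 60))
        counts, _ = count_kmers(lib, k=6)
        rc = selex._rc_table(6)
        np.testing.assert_array_equal(counts, counts[rc])

    def test_k_longer_than_read_errors(self):
        lib = SelexLibrary(["ACGTA"])
        with pytest.raises(ValueError, match="exceeds read length"):
            count_kmers(lib, k=10)


class TestEnrichment:
    def test_library_against_itself_is_flat(self):
        rng = np.random.default_rng(10)
        lib = SelexLibrary(random_reads(rng, 50, 40))
        ke = kmer_enrichment(lib, lib, k=8)
        np.testing.assert_allclose(ke.enrichment, 1.0)

    def test_ratio_definition(self):
        # 5 occurrences vs 1 at matched depth: enrichment -> 5 as eps -> 0
        w = "ACCGTATTGC"
        filler = random_reads(np.random.default_rng(11), 995, 10)
        sel = SelexLibrary([w] * 5 + filler)
        null = SelexLibrary([w] * 1 + filler[: len(filler)] + random_reads(
            np.random.default_rng(12), 4, 10))
        ke = kmer_enrichment(sel, null, k=10, pseudocount=1e-12)
        assert ke.enrichment_of(w) == pytest.approx(5.0, rel=1e-3)
        assert ke.enrichment_of(revcomp(w)) == pytest.approx(ke.enrichment_of(w))

    def test_rank_and_table_consistent(self, selex_run):
        ke = selex_run["ke"]
        top = ke.top_table(10)
        assert ke.rank_of(top["kmer"].iloc[0]) == 1
        assert (np.diff(top["enrichment"]) <= 0).all()


class TestSeedsAndMotif:
    def test_single_sequence_library_one_hot_pwm(self):
        seedkmer = "ACGTACGTTG"
        sel = SelexLibrary([seedkmer])
        null = SelexLibrary(["A" * 10])
        ke = kmer_enrichment(sel, null, k=10)
        motif = build_motif(ke, sel, extend=0, seed=seedkmer)
        assert motif.consensus == seedkmer
        onehot = np.zeros((4, 10))
        for j, b in enumerate(seedkmer):
            onehot["ACGT".index(b), j] = 1.0
        np.testing.assert_allclose(motif.pwm, onehot)

    def test_no_signal_raises(self):
        rng = np.random.default_rng(13)
        lib = SelexLibrary(random_reads(rng, 30, 40))
        ke = kmer_enrichment(lib, lib, k=10)
        with pytest.raises(ValueError, match="no signal"):
            build_motif(ke, lib)

    def test_seed_is_local_maximum(self, selex_run):
        ke = selex_run["ke"]
        (seed,) = find_seeds(ke, n=1)
        e = ke.enrichment
        code = kmer_to_code(seed)
        neighbors = selex._single_sub_neighbors(code, 10)
        assert (e[neighbors] <= e[code]).all()

    def test_two_planted_motifs_found_as_distinct_seeds(self):
        rng = np.random.default_rng(14)
        m1, m2 = "TTACGCGTAA", "AGGGTTTCCC"
        reads = []
        for r in random_reads(rng, 3000, 50):
            roll = rng.random()
            if roll < 0.25:
                p = rng.integers(0, 40)
                r = r[:p] + m1 + r[p + 10 :]
            elif roll < 0.5:
                p = rng.integers(0, 40)
                r = r[:p] + m2 + r[p + 10 :]
            reads.append(r)
        sel = SelexLibrary(reads)
        null = shuffle_library(sel, seed=3, repeats=5)
        ke = kmer_enrichment(sel, null, k=10)
        seeds = find_seeds(ke, n=2)
        assert len(seeds) == 2
        hits = {
            planted: max(selex._alignment_identity(s, planted) for s in seeds)
            for planted in (m1, m2)
        }
        assert all(v >= 0.8 for v in hits.values())

    def test_planted_consensus_recovered_in_simulation(self, selex_cfg, selex_run):
        motif = build_motif(selex_run["ke"], selex_run["r4"], extend=2)
        core = motif.consensus[motif.core_offset : motif.core_offset + 10]
        planted = selex_cfg.consensus
        matches = max(
            sum(p in IUPAC_SETS[c] for p, c in zip(cand, core))
            for cand in (planted, revcomp(planted))
        )
        assert matches >= 8


class TestFoldChange:
    def test_selected_equals_null_fold_one(self):
        rng = np.random.default_rng(15)
        lib = SelexLibrary(random_reads(rng, 40, 40))
        motif = Motif(np.full((4, 8), 0.25), "A" * 8, "N" * 8, 0.0)
        assert motif_fold_change(motif, lib, lib) == pytest.approx(1.0)

    def test_motif_absent_from_both_fold_one(self):
        rng = np.random.default_rng(16)
        a = SelexLibrary(["AT" * 20] * 30)
        b = SelexLibrary(["TA" * 20] * 30)
        pwm = np.full((4, 8), 0.01)
        pwm[1] = 0.97  # strict C-run motif, absent from AT-only reads
        motif = Motif(pwm, "C" * 8, "C" * 8, 10.0)
        assert motif_fold_change(motif, a, b) == pytest.approx(1.0)

    def test_planted_motif_beats_scrambled_columns(self, selex_run):
        r4, null, ke = selex_run["r4"], selex_run["null"], selex_run["ke"]
        motif = build_motif(ke, r4, extend=2)
        rng = np.random.default_rng(17)
        scrambled = Motif(
            motif.pwm[:, rng.permutation(motif.length)],
            motif.seed, motif.consensus, motif.match_threshold,
            motif.background, motif.core_offset,
        )
        assert motif_fold_change(motif, r4, null) > motif_fold_change(
            scrambled, r4, null
        )


class TestReplicateAgreement:
    def test_log_enrichment_correlates_between_replicates(
        self, selex_run, selex_replicate
    ):
        r = selex.replicate_enrichment_correlation(
            selex_run["ke"], selex_replicate["ke"]
        )
        assert r > 0.9
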