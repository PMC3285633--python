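"""Read-back mapping, chimericity, Contig Score, N50, scaftigs."""
import re
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgsim import (
    Genome,
    assembly_summary,
    assess_contigs,
    best_hsp,
    classify_chimeric,
    contig_score,
    degree_of_chimericity,
    extract_scaftigs,
    generate_synthetic_genome,
    genome_coverage,
    majority_genome,
    map_reads_to_genomes,
    n50,
    reverse_complement,
)
from mgsim.assess import Alignment


class TestReadMapping:
    def test_error_free_read_maps_at_truth_locus(self, small_genomes):
        genome = small_genomes[0]
        read = genome.sequence[4000:4075]
        (aln,) = map_reads_to_genomes([("r1", read)], [genome])
        assert (aln.genome_id, aln.start, aln.end, aln.strand, aln.n_mismatches) == (
            genome.id, 4000, 4075, "+", 0,
        )

    def test_two_mismatches_found_three_not(self, small_genomes):
        genome = small_genomes[0]
        window = list(genome.sequence[1000:1075])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for pos in (10, 40):
            window[pos] = flip[window[pos]]
        hits = map_reads_to_genomes([("two", "".join(window))], [genome])
        assert any(a.start == 1000 and a.n_mismatches == 2 for a in hits)
        window[70] = flip[window[70]]
        assert map_reads_to_genomes([("three", "".join(window))], [genome]) == []

    def test_reverse_strand_read_found(self, small_genomes):
        genome = small_genomes[0]
        read = reverse_complement(genome.sequence[2000:2075])
        (aln,) = map_reads_to_genomes([("rc", read)], [genome])
        assert (aln.start, aln.strand) == (2000, "-")

    def test_duplicated_segment_reports_both_loci(self):
        core = generate_synthetic_genome(2000, 0.5, seed=5).sequence
        shared = core[500:700]
        g1 = Genome("g1", core)
        g2 = Genome("g2", generate_synthetic_genome(1000, 0.5, seed=6).sequence + shared)
        hits = map_reads_to_genomes([("dup", shared[:75])], [g1, g2])
        assert {a.genome_id for a in hits} == {"g1", "g2"}


class TestGenomeCoverage:
    def test_tiling_reads_cover_everything(self, small_genomes):
        genome = small_genomes[0]
        alns = [
            Alignment(f"r{i}", genome.id, s, min(s + 75, genome.length), "+", 0)
            for i, s in enumerate(range(0, genome.length, 75))
        ]
        assert genome_coverage(alns, genome) == 1.0

    def test_single_alignment_fraction(self):
        genome = Genome("g", "ACGT" * 250)  # 1000 bp
        alns = [Alignment("r", "g", 100, 175, "+", 0)]
        assert genome_coverage(alns, genome) == pytest.approx(0.075)

    def test_no_alignments_zero(self, small_genomes):
        assert genome_coverage([], small_genomes[0]) == 0.0


class TestChimericity:
    def test_unique_reads_from_two_genomes_chimeric_in_both_modes(self):
        reads = [("r1", "A", True), ("r2", "B", True)]
        assert classify_chimeric(reads, mode="classic")
        assert classify_chimeric(reads, mode="illumina")

    def test_multimapped_second_genome_only_flags_classic_mode(self):
        reads = [("r1", "A", True), ("r2", "A", True), ("r3", "B", False)]
        assert classify_chimeric(reads, mode="classic")
        assert not classify_chimeric(reads, mode="illumina")

    def test_single_read_contig_never_chimeric(self):
        reads = [("r1", "A", True)]
        assert not classify_chimeric(reads, mode="classic")
        assert not classify_chimeric(reads, mode="illumina")

    def test_modes_agree_when_all_reads_unique(self, rng):
        for _ in range(200):
            reads = [
                (f"r{i}", f"g{rng.integers(0, 3)}", True)
                for i in range(int(rng.integers(1, 10)))
            ]
            assert classify_chimeric(reads, "classic") == classify_chimeric(reads, "illumina")

    def test_empty_contig_rejected(self):
        with pytest.raises(ValueError):
            classify_chimeric([], mode="classic")


class TestDegreeOfChimericity:
    def test_seven_three_split(self):
        assert degree_of_chimericity(["A"] * 7 + ["B"] * 3) == pytest.approx(0.3)

    def test_single_source_is_zero(self):
        assert degree_of_chimericity(["A"] * 5) == 0.0

    def test_tie_takes_lexicographically_smallest_majority(self):
        sources = ["B"] * 5 + ["A"] * 5
        assert majority_genome(sources) == "A"
        assert degree_of_chimericity(sources) == pytest.approx(0.5)

    def test_matches_max_count_oracle_on_random_compositions(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            sources = [f"g{rng.integers(0, 5)}" for _ in range(n)]
            expected = 1.0 - max(Counter(sources).values()) / n
            assert degree_of_chimericity(sources) == pytest.approx(expected)
            assert 0.0 <= degree_of_chimericity(sources) <= 1.0 - 1.0 / n


class TestContigScore:
    def test_exact_substring_scores_100(self, small_genomes):
        contig = small_genomes[0].sequence[3000:5000]
        assert contig_score(contig, small_genomes) == pytest.approx(100.0)

    def test_reverse_complement_substring_scores_100(self, small_genomes):
        contig = reverse_complement(small_genomes[1].sequence[1000:2500])
        assert contig_score(contig, small_genomes) == pytest.approx(100.0)

    def test_score_is_identity_times_coverage(self, small_genomes):
        """The reported score must equal pid% x cov% / 100 for the best HSP."""
        rng = np.random.default_rng(77)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for _ in range(100):
            genome = small_genomes[int(rng.integers(0, len(small_genomes)))]
            start = int(rng.integers(0, genome.length - 1000))
            contig = list(genome.sequence[start : start + 1000])
            for pos in rng.choice(1000, size=int(rng.integers(0, 8)), replace=False):
                contig[pos] = flip[contig[pos]]
            contig = "".join(contig)
            hsp = best_hsp(contig, small_genomes)
            score = contig_score(contig, small_genomes)
            assert score == pytest.approx(
                hsp.identity * 100.0 * hsp.contig_coverage * 100.0 / 100.0
            )
            assert 0.0 <= score <= 100.0

    def test_perfect_score_requires_full_identity_and_coverage(self, small_genomes):
        # half-matching chimera of two genomes: HSP covers only part
        contig = (
            small_genomes[0].sequence[1000:2000] + small_genomes[1].sequence[5000:6000]
        )
        hsp = best_hsp(contig, small_genomes)
        score = contig_score(contig, small_genomes)
        assert score < 100.0
        assert hsp.contig_coverage < 1.0

    def test_unrelated_contig_scores_zero(self):
        genome = generate_synthetic_genome(5000, 1.0, seed=1, genome_id="gc")  # G/C only
        assert contig_score("AT" * 200, [genome]) == 0.0

    def test_no_genomes_rejected(self):
        with pytest.raises(ValueError):
            contig_score("ACGT" * 30, [])


def _n50_oracle(lengths):
    total = sum(lengths)
    return max(L for L in lengths if sum(x for x in lengths if x >= L) >= total / 2)


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([1000, 500, 500], 1000), ([42], 42), ([500, 500, 500, 500], 500)],
    )
    def test_known_values(self, lengths, expected):
        assert n50(lengths) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.sampled_from(range(100, 1001, 100)), min_size=1, max_size=8))
    def test_agrees_with_threshold_oracle(self, lengths):
        assert n50(lengths) == _n50_oracle(lengths)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            n50([])
        with pytest.raises(ValueError):
            n50([100, 0])


class TestAssemblySummary:
    def test_strict_500_cutoff(self):
        summary = assembly_summary([600, 400, 501])
        assert summary.n_contigs_over_min == 2
        assert summary.sum_length == 1101
        assert not summary.empty

    def test_all_short_flags_empty(self):
        summary = assembly_summary([500, 100, 42])
        assert summary.n_contigs_over_min == 0
        assert summary.empty

    def test_longest_and_n50_consistency(self):
        summary = assembly_summary([22_725, 600, 700, 800])
        assert summary.longest == 22_725
        assert summary.n50 <= summary.longest


class TestScaftigs:
    @pytest.mark.parametrize(
        "scaffold,expected",
        [
            ("ACGTNNNACGT", ["ACGT", "ACGT"]),
            ("ACGT", ["ACGT"]),
            ("NNNN", []),
            ("NACGTN", ["ACGT"]),
            ("ANCNG", ["A", "C", "G"]),
        ],
    )
    def test_maximal_n_free_pieces(self, scaffold, expected):
        assert extract_scaftigs(scaffold) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_reconstruction_with_gap_runs(self, scaffold):
        scaftigs = extract_scaftigs(scaffold)
        gaps = [g for g in re.findall(r"N+", scaffold)]
        pieces = re.split(r"(N+)", scaffold)
        rebuilt = "".join(pieces)
        assert rebuilt == scaffold
        assert [p for p in pieces if p and "N" not in p] == scaftigs
        assert sum(map(len, scaftigs)) + sum(map(len, gaps)) == len(scaffold)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            extract_scaftigs("ACGTX")


class TestAssessContigs:
    def test_single_source_contig_clean_and_spliced_fraction_exact(self, small_genomes):
        gA, gB = small_genomes[0], small_genomes[1]
        contig_pure = gA.sequence[0:750]
        contig_mixed = gA.sequence[1000:1525] + gB.sequence[2000:2225]
        contigs = {"pure": contig_pure, "mixed": contig_mixed}

        read_sources = {}
        read_map = {}
        for i in range(10):  # pure contig: 10 tiling reads from A
            rid = f"a{i}"
            read_sources[rid] = gA.id
            read_map[rid] = {"pure"}
        for i in range(7):  # mixed contig: 7 reads from A, 3 from B
            rid = f"m{i}"
            read_sources[rid] = gA.id
            read_map[rid] = {"mixed"}
        for i in range(3):
            rid = f"x{i}"
            read_sources[rid] = gB.id
            read_map[rid] = {"mixed"}

        results = {a.contig_id: a for a in assess_contigs(
            contigs, read_sources, read_map, mode="illumina", genomes=small_genomes
        )}
        assert not results["pure"].chimeric
        assert results["pure"].degree_of_chimericity == 0.0
        assert results["pure"].contig_score == pytest.approx(100.0)
        assert results["mixed"].chimeric
        assert results["mixed"].degree_of_chimericity == pytest.approx(0.3)
        assert results["mixed"].majority_genome == gA.id

    def test_unknown_read_in_map_rejected(self, small_genomes):
        with pytest.raises(KeyError):
            assess_contigs({"c": "ACGT" * 50}, {}, {"ghost": {"c"}})
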