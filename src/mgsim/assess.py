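"""Score contigs and scaffolds against the simulator's ground truth.

Metrics
-------
* **Read-back mapping and genome coverage** — an exhaustive k-mismatch
  ungapped mapper (seed-and-verify, both strands) re-creates the
  "map reads to source genomes allowing 2 mismatches" check used to judge
  raw-data accuracy; coverage is the fraction of genome positions hit.
* **Chimericity** — a contig is *chimeric* when it combines reads that
  originate from more than one genome (classic definition); for short-read
  assemblies, where a read can be assigned to several contigs, only
  uniquely-assigned reads count (illumina mode).  The *degree of
  chimericity* of a contig is the fraction of its reads that do not come
  from the majority source genome.
* **Contig Score** — best local alignment (HSP) of the contig against any
  reference genome; the score is percent identity of the HSP times the
  percent of the contig the HSP covers, divided by 100, so a perfect
  full-length match scores 100.
* **Length summaries** — N50 (cumulative-from-largest convention), count
  and statistics of contigs above a length cutoff (500 bp by default,
  strict), scaftig extraction from scaffolds.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .community import Genome
from .simulate import reverse_complement

# ---------------------------------------------------------------------------
# read-back mapping


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a full read on a genome."""

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    n_mismatches: int


def _count_mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def map_reads_to_genomes(
    reads: list[tuple[str, str]],
    genomes: list[Genome],
    max_mismatches: int = 2,
    seed_len: int = 15,
) -> list[Alignment]:
    """All ungapped full-length placements with <= ``max_mismatches``.

    Seed-and-verify: the genome's k-mers are hashed; each read is split into
    ``max_mismatches + 1`` segments whose leading k-mers are looked up (by
    the pigeonhole principle a read within the mismatch budget has at least
    one exact segment, hence one exact seed).  Both strands are searched and
    every qualifying locus is reported.  Exhaustive, and intended for
    desk-scale genomes.
    """
    if not reads or not genomes:
        raise ValueError("reads and genomes must be non-empty")
    min_len = min(len(seq) for _, seq in reads)
    if min_len == 0:
        raise ValueError("zero-length read")
    k = min(seed_len, min_len // (max_mismatches + 1))
    if k < 4:
        raise ValueError(
            f"reads of length {min_len} are too short for {max_mismatches} "
            "mismatches with this seed length"
        )

    index: dict[str, list[tuple[int, int]]] = {}
    for gi, genome in enumerate(genomes):
        seq = genome.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((gi, pos))

    alignments: list[Alignment] = []
    for read_id, seq in reads:
        n = len(seq)
        seg = n // (max_mismatches + 1)
        offsets = [j * seg for j in range(max_mismatches + 1)]
        seen: set[tuple[int, int, str]] = set()
        for strand in "+-":
            s = seq if strand == "+" else reverse_complement(seq)
            for off in offsets:
                for gi, pos in index.get(s[off : off + k], ()):
                    start = pos - off
                    key = (gi, start, strand)
                    if key in seen or start < 0:
                        continue
                    seen.add(key)
                    genome = genomes[gi]
                    if start + n > genome.length:
                        continue
                    mm = _count_mismatches(s, genome.sequence[start : start + n],
                                           max_mismatches)
                    if mm <= max_mismatches:
                        alignments.append(
                            Alignment(read_id, genome.id, start, start + n, strand, mm)
                        )
    return alignments


def genome_coverage(alignments: list[Alignment], genome: Genome) -> float:
    """Fraction of genome positions covered by at least one alignment."""
    covered = np.zeros(genome.length, dtype=bool)
    for aln in alignments:
        if aln.genome_id == genome.id:
            covered[aln.start : aln.end] = True
    return float(covered.mean())


# ---------------------------------------------------------------------------
# chimericity


def classify_chimeric(
    contig_reads: list[tuple[str, str, bool]],
    mode: str = "illumina",
) -> bool:
    """Is a contig chimeric?

    ``contig_reads`` holds (read_id, source_genome, is_unique) for every
    read in the contig.  Classic mode: chimeric iff the reads come from more
    than one genome.  Illumina mode: only uniquely-assigned reads count
    (a multi-mapped short read may legitimately match several genomes).
    A single-read contig can never be chimeric.
    """
    if not contig_reads:
        raise ValueError("contig has no reads")
    if mode == "classic":
        sources = {g for _, g, _ in contig_reads}
    elif mode == "illumina":
        sources = {g for _, g, uniq in contig_reads if uniq}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return len(sources) > 1


def majority_genome(sources: list[str]) -> str:
    """Most frequent source genome; ties broken lexicographically."""
    if not sources:
        raise ValueError("no sources")
    counts = Counter(sources)
    best = max(counts.values())
    return min(g for g, c in counts.items() if c == best)


def degree_of_chimericity(sources: list[str]) -> float:
    """Fraction of a contig's reads not from its majority source genome."""
    if not sources:
        raise ValueError("contig has no reads")
    counts = Counter(sources)
    return 1.0 - counts[majority_genome(sources)] / len(sources)


# ---------------------------------------------------------------------------
# contig score

#: megablast-like scoring for high-identity contig-vs-source alignment
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1.0, -2.0, -5.0, -2.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = _MATCH
    aligner.mismatch_score = _MISMATCH
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class HSP:
    """Best local alignment of a contig against one genome."""

    genome_id: str
    score: float
    identity: float  # matches / alignment columns, gaps count as columns
    contig_coverage: float  # aligned contig span / contig length
    strand: str


def _seed_windows(contig: str, genome: str, k: int = 15, margin: int | None = None):
    """Candidate genome windows sharing a k-mer with the contig, merged."""
    if margin is None:
        margin = len(contig) // 2 + 100
    kmers = {contig[i : i + k] for i in range(len(contig) - k + 1)}
    hits = []
    for pos in range(len(genome) - k + 1):
        if genome[pos : pos + k] in kmers:
            hits.append(pos)
    if not hits:
        return []
    windows = []
    lo = hi = hits[0]
    for pos in hits[1:]:
        if pos <= hi + margin:
            hi = pos
        else:
            windows.append((max(0, lo - margin), min(len(genome), hi + k + margin)))
            lo = hi = pos
    windows.append((max(0, lo - margin), min(len(genome), hi + k + margin)))
    return windows


def best_hsp(contig: str, genomes: list[Genome], seed_len: int = 15) -> HSP | None:
    """Highest-scoring local alignment of the contig over all genomes/strands.

    Seed-and-extend: only genome windows sharing an exact ``seed_len``-mer
    with the contig are aligned (local Smith-Waterman with megablast-like
    scores).  Ties go to higher identity, then lower genome id.
    """
    if not contig:
        raise ValueError("empty contig")
    if not genomes:
        raise ValueError("no genomes supplied")
    aligner = _make_aligner()
    best: HSP | None = None
    for genome in sorted(genomes, key=lambda g: g.id):
        for strand, query in (("+", contig), ("-", reverse_complement(contig))):
            for lo, hi in _seed_windows(query, genome.sequence, k=seed_len):
                window = genome.sequence[lo:hi]
                alignments = aligner.align(window, query)
                if len(alignments) == 0:
                    continue
                aln = alignments[0]
                counts = aln.counts()
                columns = counts.identities + counts.mismatches + counts.gaps
                if columns == 0:
                    continue
                identity = counts.identities / columns
                q_coords = aln.coordinates[1]
                coverage = (q_coords[-1] - q_coords[0]) / len(contig)
                cand = HSP(genome.id, float(aln.score), identity, coverage, strand)
                if (
                    best is None
                    or cand.score > best.score
                    or (cand.score == best.score and cand.identity > best.identity)
                ):
                    best = cand
    return best


def contig_score(contig: str, genomes: list[Genome], seed_len: int = 15) -> float:
    """Contig Score in [0, 100]: HSP percent identity x percent of the
    contig covered by the HSP, divided by 100.  No HSP at all scores 0."""
    hsp = best_hsp(contig, genomes, seed_len=seed_len)
    if hsp is None:
        return 0.0
    return (hsp.identity * 100.0) * (hsp.contig_coverage * 100.0) / 100.0


# ---------------------------------------------------------------------------
# length statistics


def n50(lengths: list[int]) -> int:
    """Length at which the cumulative sum from the largest contig reaches
    half the total assembled bases."""
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]  # unreachable


@dataclass
class AssemblySummary:
    n_contigs_over_min: int
    sum_length: int
    n50: int
    longest: int
    mean_length: float
    min_len: int = 500
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f"n_contigs_over_{self.min_len}", self.n_contigs_over_min),
                ("sum_length", self.sum_length),
                ("N50", self.n50),
                ("longest", self.longest),
                ("mean_length", round(self.mean_length, 2)),
            ],
            columns=["metric", "value"],
        )


def assembly_summary(contig_lengths: list[int], min_len: int = 500) -> AssemblySummary:
    """Length statistics over contigs strictly longer than ``min_len``."""
    if not contig_lengths:
        raise ValueError("no contigs")
    kept = [x for x in contig_lengths if x > min_len]
    if not kept:
        return AssemblySummary(0, 0, 0, 0, 0.0, min_len=min_len, empty=True)
    return AssemblySummary(
        n_contigs_over_min=len(kept),
        sum_length=sum(kept),
        n50=n50(kept),
        longest=max(kept),
        mean_length=sum(kept) / len(kept),
        min_len=min_len,
    )


def extract_scaftigs(scaffold: str) -> list[str]:
    """Maximal N-free substrings of a scaffold, in order."""
    if not set(scaffold) <= set("ACGTN"):
        raise ValueError("scaffold must be over {A,C,G,T,N}")
    return [piece for piece in scaffold.split("N") if piece]


# ---------------------------------------------------------------------------
# per-contig assessment


@dataclass
class ContigAssessment:
    contig_id: str
    length: int
    n_reads: int
    chimeric: bool
    degree_of_chimericity: float
    majority_genome: str
    contig_score: float | None = None


def assess_contigs(
    contigs: dict[str, str],
    read_sources: dict[str, str],
    read_map: dict[str, set[str]],
    mode: str = "illumina",
    genomes: list[Genome] | None = None,
) -> list[ContigAssessment]:
    """Chimericity (and optionally Contig Score) for every contig.

    ``read_sources`` maps read_id -> true source genome (from the truth
    table); ``read_map`` maps read_id -> contig ids it was assigned to
    (from an external mapper's TSV or truth-based placement).  A read is
    *unique* when it is assigned to exactly one contig.
    """
    by_contig: dict[str, list[tuple[str, str, bool]]] = {c: [] for c in contigs}
    for read_id, assigned in read_map.items():
        if read_id not in read_sources:
            raise KeyError(f"read {read_id!r} missing from the truth table")
        uniq = len(assigned) == 1
        for contig_id in assigned:
            if contig_id in by_contig:
                by_contig[contig_id].append((read_id, read_sources[read_id], uniq))

    out = []
    for contig_id, seq in contigs.items():
        members = by_contig[contig_id]
        if not members:
            continue
        sources = [g for _, g, _ in members]
        out.append(
            ContigAssessment(
                contig_id=contig_id,
                length=len(seq),
                n_reads=len(members),
                chimeric=classify_chimeric(members, mode=mode),
                degree_of_chimericity=degree_of_chimericity(sources),
                majority_genome=majority_genome(sources),
                contig_score=(contig_score(seq, genomes) if genomes else None),
            )
        )
    return out


def assessment_frame(assessments: list[ContigAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [a.contig_id for a in assessments],
            "length": [a.length for a in assessments],
            "n_reads": [a.n_reads for a in assessments],
            "chimeric": [a.chimeric for a in assessments],
            "degree_of_chimericity": [a.degree_of_chimericity for a in assessments],
            "majority_genome": [a.majority_genome for a in assessments],
            "contig_score": [a.contig_score for a in assessments],
        }
    )
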