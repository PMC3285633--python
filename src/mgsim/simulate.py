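"""Read simulation with per-base error injection and ground-truth provenance.

Reads are sampled from reference genomes according to a community profile
(see :mod:`mgsim.community`), assigned a quality string from a platform
quality model (see :mod:`mgsim.error_models`), and then corrupted base by
base with the error probability implied by each quality value.  Every
emitted read carries a :class:`TruthRecord` with its source genome, the
reference window it was drawn from, its strand/mate, and the positions and
kinds of the injected errors — the ground truth against which assemblies
are later scored.

Platforms
---------
illumina
    Fixed-length reads (default 75 bp), paired-end from inserts of
    configurable size, substitution errors only, FASTQ output.
sanger
    Variable-length single-end reads, Normal(800, sd) lengths, substitution
    errors, FASTA + QUAL output.
pyro
    Variable-length single-end reads, Normal(255, sd) lengths, substitution
    errors plus homopolymer length errors (one-base insertions/deletions in
    homopolymer runs), FASTA + QUAL output.

Coordinates are 0-based half-open on the reference forward strand; a minus
strand read stores the sequence as sequenced (reverse complement of the
reference window).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .community import CommunityProfile, Genome, allocate_reads
from .error_models import QualityProfile, default_profile, phred_to_error_prob

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

PLATFORM_READ_LENGTHS = {"sanger": 800.0, "pyro": 255.0}
DEFAULT_ILLUMINA_READ_LENGTH = 75
DEFAULT_SANGER_SD = 100.0
DEFAULT_PYRO_SD = 50.0
SANGER_MIN_LENGTH = 100
PYRO_MIN_LENGTH = 50


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Insert:
    """A sequenced DNA fragment: a reference window plus a strand."""

    genome_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("invalid insert coordinates")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: np.ndarray  # integer Phred values, same length as sequence
    platform: str = "illumina"
    mate: str = "none"  # 'none', '1' or '2'

    def __post_init__(self):
        self.quality = np.asarray(self.quality, dtype=int)
        if len(self.sequence) != self.quality.size:
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TruthRecord:
    """Provenance of one simulated read, including every injected error."""

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    mate: str = "none"
    error_positions: list[int] = field(default_factory=list)
    error_types: list[str] = field(default_factory=list)

    @property
    def n_sub(self) -> int:
        return self.error_types.count("sub")

    @property
    def n_ins(self) -> int:
        return self.error_types.count("ins")

    @property
    def n_del(self) -> int:
        return self.error_types.count("del")


def sample_insert(
    genome: Genome,
    size_mean: float,
    size_sd: float,
    rng: np.random.Generator,
    min_size: int = 1,
) -> Insert:
    """Draw an insert: Normal(size_mean, size_sd) length (rounded, clamped to
    [min_size, genome length]), uniform start, fair-coin strand."""
    if size_mean > genome.length:
        raise ValueError(
            f"mean insert size {size_mean} exceeds genome length {genome.length}"
        )
    if min_size > genome.length:
        raise ValueError("genome shorter than the minimum insert size")
    size = int(round(rng.normal(size_mean, size_sd))) if size_sd > 0 else int(round(size_mean))
    size = int(np.clip(size, min_size, genome.length))
    start = int(rng.integers(0, genome.length - size + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return Insert(genome.id, start, start + size, strand)


def insert_sequence(insert: Insert, genome: Genome) -> str:
    """The insert as sequenced: reference window, reverse-complemented on '-'."""
    seq = genome.sequence[insert.start : insert.end]
    return seq if insert.strand == "+" else reverse_complement(seq)


def extract_paired_reads(insert: Insert, genome: Genome, read_length: int) -> tuple[str, str]:
    """Innie paired-end reads from an insert.

    /1 is the first ``read_length`` bases of the insert on its strand; /2 is
    the reverse complement of the last ``read_length`` bases (so the mates
    face each other).
    """
    if read_length > insert.size:
        raise ValueError("read_length exceeds insert size")
    seq = insert_sequence(insert, genome)
    return seq[:read_length], reverse_complement(seq[-read_length:])


def _mate_window(insert: Insert, read_length: int, mate: str) -> tuple[int, int, str]:
    """Reference window and strand of one mate of an insert."""
    if insert.strand == "+":
        if mate == "1":
            return insert.start, insert.start + read_length, "+"
        return insert.end - read_length, insert.end, "-"
    if mate == "1":
        return insert.end - read_length, insert.end, "-"
    return insert.start, insert.start + read_length, "+"


def inject_errors(
    sequence: str,
    quality: np.ndarray,
    rng: np.random.Generator,
    platform: str = "illumina",
    convention: str = "odds",
    read_id: str = "read",
    genome_id: str = "",
    start: int = 0,
    end: int | None = None,
    strand: str = "+",
    mate: str = "none",
) -> tuple[SimulatedRead, TruthRecord]:
    """Corrupt a raw read according to its quality string.

    Each base is substituted independently with the error probability of its
    quality value (substitute uniform over the 3 other bases).  For
    pyrosequencing, each homopolymer run of length >= 2 additionally suffers
    a length error (one-base duplication or deletion, fair coin) with the
    error probability of the run's first base.  All changes are logged in
    the returned :class:`TruthRecord`; positions are 0-based offsets in the
    final read.
    """
    quality = np.asarray(quality, dtype=int)
    n = len(sequence)
    if n != quality.size:
        raise ValueError("sequence and quality lengths differ")
    if end is None:
        end = start + n

    p = phred_to_error_prob(quality.astype(float), convention=convention)
    sub_mask = rng.random(n) < p
    chars = list(sequence)
    sub_pre: list[int] = []  # substitution positions in pre-indel coordinates
    for i in np.flatnonzero(sub_mask):
        offset = int(rng.integers(1, 4))
        chars[i] = _BASES[(_BASE_INDEX[chars[i]] + offset) % 4]
        sub_pre.append(int(i))

    quals = list(quality)
    indels: list[tuple[int, str]] = []  # (pre-indel position, 'ins'/'del')
    if platform == "pyro":
        # homopolymer length errors on maximal runs of the substituted read
        runs = []
        i = 0
        while i < n:
            j = i
            while j < n and chars[j] == chars[i]:
                j += 1
            if j - i >= 2:
                runs.append(i)
            i = j
        shift = 0  # index shift from indels already applied (left to right)
        for run_start in runs:
            if rng.random() >= p[run_start]:
                continue
            pos = run_start + shift
            if rng.random() < 0.5:  # one-base duplication
                chars.insert(pos, chars[pos])
                quals.insert(pos, quals[pos])
                indels.append((run_start, "ins"))
                shift += 1
            else:  # one-base deletion
                del chars[pos]
                del quals[pos]
                indels.append((run_start, "del"))
                shift -= 1

    # translate pre-indel coordinates to offsets in the final read
    final_len = len(chars)
    ins_pre = sorted(q for q, t in indels if t == "ins")
    del_pre = sorted(q for q, t in indels if t == "del")
    del_set = set(del_pre)

    def _final(i: int, count_ins_at: bool) -> int:
        shift = int(np.searchsorted(ins_pre, i, side="right" if count_ins_at else "left"))
        shift -= int(np.searchsorted(del_pre, i, side="left"))
        return min(max(i + shift, 0), max(final_len - 1, 0))

    raw_events: list[tuple[int, str]] = []
    for i in sub_pre:
        # a substituted base later removed by a deletion leaves only a junction
        raw_events.append((_final(i, count_ins_at=i not in del_set), "sub"))
    for q, t in indels:
        raw_events.append((_final(q, count_ins_at=False), t))

    # enforce strictly increasing positions (collisions only from overlapping
    # events, which are rare; bump within bounds, else drop)
    ordered_pos: list[int] = []
    ordered_types: list[str] = []
    for pos, t in sorted(raw_events):
        while ordered_pos and pos <= ordered_pos[-1]:
            pos += 1
        if pos < final_len:
            ordered_pos.append(pos)
            ordered_types.append(t)

    read = SimulatedRead(read_id, "".join(chars), np.asarray(quals, dtype=int),
                         platform=platform, mate=mate)
    truth = TruthRecord(read_id, genome_id, start, end, strand, mate,
                        ordered_pos, ordered_types)
    return read, truth


def simulate_platform_read_length(
    platform: str,
    rng: np.random.Generator,
    *,
    illumina_length: int = DEFAULT_ILLUMINA_READ_LENGTH,
    sanger_sd: float = DEFAULT_SANGER_SD,
    pyro_sd: float = DEFAULT_PYRO_SD,
) -> int:
    """Draw one read length for a platform.

    Illumina reads are fixed-length; Sanger lengths are Normal(800, sd)
    truncated at 100 bp; pyro lengths are Normal(255, sd) truncated at 50 bp.
    """
    if platform == "illumina":
        return illumina_length
    if platform == "sanger":
        return max(SANGER_MIN_LENGTH, int(round(rng.normal(PLATFORM_READ_LENGTHS["sanger"], sanger_sd))))
    if platform == "pyro":
        return max(PYRO_MIN_LENGTH, int(round(rng.normal(PLATFORM_READ_LENGTHS["pyro"], pyro_sd))))
    raise ValueError(f"unknown platform {platform!r}")


@dataclass
class SimulationConfig:
    """Everything a simulation run needs; deterministic given ``seed``."""

    genomes: list[Genome]
    profile: CommunityProfile
    platform: str = "illumina"
    n_fragments: int = 1000  # inserts (paired) or reads (single-end)
    read_length: int = DEFAULT_ILLUMINA_READ_LENGTH
    paired: bool = True
    insert_size: float = 200.0
    insert_sd: float = 20.0
    read_length_sd: float | None = None  # sanger/pyro only; default per platform
    quality_model: QualityProfile | None = None
    convention: str = "odds"
    seed: int = 0

    def __post_init__(self):
        if self.platform not in ("illumina", "sanger", "pyro"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.platform != "illumina":
            self.paired = False
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        ids = {g.id for g in self.genomes}
        missing = [g for g in self.profile.genome_ids if g not in ids]
        if missing:
            raise ValueError(f"profile references unknown genomes {missing}")
        if self.quality_model is None:
            self.quality_model = default_profile(self.platform, read_length=self.read_length)


@dataclass
class SimulationResult:
    reads: list[SimulatedRead]
    truth: list[TruthRecord]
    summary: pd.DataFrame
    seed: int

    @property
    def total_bases(self) -> int:
        return int(sum(len(r) for r in self.reads))


def simulate_metagenome(config: SimulationConfig, out_prefix: str | None = None) -> SimulationResult:
    """Run one simulation; optionally write reads, truth table and summary.

    Illumina emits paired FASTQ (``<prefix>.1.fq``/``.2.fq``); Sanger and
    pyro emit ``<prefix>.fasta`` + ``<prefix>.qual``.  The truth table goes
    to ``<prefix>.truth.tsv`` and the per-genome summary (read counts,
    bases, expected coverage) to ``<prefix>.summary.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    genome_by_id = {g.id: g for g in config.genomes}
    lengths = {g.id: g.length for g in config.genomes}
    allocation = allocate_reads(config.profile, lengths, config.n_fragments)

    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    rows = []
    serial = 0
    sanger_sd = config.read_length_sd if config.read_length_sd is not None else DEFAULT_SANGER_SD
    pyro_sd = config.read_length_sd if config.read_length_sd is not None else DEFAULT_PYRO_SD

    for genome_id in config.profile.genome_ids:
        genome = genome_by_id[genome_id]
        n_frag = allocation.counts[genome_id]
        genome_bases = 0
        for _ in range(n_frag):
            serial += 1
            if config.paired:
                insert = sample_insert(genome, config.insert_size, config.insert_sd,
                                       rng, min_size=config.read_length)
                raw1, raw2 = extract_paired_reads(insert, genome, config.read_length)
                base_id = f"read{serial:08d}|{genome_id}:{insert.start}-{insert.end}:{insert.strand}"
                for mate, raw in (("1", raw1), ("2", raw2)):
                    w_start, w_end, w_strand = _mate_window(insert, config.read_length, mate)
                    quals = config.quality_model.sample(len(raw), rng)
                    read, rec = inject_errors(
                        raw, quals, rng, platform=config.platform,
                        convention=config.convention,
                        read_id=f"{base_id}/{mate}", genome_id=genome_id,
                        start=w_start, end=w_end, strand=w_strand, mate=mate,
                    )
                    reads.append(read)
                    truth.append(rec)
                    genome_bases += len(read)
            else:
                length = simulate_platform_read_length(
                    config.platform, rng, illumina_length=config.read_length,
                    sanger_sd=sanger_sd, pyro_sd=pyro_sd)
                length = min(length, genome.length)
                start = int(rng.integers(0, genome.length - length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                window = genome.sequence[start : start + length]
                raw = window if strand == "+" else reverse_complement(window)
                read_id = f"read{serial:08d}|{genome_id}:{start}-{start + length}:{strand}"
                quals = config.quality_model.sample(length, rng)
                read, rec = inject_errors(
                    raw, quals, rng, platform=config.platform,
                    convention=config.convention,
                    read_id=read_id, genome_id=genome_id,
                    start=start, end=start + length, strand=strand,
                )
                reads.append(read)
                truth.append(rec)
                genome_bases += len(read)
        n_reads = n_frag * (2 if config.paired else 1)
        rows.append(
            {
                "genome_id": genome_id,
                "abundance": config.profile.abundance_of(genome_id),
                "genome_length": genome.length,
                "n_fragments": n_frag,
                "n_reads": n_reads,
                "bases": genome_bases,
                "expected_coverage": genome_bases / genome.length,
            }
        )

    summary = pd.DataFrame(rows)
    summary.attrs["seed"] = config.seed
    summary.attrs["platform"] = config.platform
    summary.attrs["mean_read_length"] = (
        float(np.mean([len(r) for r in reads])) if reads else 0.0
    )
    result = SimulationResult(reads, truth, summary, config.seed)

    if out_prefix is not None:
        write_simulation(result, config, out_prefix)
    return result


def write_simulation(result: SimulationResult, config: SimulationConfig, out_prefix: str) -> None:
    if config.platform == "illumina" and config.paired:
        io.write_fastq(
            ((r.read_id, r.sequence, r.quality) for r in result.reads if r.mate == "1"),
            f"{out_prefix}.1.fq",
        )
        io.write_fastq(
            ((r.read_id, r.sequence, r.quality) for r in result.reads if r.mate == "2"),
            f"{out_prefix}.2.fq",
        )
    elif config.platform == "illumina":
        io.write_fastq(((r.read_id, r.sequence, r.quality) for r in result.reads),
                       f"{out_prefix}.fq")
    else:
        io.write_fasta(((r.read_id, r.sequence) for r in result.reads),
                       f"{out_prefix}.fasta")
        io.write_qual(((r.read_id, r.quality) for r in result.reads),
                      f"{out_prefix}.qual")
    write_truth_table(result.truth, f"{out_prefix}.truth.tsv")
    summary = result.summary.copy()
    io.write_tsv(summary, f"{out_prefix}.summary.tsv")


def write_truth_table(records: list[TruthRecord], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "genome_id": [r.genome_id for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "strand": [r.strand for r in records],
            "mate": [r.mate for r in records],
            "n_sub": [r.n_sub for r in records],
            "n_ins": [r.n_ins for r in records],
            "n_del": [r.n_del for r in records],
            "error_positions": [",".join(map(str, r.error_positions)) for r in records],
            "error_types": [",".join(r.error_types) for r in records],
        }
    )
    io.write_tsv(frame, path)


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"error_positions": str, "error_types": str},
                       keep_default_na=False)
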