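"""Community structure and per-genome sequencing effort.

A simulated metagenome starts from a *community profile*: genomes ranked by
relative organism abundance.  Sequencing is shotgun over the pooled DNA, so
the share of reads a genome receives is proportional to
``abundance x genome length`` — an abundant organism with a small genome can
contribute fewer bases than a rarer organism with a large one.

This module builds rank-abundance profiles (uniform, geometric, lognormal,
or user-supplied), converts them into exact integer read allocations, and
generates synthetic reference genomes to stand in for real isolates.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Genome:
    """A reference genome: an identifier and an unambiguous DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if not set(self.sequence) <= {"A", "C", "G", "T"}:
            raise ValueError(f"genome {self.id!r} contains non-ACGT characters")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CommunityProfile:
    """Ranked relative abundances over genomes.

    Entries are (genome_id, relative_abundance) sorted by descending
    abundance; abundances are strictly positive and sum to 1.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        abunds = np.array([a for _, a in self.entries], dtype=float)
        if abunds.size == 0:
            raise ValueError("empty community profile")
        if (abunds <= 0).any():
            raise ValueError("abundances must be strictly positive")
        if abs(abunds.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {abunds.sum()}, not 1")
        if (np.diff(abunds) > 1e-12).any():
            raise ValueError("entries must be sorted by descending abundance")
        ids = [g for g, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in profile")

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.entries], dtype=float)

    def abundance_of(self, genome_id: str) -> float:
        return dict(self.entries)[genome_id]

    def to_tsv(self, path: str | os.PathLike) -> None:
        frame = pd.DataFrame(self.entries, columns=["genome_id", "abundance"])
        io.write_tsv(frame, path)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CommunityProfile":
        frame = pd.read_csv(path, sep="\t")
        return from_abundances(frame["genome_id"].astype(str), frame["abundance"].astype(float))


@dataclass(frozen=True)
class ReadAllocation:
    """Integer read (or insert) counts per genome, conserving the total."""

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("allocation counts do not sum to the total")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")


def from_abundances(genome_ids, abundances) -> CommunityProfile:
    """Build a profile from a raw abundance vector (normalized, rank-sorted)."""
    ids = list(genome_ids)
    ab = np.asarray(list(abundances), dtype=float)
    if len(ids) != ab.size:
        raise ValueError("genome_ids and abundances differ in length")
    if (ab <= 0).any():
        raise ValueError("abundances must be strictly positive")
    ab = ab / ab.sum()
    order = np.argsort(-ab, kind="stable")
    return CommunityProfile(tuple((ids[i], float(ab[i])) for i in order))


def build_rank_abundance(
    n_genomes: int,
    model: str = "uniform",
    genome_ids: list[str] | None = None,
    *,
    ratio: float = 0.5,
    sigma: float = 1.0,
    mu: float = 0.0,
) -> CommunityProfile:
    """Build a rank-abundance curve for ``n_genomes`` community members.

    Models
    ------
    uniform
        Every genome at abundance ``1/n``.
    geometric
        Abundance of rank k proportional to ``ratio**k`` (ratio in (0, 1]).
    lognormal
        Abundances proportional to lognormal quantiles at the plotting
        positions ``(i + 0.5)/n`` (``mu``/``sigma`` on the log scale), a
        deterministic stand-in for a sorted lognormal draw.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if genome_ids is None:
        width = len(str(n_genomes))
        genome_ids = [f"genome{str(i + 1).zfill(width)}" for i in range(n_genomes)]
    if len(genome_ids) != n_genomes:
        raise ValueError("genome_ids length must equal n_genomes")

    if model == "uniform":
        raw = np.ones(n_genomes)
    elif model == "geometric":
        if not 0 < ratio <= 1:
            raise ValueError("geometric ratio must be in (0, 1]")
        raw = ratio ** np.arange(n_genomes)
    elif model == "lognormal":
        if sigma <= 0:
            raise ValueError("lognormal sigma must be > 0")
        q = (np.arange(n_genomes) + 0.5) / n_genomes
        raw = stats.lognorm.ppf(1.0 - q, s=sigma, scale=np.exp(mu))
    else:
        raise ValueError(f"unknown rank-abundance model {model!r}")

    raw = np.sort(raw)[::-1]
    return CommunityProfile(tuple(zip(genome_ids, (raw / raw.sum()).tolist())))


def allocate_reads(
    profile: CommunityProfile,
    genome_lengths: dict[str, int],
    total: int,
) -> ReadAllocation:
    """Split ``total`` reads among genomes proportionally to abundance x length.

    Fractional shares are rounded by the largest-remainder method, so counts
    sum to ``total`` exactly and each count is within one read of its exact
    real-valued share.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    ids = profile.genome_ids
    missing = [g for g in ids if g not in genome_lengths]
    if missing:
        raise KeyError(f"no genome length for {missing}")
    weights = profile.abundances * np.array([genome_lengths[g] for g in ids], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total abundance x length weight is zero")
    exact = total * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = total - counts.sum()
    # hand the leftover reads to the largest fractional remainders (ties by rank)
    for i in np.argsort(-remainder, kind="stable")[:short]:
        counts[i] += 1
    return ReadAllocation(dict(zip(ids, counts.tolist())), total)


def generate_synthetic_genome(length: int, gc_content: float = 0.5, seed: int | None = None,
                              genome_id: str = "synthetic") -> Genome:
    """Generate an i.i.d. random genome with the given GC fraction.

    A stand-in for real isolate references when exercising the simulator and
    assessment pipeline; deterministic for a given (length, gc, seed).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return Genome(genome_id, _BASES[idx].tobytes().decode("ascii"))
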