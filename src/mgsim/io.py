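"""Readers and writers for the plain-text formats the toolkit exchanges.

Sequence formats (FASTA, QUAL, FASTQ) go through Biopython; tables
(community profiles, truth tables, read-to-contig maps, reports) are
tab-separated files handled with pandas.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Highest Phred value representable in Sanger FASTQ (ASCII '~' - 33).
MAX_QUAL = 93
PHRED_OFFSET = 33

_ACGT = frozenset("ACGT")


def phred_encode(quals: Sequence[int]) -> str:
    """Encode integer Phred values as a Sanger (Phred+33) ASCII string."""
    return "".join(chr(min(int(q), MAX_QUAL) + PHRED_OFFSET) for q in quals)


def phred_decode(text: str) -> np.ndarray:
    """Decode a Sanger (Phred+33) ASCII quality string to integers."""
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET


def read_fasta(path: str | os.PathLike, strict_acgt: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs.

    With ``strict_acgt`` any IUPAC ambiguity code (anything outside A/C/G/T)
    raises ``ValueError`` — simulation reference genomes must be unambiguous.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if strict_acgt and not set(seq) <= _ACGT:
            bad = sorted(set(seq) - _ACGT)
            raise ValueError(
                f"sequence {rec.id!r} contains non-ACGT characters {bad}; "
                "simulation references must be unambiguous"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_qual(path: str | os.PathLike) -> list[tuple[str, np.ndarray]]:
    """Read a .qual file (FASTA-like headers, whitespace-separated integers)."""
    out = []
    for rec in SeqIO.parse(str(path), "qual"):
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=int)
        if quals.size and (quals.min() < 0 or quals.max() > MAX_QUAL):
            raise ValueError(
                f"record {rec.id!r} has quality values outside [0, {MAX_QUAL}]"
            )
        out.append((rec.id, quals))
    return out


def write_qual(records: Iterable[tuple[str, Sequence[int]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, quals in records:
            fh.write(f">{name}\n")
            vals = [str(int(q)) for q in quals]
            for i in range(0, len(vals), 20):
                fh.write(" ".join(vals[i : i + 20]) + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, np.ndarray]]:
    """Read Sanger-encoded FASTQ into (id, sequence, quality array) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (
                rec.description or rec.id,
                str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
            )
        )
    return out


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | os.PathLike) -> None:
    """Write (id, sequence, qualities) triples as Sanger Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, quals in records:
            fh.write(f"@{name}\n{seq}\n+\n{phred_encode(quals)}\n")


def write_seqrecords_fastq(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    SeqIO.write(records, str(path), "fastq")


def make_seqrecord(name: str, seq: str, quals: Sequence[int] | None = None) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name, description="")
    if quals is not None:
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
    return rec


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=False, **kwargs)


def read_read_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column read_id <tab> contig_id map (no header).

    A read may appear under several contigs (multi-mapping); the result maps
    each read to the set of contigs it was assigned to.
    """
    frame = pd.read_csv(path, sep="\t", header=None, names=["read_id", "contig_id"], dtype=str)
    out: dict[str, set[str]] = {}
    for read_id, contig_id in zip(frame["read_id"], frame["contig_id"]):
        out.setdefault(read_id, set()).add(contig_id)
    return out
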