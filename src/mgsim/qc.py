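"""Illumina read quality control: trim, filter, account.

The pipeline applies, in order:

1. **5' composition trim** — the per-cycle frequency of each base over the
   whole read set is compared to its mean across all cycles; leading cycles
   where any base frequency deviates by more than 2 standard deviations are
   removed from every read.  Aberrant leading-cycle composition is a
   library-preparation artifact, so the statistic (and the trim) is
   population-level, not per read.
2. **3' quality trim** — terminal bases with quality below 20 are removed
   until the read ends in a base of quality >= 20.
3. **read filters** — reads shorter than 35 bases or with median quality
   below 20 are discarded.

The :class:`QCReport` records reads/bases in and out, the global 5' trim,
per-read 3' trim lengths, and a histogram of removal reasons.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulatedRead

_BASES = "ACGT"


@dataclass
class QCReport:
    reads_in: int
    reads_out: int
    bases_in: int
    bases_out: int
    five_prime_trim: int
    three_prime_trim_lengths: list[int] = field(default_factory=list)
    removal_reasons: Counter = field(default_factory=Counter)

    def __post_init__(self):
        if self.reads_out > self.reads_in or self.bases_out > self.bases_in:
            raise ValueError("QC cannot create reads or bases")
        removed = self.reads_in - self.reads_out
        if sum(self.removal_reasons.values()) != removed:
            raise ValueError("removal reasons do not account for all removed reads")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("reads_in", self.reads_in),
                ("reads_out", self.reads_out),
                ("bases_in", self.bases_in),
                ("bases_out", self.bases_out),
                ("five_prime_trim_cycles", self.five_prime_trim),
                ("removed_too_short", self.removal_reasons.get("too_short", 0)),
                ("removed_low_median_q", self.removal_reasons.get("low_median_q", 0)),
            ],
            columns=["metric", "value"],
        )


def five_prime_composition_trim(
    sequences: list[str],
    n_sd: float = 2.0,
    window: int = 10,
) -> int:
    """Leading cycles to trim so base composition is stable.

    For each base b, the frequency f_b(c) at each cycle c is computed over
    all reads covering that cycle, then the mean and standard deviation of
    f_b across cycles.  The trim offset is the smallest t such that every
    cycle after t has all four base frequencies within ``n_sd`` standard
    deviations of their cross-cycle mean.  Only the first ``window`` cycles
    are eligible for trimming (a 5' operation); deeper outlier cycles are
    ignored here.

    When read lengths differ, the composition statistic is computed over the
    reads of the modal length only (so a previously trimmed set does not
    distort the per-cycle denominators).
    """
    if not sequences:
        raise ValueError("empty read set")
    lengths = Counter(len(s) for s in sequences)
    modal_len = max(lengths, key=lambda k: (lengths[k], k))
    pool = [s for s in sequences if len(s) == modal_len]
    if modal_len == 0:
        return 0

    counts = np.zeros((4, modal_len))
    for seq in pool:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for bi, base in enumerate(_BASES):
            counts[bi] += arr == ord(base)
    freqs = counts / len(pool)

    mean = freqs.mean(axis=1, keepdims=True)
    sd = freqs.std(axis=1, keepdims=True)
    offending = (np.abs(freqs - mean) > n_sd * sd).any(axis=0)
    eligible = offending[: min(window, modal_len)]
    if not eligible.any():
        return 0
    return int(np.flatnonzero(eligible)[-1]) + 1


def three_prime_quality_trim(read: SimulatedRead, q_min: int = 20) -> SimulatedRead:
    """Strip 3'-terminal bases with quality below ``q_min``."""
    q = read.quality
    keep = len(q)
    while keep > 0 and q[keep - 1] < q_min:
        keep -= 1
    if keep == len(q):
        return read
    return SimulatedRead(read.read_id, read.sequence[:keep], q[:keep],
                         platform=read.platform, mate=read.mate)


def filter_read(
    read: SimulatedRead,
    min_len: int = 35,
    min_median_q: float = 20.0,
) -> tuple[bool, str | None]:
    """Keep/discard decision for an already-trimmed read.

    Discards reads shorter than ``min_len`` (reason ``too_short``) or with
    median quality below ``min_median_q`` (reason ``low_median_q``).  The
    median of an even number of qualities is the mean of the two central
    values.
    """
    if len(read) < min_len:
        return False, "too_short"
    if float(np.median(read.quality)) < min_median_q:
        return False, "low_median_q"
    return True, None


def qc_pipeline(
    reads: list[SimulatedRead],
    *,
    q_trim: int = 20,
    min_len: int = 35,
    min_median_q: float = 20.0,
    n_sd: float = 2.0,
    five_prime_window: int = 10,
) -> tuple[list[SimulatedRead], QCReport]:
    """5' composition trim, then 3' quality trim, then read filters."""
    if not reads:
        raise ValueError("empty read set")
    bases_in = sum(len(r) for r in reads)

    offset = five_prime_composition_trim(
        [r.sequence for r in reads], n_sd=n_sd, window=five_prime_window
    )
    trimmed5 = [
        SimulatedRead(r.read_id, r.sequence[offset:], r.quality[offset:],
                      platform=r.platform, mate=r.mate)
        if offset else r
        for r in reads
    ]

    kept: list[SimulatedRead] = []
    reasons: Counter = Counter()
    trim3_lengths: list[int] = []
    for read in trimmed5:
        trimmed = three_prime_quality_trim(read, q_min=q_trim)
        trim3_lengths.append(len(read) - len(trimmed))
        keep, reason = filter_read(trimmed, min_len=min_len, min_median_q=min_median_q)
        if keep:
            kept.append(trimmed)
        else:
            reasons[reason] += 1

    report = QCReport(
        reads_in=len(reads),
        reads_out=len(kept),
        bases_in=bases_in,
        bases_out=sum(len(r) for r in kept),
        five_prime_trim=offset,
        three_prime_trim_lengths=trim3_lengths,
        removal_reasons=reasons,
    )
    return kept, report
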