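"""Assembly summary statistics and genome-size bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kmerspec import GenomeSizeEstimate

#: flow-cytometry DNA-mass conversion: 1 picogram is approximately 978 Mb
MB_PER_PG = 978.0


@dataclass
class AssemblyStats:
    contig_count: int
    total_length: int
    longest: int
    n50: int
    n90: int


def nxx(lengths, x: float) -> int:
    """Nxx by the descending-cumulative-sum convention.

    The smallest length L* such that contigs of length >= L* sum to at
    least x% of the total assembly length.
    """
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length list")
    if np.any(lengths <= 0):
        raise ValueError("contig lengths must be positive")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    srt = np.sort(lengths)[::-1]
    cum = np.cumsum(srt)
    target = x / 100 * cum[-1]
    return int(srt[np.searchsorted(cum, target)])


def assembly_stats(lengths) -> AssemblyStats:
    lengths = [int(l) for l in lengths]
    return AssemblyStats(
        contig_count=len(lengths),
        total_length=sum(lengths),
        longest=max(lengths),
        n50=nxx(lengths, 50),
        n90=nxx(lengths, 90),
    )


def assembly_stats_from_fasta(path) -> AssemblyStats:
    from Bio import SeqIO
    return assembly_stats([len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")])


def pg_to_bases(picograms: float) -> float:
    """Convert a flow-cytometry DNA mass to bases (1 pg ~ 978 Mb)."""
    if picograms <= 0:
        raise ValueError("picograms must be positive")
    return picograms * MB_PER_PG * 1e6


@dataclass
class CombinedEstimate:
    G: float
    agree: bool
    note: Optional[str]
    kmer: GenomeSizeEstimate
    flow: GenomeSizeEstimate


def combine_size_estimates(kmer_est: GenomeSizeEstimate,
                           flow_est: GenomeSizeEstimate,
                           agree_tol: float = 0.15) -> CombinedEstimate:
    """Unweighted mean of a k-mer and a flow-cytometry genome size.

    The agreement flag is set when the two differ by less than
    ``agree_tol`` relative to their mean.  When the k-mer estimate is
    about half the flow value — the signature of reading the survey peak
    one copy-number too high (the doubled peak mistaken for the
    single-copy peak) — a peak-misassignment note is attached.
    """
    a, b = kmer_est.G, flow_est.G
    mean = (a + b) / 2
    agree = abs(a - b) / mean < agree_tol
    note = None
    if not agree and 0.45 <= a / b <= 0.55:
        note = ("k-mer estimate is ~half the flow-cytometry size: "
                "the k-mer peak used may be the two-copy (doubled) peak; "
                "re-estimate at half its depth")
    return CombinedEstimate(mean, agree, note, kmer_est, flow_est)
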