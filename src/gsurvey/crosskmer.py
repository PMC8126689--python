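"""Haploid-vs-bulk cross k-mer comparison.

A bimodal k-mer spectrum is ambiguous: the lower peak can hold either
heterozygous k-mers (each haplotype-specific) or homozygous single-copy
k-mers sitting below a two-copy duplication peak.  A haploid sample (a
single gamete) breaks the tie.  Every distinct k-mer of the haploid
sample is looked up in the bulk WGS depth table; if the haploid set is as
well represented at the lower peak as the bulk's own distinct k-mers, the
lower peak is homozygous (duplication scenario), whereas a heterozygous
lower peak loses about half its mass in the haploid sample, which carries
only one allele per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kmerspec import KmerSpectrum, KmerTable, PeakCall

DUPLICATION = "duplication_consistent"
HETEROZYGOSITY = "heterozygosity_consistent"
INCONCLUSIVE = "inconclusive"


@dataclass
class CrossDepthDistribution:
    """Fraction of haploid-sample distinct k-mers at each bulk WGS depth.

    Depth 0 collects haploid k-mers absent from the WGS table.  Fractions
    sum to 1.
    """

    K: int
    depths: np.ndarray
    fractions: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for d, f in zip(self.depths, self.fractions):
                fh.write(f"{d}\t{f:.10g}\n")

    def mass(self, lo: int, hi: int) -> float:
        """Summed fraction over depths in [lo, hi]."""
        sel = (self.depths >= lo) & (self.depths <= hi)
        return float(self.fractions[sel].sum())


def cross_distribution(haploid_kmers, wgs_table: KmerTable) -> CrossDepthDistribution:
    """Distribute a haploid sample's distinct k-mers over bulk WGS depths."""
    if isinstance(haploid_kmers, KmerTable):
        if haploid_kmers.K != wgs_table.K:
            raise ValueError("haploid and WGS tables use different K")
        codes = haploid_kmers.codes
    else:
        codes = np.unique(np.asarray(haploid_kmers, dtype=np.uint64))
    if codes.size == 0:
        raise ValueError("empty haploid k-mer set")
    depths = wgs_table.depth_of(codes)
    uniq, counts = np.unique(depths, return_counts=True)
    return CrossDepthDistribution(wgs_table.K, uniq,
                                  counts / counts.sum())


@dataclass
class CrossVerdict:
    verdict: str
    ratio: float
    window: tuple
    cross_fraction: float
    wgs_fraction: float
    thresholds: dict = field(default_factory=dict)


def diagnose_peakA(cross: CrossDepthDistribution, wgs_peaks: PeakCall,
                   wgs_spec: KmerSpectrum, r_hi: float = 0.85,
                   r_lo: float = 0.75) -> CrossVerdict:
    """Decide whether the bulk spectrum's Peak A is homozygous or heterozygous.

    The evidence ratio r compares, within Peak A's +-25% depth window, the
    haploid sample's share of distinct k-mers against the bulk's own
    share.  Both shares are renormalized over depths at or above the error
    valley (discarding depth 0 and sub-valley k-mers, which are dominated
    by sequencing/amplification artifacts).  A haploid genome reproduces a
    homozygous Peak A in full (r ~ 1, duplication scenario) but retains
    only one of the two alleles of every heterozygous k-mer pair, which
    drives r towards ~0.5-0.7 in the heterozygosity scenario.  Verdict:
    duplication_consistent if r >= r_hi, heterozygosity_consistent if
    r <= r_lo, else inconclusive.
    """
    if wgs_peaks.peakA is None:
        raise ValueError("bulk spectrum has no Peak A")
    dA = wgs_peaks.peakA.depth
    lo = max(wgs_peaks.error_valley, int(round(0.75 * dA)))
    hi = int(round(1.25 * dA))
    valley = max(1, wgs_peaks.error_valley)

    cross_total = cross.mass(valley, np.iinfo(np.int64).max)
    if cross_total <= 0:
        raise ValueError("haploid sample has no k-mers above the error valley")
    cross_frac = cross.mass(lo, hi) / cross_total

    hist = wgs_spec.hist
    wgs_total = int(hist[valley:].sum())
    wgs_win = int(hist[lo:min(hi, len(hist) - 1) + 1].sum())
    if wgs_total == 0 or wgs_win == 0:
        raise ValueError("bulk spectrum empty in the Peak A window")
    wgs_frac = wgs_win / wgs_total

    r = cross_frac / wgs_frac
    if r >= r_hi:
        verdict = DUPLICATION
    elif r <= r_lo:
        verdict = HETEROZYGOSITY
    else:
        verdict = INCONCLUSIVE
    return CrossVerdict(verdict, r, (lo, hi), cross_frac, wgs_frac,
                        {"r_hi": r_hi, "r_lo": r_lo})
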