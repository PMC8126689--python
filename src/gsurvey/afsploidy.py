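"""Allele-frequency-spectrum ploidy classification from per-site base counts.

At every polymorphic site the four base counts are converted to fractions
and sorted from most to least frequent (rank 1..4).  Binning these ranked
fractions over many sites gives the read-count allele frequency spectrum:
haploids show no interior structure (any minor signal is sequencing
error), diploids a single mode at 0.5, and tetraploids additional modes
at 0.25 and 0.75 from one- and three-dose alleles.  The leftmost and
rightmost regions of the spectrum are excluded from mode search since in
real data they collect truncated peaks from population-level variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kmerspec import moving_average

BASE_COLS = ["A", "C", "G", "T"]

HAPLOID = "haploid"
DIPLOID = "diploid"
POLYPLOID = "polyploid"
INCONCLUSIVE = "inconclusive"


def site_fractions(counts) -> np.ndarray:
    """Sorted (descending) base fractions of one site; they sum to 1."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("site has zero total depth")
    return np.sort(c / total)[::-1]


@dataclass
class AlleleFrequencySpectrum:
    """Four per-rank histograms over [0, 1] plus filtering bookkeeping."""

    bin_width: float
    hist: np.ndarray  # shape (4, n_bins), counts of sites per rank
    n_sites: int  # sites passing filters
    n_input: int  # sites before filtering
    median_depth: float

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.hist.shape[1]
        return (np.arange(n) + 0.5) * self.bin_width

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.hist.T, columns=["first", "second", "third", "fourth"])
        df.insert(0, "bin_center", self.bin_centers)
        df.to_csv(path, sep="\t", index=False)


def build_afs(sites: pd.DataFrame, min_depth: int = 10, min_minor_count: int = 3,
              min_minor_frac: float = 0.05,
              bin_width: float = 0.01) -> AlleleFrequencySpectrum:
    """Filter sites and bin their ranked base fractions.

    Filters (SNP-quality surrogates): total depth >= ``min_depth``, second
    most frequent base count >= ``min_minor_count`` and fraction >=
    ``min_minor_frac``.  Sites failing them are excluded; a spectrum where
    every site was filtered out is returned empty (n_sites == 0) rather
    than raised, since that emptiness is itself the haploid signature.
    """
    if len(sites) == 0:
        raise ValueError("no input sites")
    counts = sites[BASE_COLS].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("site with zero total depth")
    order = np.sort(counts, axis=1)[:, ::-1]
    keep = (totals >= min_depth) & (order[:, 1] >= min_minor_count) & \
        (order[:, 1] / totals >= min_minor_frac)
    kept = order[keep]
    fracs = kept / kept.sum(axis=1, keepdims=True) if len(kept) else kept
    n_bins = int(round(1.0 / bin_width))
    hist = np.zeros((4, n_bins), dtype=np.int64)
    for r in range(4):
        if len(fracs):
            hist[r] = np.histogram(fracs[:, r], bins=n_bins, range=(0, 1))[0]
    med = float(np.median(totals[keep])) if keep.any() else float("nan")
    return AlleleFrequencySpectrum(bin_width, hist, int(keep.sum()),
                                   len(sites), med)


@dataclass
class PloidyVerdict:
    call: str
    modes: list  # (position, height) of detected interior modes
    thresholds: dict = field(default_factory=dict)


def classify_ploidy(afs: AlleleFrequencySpectrum,
                    interior: tuple = (0.15, 0.85), mode_tol: float = 0.05,
                    m_min_factor: float = 1.0, prominence_frac: float = 0.1,
                    smooth_window: Optional[int] = None) -> PloidyVerdict:
    """Call ploidy from interior modes of the rank-1 + rank-2 histogram.

    Mode search runs on the combined first/second-rank histogram within
    the ``interior`` window, after moving-average smoothing wide enough to
    iron out the depth-granularity comb (site fractions are multiples of
    1/depth; the automatic window spans about four granularity steps).  A
    mode must clear a height floor of ``m_min_factor`` times the mean
    interior bin mass — which rejects modes in a near-empty or flat-noise
    interior — and a prominence of ``prominence_frac`` times the tallest
    interior bin, which rejects residual comb ripple while keeping the
    genuinely broad, overlapping dosage modes of low-depth polyploid data.
    No interior modes -> haploid; modes near 0.25 and 0.75 -> polyploid;
    modes only near 0.5 -> diploid; anything else -> inconclusive.
    """
    combined = (afs.hist[0] + afs.hist[1]).astype(float)
    centers = afs.bin_centers
    if smooth_window is None:
        # cover ~4 depth-granularity steps, at least 5 bins, odd
        step = 1.0 / afs.median_depth if np.isfinite(afs.median_depth) and \
            afs.median_depth > 0 else 0.0
        smooth_window = max(5, int(np.ceil(4.0 * step / afs.bin_width)))
        smooth_window += 1 - smooth_window % 2
    sm = moving_average(combined, smooth_window)

    sel = (centers >= interior[0]) & (centers <= interior[1])
    seg, seg_centers = sm[sel], centers[sel]
    thresholds = {"interior": interior, "mode_tol": mode_tol,
                  "m_min_factor": m_min_factor,
                  "prominence_frac": prominence_frac,
                  "smooth_window": smooth_window}

    modes = []
    if seg.size and seg.max() > 0:
        m_min = m_min_factor * seg.mean()
        idx, props = find_peaks(seg, height=m_min,
                                prominence=prominence_frac * seg.max())
        modes = [(float(seg_centers[i]), float(seg[i])) for i in idx]
    thresholds["m_min"] = m_min_factor * float(seg.mean()) if seg.size else 0.0

    near = lambda target: any(abs(p - target) <= mode_tol for p, _ in modes)
    if not modes:
        call = HAPLOID
    elif near(0.25) and near(0.75):
        call = POLYPLOID
    elif all(abs(p - 0.5) <= mode_tol for p, _ in modes):
        call = DIPLOID
    else:
        call = INCONCLUSIVE
    return PloidyVerdict(call, modes, thresholds)


def read_site_counts(path) -> pd.DataFrame:
    """Read a per-site base-count table (contig, pos, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"contig", "pos", *BASE_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"site-count table missing columns: {sorted(missing)}")
    return df


def read_vcf_ad(path) -> pd.DataFrame:
    """Convenience reader: biallelic VCF records with AD allelic depths.

    Produces the same contig/pos/A/C/G/T frame as :func:`read_site_counts`,
    assigning REF and ALT depths to their bases.  Multi-allelic records
    take the first ALT only; records without AD are skipped.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if ref not in BASE_COLS or alt not in BASE_COLS:
                continue
            ad = np.zeros(2, dtype=int)
            found = False
            for sample in rec.samples.values():
                sad = sample.get("AD")
                if sad is not None:
                    ad += np.asarray(sad[:2], dtype=int)
                    found = True
            if not found:
                continue
            counts = dict.fromkeys(BASE_COLS, 0)
            counts[ref], counts[alt] = int(ad[0]), int(ad[1])
            rows.append({"contig": rec.contig, "pos": rec.pos, **counts})
    if not rows:
        raise ValueError("no usable AD records in VCF")
    return pd.DataFrame(rows)
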