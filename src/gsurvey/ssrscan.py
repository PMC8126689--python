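"""Perfect SSR detection, compound merging and landscape statistics.

An SSR locus is a maximal, non-extendable perfect tandem run of a
primitive 1-6 bp motif meeting a per-motif-length minimum copy threshold.
Motifs are pooled by their canonical form (lexicographic minimum over all
rotations of the motif and of its reverse complement), so (TG)n, (GT)n,
(CA)n and (AC)n all report as AC.  Runs of different periods that overlap
are resolved to the longer run, ties to the shorter motif.  SSR loci
separated by at most ``d_max`` bases chain head-to-tail into compound
SSRs.  Only perfect repeats are called: interrupted repeats surface as
compounds of their perfect pieces, which keeps the scanner equivalent to
an exact brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dna import decode, encode, revcomp

#: minimum full copies per motif length (community-standard MISA-like defaults)
DEFAULT_THRESHOLDS = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


def primitive_period(motif: str) -> str:
    """Shortest period of a motif ('ATAT' -> 'AT')."""
    n = len(motif)
    for p in range(1, n + 1):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return motif[:p]
    return motif


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over rotations of the motif and of its revcomp."""
    motif = primitive_period(motif.upper())
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


@dataclass
class SSRLocus:
    contig: str
    start: int  # 0-based half-open
    end: int
    motif: str  # as found at the locus start
    canonical: str
    copy_number: float  # may be fractional

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CompoundSSR:
    contig: str
    start: int
    end: int
    members: list  # ordered SSRLocus list

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return self.end - self.start


def _runs_of_period(arr: np.ndarray, m: int):
    """Maximal perfect tandem runs of period m as (start, end) intervals."""
    n = len(arr)
    if n < 2 * m:
        return
    eq = arr[m:] == arr[:-m]
    # boundaries of True runs in eq
    padded = np.concatenate([[False], eq, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e + m)  # tract occupies [s, e+m)


def find_ssrs(seq, thresholds: Optional[dict] = None,
              contig: str = "chr1") -> list:
    """Scan one sequence for perfect SSR loci.

    ``thresholds`` maps motif length (1-6) to the minimum number of full
    copies; motif lengths absent from the map are not searched.  Returns
    loci sorted by start after overlap resolution.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    arr = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)

    candidates = []
    for m, min_copies in sorted(thresholds.items()):
        if min_copies <= 0:
            raise ValueError("thresholds must be positive")
        for s, e in _runs_of_period(arr, m):
            if (e - s) // m < min_copies:
                continue
            motif = decode(arr[s:s + m])
            if len(primitive_period(motif)) != m:
                continue  # non-primitive motif; found at its true period
            candidates.append(SSRLocus(contig, s, e, motif,
                                       canonical_motif(motif), (e - s) / m))

    # longer run wins on overlap; ties to the shorter motif, then leftmost
    candidates.sort(key=lambda l: (-(l.end - l.start), len(l.motif), l.start))
    accepted = []
    occupied = np.zeros(len(arr), dtype=bool)
    for loc in candidates:
        if not occupied[loc.start:loc.end].any():
            accepted.append(loc)
            occupied[loc.start:loc.end] = True
    accepted.sort(key=lambda l: l.start)
    return accepted


def merge_compound(loci: list, d_max: int = 10):
    """Chain-merge sorted loci with head-to-tail gaps <= ``d_max``.

    Returns (singles, compounds); every input locus lands in exactly one
    output group.
    """
    for a, b in zip(loci, loci[1:]):
        if (a.contig, a.start) > (b.contig, b.start):
            raise ValueError("loci must be sorted by contig and start")
    singles, compounds = [], []
    group = []
    def flush():
        if len(group) == 1:
            singles.append(group[0])
        elif group:
            compounds.append(CompoundSSR(group[0].contig, group[0].start,
                                         group[-1].end, list(group)))
    for loc in loci:
        if group and loc.contig == group[-1].contig and \
                loc.start - group[-1].end <= d_max:
            group.append(loc)
        else:
            flush()
            group = [loc]
    flush()
    return singles, compounds


@dataclass
class SSRSummary:
    genome_content_fraction: float  # fraction of genome bases inside SSR loci
    density_per_mb: float  # loci per megabase
    mean_locus_length: float
    compound_fraction: float  # share of loci that are members of compounds
    motif_content: pd.DataFrame  # per-canonical-motif locus counts and bases
    n_loci: int
    n_compounds: int
    flagged_empty: bool = False


def ssr_summary(loci: list, compounds: list, genome_length: int) -> SSRSummary:
    """Landscape statistics of an SSR annotation."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not loci:
        empty = pd.DataFrame(columns=["canonical", "n_loci", "bases", "content"])
        return SSRSummary(0.0, 0.0, 0.0, 0.0, empty, 0, 0, flagged_empty=True)
    total_bases = sum(l.length for l in loci)
    in_compound = sum(c.n_members for c in compounds)
    rows = {}
    for l in loci:
        n, b = rows.get(l.canonical, (0, 0))
        rows[l.canonical] = (n + 1, b + l.length)
    motif_content = pd.DataFrame(
        [(k, n, b, b / genome_length) for k, (n, b) in sorted(rows.items())],
        columns=["canonical", "n_loci", "bases", "content"]
    ).sort_values("bases", ascending=False, ignore_index=True)
    return SSRSummary(
        genome_content_fraction=total_bases / genome_length,
        density_per_mb=len(loci) / (genome_length / 1e6),
        mean_locus_length=total_bases / len(loci),
        compound_fraction=in_compound / len(loci),
        motif_content=motif_content,
        n_loci=len(loci),
        n_compounds=len(compounds),
    )


def coverage_by_region(depth_track: np.ndarray, ssr_bed, te_bed) -> dict:
    """Mean read depth over SSR, TE and remaining genome bases.

    ``ssr_bed`` and ``te_bed`` are iterables of (start, end) 0-based
    half-open intervals; SSR takes precedence where they overlap, and the
    three classes partition the genome.  An empty class reports None.
    """
    depth_track = np.asarray(depth_track)
    n = len(depth_track)
    klass = np.zeros(n, dtype=np.uint8)  # 0 other, 1 TE, 2 SSR
    for s, e in te_bed:
        if s < 0 or e > n:
            raise ValueError("TE interval outside depth track")
        klass[s:e] = 1
    for s, e in ssr_bed:
        if s < 0 or e > n:
            raise ValueError("SSR interval outside depth track")
        klass[s:e] = 2
    out = {}
    for name, code in (("SSR", 2), ("TE", 1), ("other", 0)):
        sel = klass == code
        out[name] = float(depth_track[sel].mean()) if sel.any() else None
    return out


def loci_to_bed(loci: list, path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.contig}\t{l.start}\t{l.end}\t{l.motif}\t"
                     f"{l.canonical}\t{l.copy_number:.2f}\n")


def compounds_to_bed(compounds: list, path) -> None:
    with open(path, "w") as fh:
        for c in compounds:
            members = ",".join(f"{m.motif}:{m.start}-{m.end}" for m in c.members)
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\tcompound\t"
                     f"{c.n_members}\t+\t{members}\n")


def read_bedgraph(path, genome_length: int) -> np.ndarray:
    """Expand a single-contig bedGraph into a per-base depth array."""
    track = np.zeros(genome_length, dtype=float)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "depth"])
    for _, row in df.iterrows():
        track[int(row.start):int(row.end)] = row.depth
    return track
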