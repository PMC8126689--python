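"""Synthetic genomes, read sets and per-site base counts.

This module emulates the data a genome survey of a complex crustacean-like
genome consumes: a diploid (optionally polyploid) genome with controlled
heterozygosity between haplotypes, interspersed repeat (TE) families,
two-copy segmental homo-duplications, planted single and compound SSR
tracts, uniform-coverage error-bearing short reads, a haploid gamete read
set with optional amplification bias, and multinomial read counts at SNP
sites.  Every planted feature is returned as an exact truth annotation so
downstream detectors can be validated without any external data.

Coordinates follow each format's convention: truth BED intervals are
0-based half-open, the SNP table is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import decode, encode, random_codes

# named sub-streams of the single user-facing seed, so each stage can be
# re-run independently while staying reproducible
_STREAM_GENOME = 0
_STREAM_READS = 1
_STREAM_COUNTS = 2


class SizingError(ValueError):
    """Requested feature content does not fit in the genome."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Full parameterization of one simulated genome.

    ``het_rate`` is the per-base substitution rate between haplotypes
    (0.0026 corresponds to 0.26% heterozygosity).  ``dup_fraction`` is the
    fraction of the genome residing in two-copy segmental duplications,
    counting both copies.  ``ssr_config`` lists (motif, copies, count)
    tracts to plant; with probability ``compound_rate`` a planted tract
    gets a second, different-motif tract appended head-to-tail (1-3 bp
    gap), forming a compound SSR.  ``te_families`` lists
    (consensus_length, copy_number) interspersed repeat families.
    """

    seed: int
    genome_length: int
    ploidy: int = 2
    het_rate: float = 0.0026
    dup_fraction: float = 0.0
    dup_segment_length: int = 5000
    ssr_config: tuple = ()
    compound_rate: float = 0.0
    te_families: tuple = ()
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 0.0 <= self.het_rate < 1.0:
            raise ValueError("het_rate must be in [0, 1)")
        if not 0.0 <= self.dup_fraction < 1.0:
            raise ValueError("dup_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ReadSimSpec:
    """Read-simulation parameters (single-end, uniform substitution errors)."""

    coverage: float
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0
    amplification_bias: float = 1.0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.amplification_bias <= 0:
            raise ValueError("amplification_bias must be positive")


@dataclass
class SimulatedGenome:
    """Haplotype sequences plus exact truth annotations."""

    spec: SyntheticGenomeSpec
    haplotypes: list  # list of uint8 code arrays, one per haplotype copy
    snps: pd.DataFrame  # pos (1-based), ref, alt, dosage, carriers
    ssr_loci: pd.DataFrame  # start, end (0-based half-open), motif, copies, compound_id
    te_bed: pd.DataFrame  # start, end, family
    dup_bed: pd.DataFrame  # start, end, role (source|copy), pair_id
    contig: str = "chr1"

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def haplotype_names(self):
        return [f"{self.contig}_hap{i}" for i in range(self.ploidy)]

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, arr in zip(self.haplotype_names(), self.haplotypes):
                fh.write(f">{name}\n")
                s = decode(arr)
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")

    def write_truth(self, prefix) -> None:
        prefix = str(prefix)
        self.snps.to_csv(prefix + ".snps.tsv", sep="\t", index=False)
        ssr = self.ssr_loci.copy()
        ssr.insert(0, "contig", self.contig)
        ssr.to_csv(prefix + ".ssr.bed", sep="\t", index=False, header=False)
        te = self.te_bed.copy()
        te.insert(0, "contig", self.contig)
        te.to_csv(prefix + ".te.bed", sep="\t", index=False, header=False)
        dup = self.dup_bed.copy()
        dup.insert(0, "contig", self.contig)
        dup.to_csv(prefix + ".dup.bed", sep="\t", index=False, header=False)


@dataclass
class ReadSet:
    """Simulated single-end reads as a dense code matrix.

    ``codes`` has one row per read; ``hap``, ``start`` and ``strand``
    record the provenance of each read on the source haplotypes.
    """

    codes: np.ndarray
    hap: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    read_length: int

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def total_bases(self) -> int:
        return self.codes.size

    def sequences(self):
        for row in self.codes:
            yield decode(row)

    def write_fastq(self, path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences()):
                fh.write(f"@read{i} hap={self.hap[i]} pos={self.start[i]} "
                         f"strand={'-' if self.strand[i] else '+'}\n"
                         f"{seq}\n+\n{qual}\n")


class _Allocator:
    """Places disjoint intervals uniformly at random into remaining free space."""

    def __init__(self, length: int, rng: np.random.Generator, pad: int = 2):
        self.free = [(0, length)]
        self.rng = rng
        self.pad = pad

    def place(self, size: int, pad: int = None) -> int:
        pad = self.pad if pad is None else pad
        need = size + 2 * pad
        weights = np.array([max(0, b - a - need + 1) for a, b in self.free], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise SizingError("planted feature content exceeds genome length")
        gi = self.rng.choice(len(self.free), p=weights / total)
        a, b = self.free[gi]
        off = self.rng.integers(0, b - a - need + 1)
        start = a + pad + off
        # split the free gap around the claimed (padded) interval
        self.free[gi:gi + 1] = [(a, start - pad), (start + size + pad, b)]
        return int(start)


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _plant_ssr_tract(seq, start, motif_codes, copies):
    m = len(motif_codes)
    tract = np.tile(motif_codes, copies)
    seq[start:start + m * copies] = tract
    # break periodicity at both flanks so the planted tract is maximal:
    # a run of period m extends left iff seq[s-1] == seq[s-1+m]
    left = start - 1
    if left >= 0 and seq[left] == seq[left + m]:
        seq[left] = (seq[left + m] + 1) % 4
    right = start + m * copies
    if right < len(seq) and seq[right] == seq[right - m]:
        seq[right] = (seq[right - m] + 1) % 4


def simulate_genome(spec: SyntheticGenomeSpec) -> SimulatedGenome:
    """Build haplotype sequences and exact truth annotations from ``spec``."""
    rng = _substream(spec.seed, _STREAM_GENOME)
    L = spec.genome_length
    ancestral = random_codes(rng, L, spec.base_composition)
    alloc = _Allocator(L, rng)

    # interspersed repeats: identical copies of a family consensus
    te_rows = []
    for fam_id, (clen, copies) in enumerate(spec.te_families):
        consensus = random_codes(rng, int(clen))
        for _ in range(int(copies)):
            s = alloc.place(int(clen))
            ancestral[s:s + int(clen)] = consensus
            te_rows.append((s, s + int(clen), f"TE{fam_id}"))
    te_bed = pd.DataFrame(te_rows, columns=["start", "end", "family"]).sort_values(
        "start", ignore_index=True) if te_rows else pd.DataFrame(
        columns=["start", "end", "family"])

    # SSR tracts, optionally compounded head-to-tail with a different motif
    ssr_rows = []
    compound_id = 0
    motifs = [m for m, _, _ in spec.ssr_config]
    for motif, copies, count in spec.ssr_config:
        mc = encode(motif)
        for _ in range(int(count)):
            partner = None
            if spec.compound_rate > 0 and len(motifs) > 1 and \
                    rng.random() < spec.compound_rate:
                others = [x for x in motifs if x != motif]
                pm = others[rng.integers(len(others))]
                pc = next(c for mm, c, _ in spec.ssr_config if mm == pm)
                partner = (encode(pm), int(pc))
            if partner is None:
                s = alloc.place(len(mc) * copies, pad=12)
                _plant_ssr_tract(ancestral, s, mc, copies)
                ssr_rows.append((s, s + len(mc) * copies, motif, copies, -1))
            else:
                gap = int(rng.integers(1, 4))
                pmc, pcopies = partner
                span = len(mc) * copies + gap + len(pmc) * pcopies
                s = alloc.place(span, pad=12)
                s2 = s + len(mc) * copies + gap
                _plant_ssr_tract(ancestral, s, mc, copies)
                _plant_ssr_tract(ancestral, s2, pmc, pcopies)
                # gap bases must not extend either neighbouring tract
                for g in range(s + len(mc) * copies, s2):
                    forbid = {ancestral[g - len(mc)]}
                    if g + len(pmc) < L:
                        forbid.add(ancestral[g + len(pmc)])
                    choices = [b for b in range(4) if b not in forbid]
                    ancestral[g] = choices[rng.integers(len(choices))]
                ssr_rows.append((s, s + len(mc) * copies, motif, copies, compound_id))
                ssr_rows.append((s2, s2 + len(pmc) * pcopies, decode(pmc),
                                 pcopies, compound_id))
                compound_id += 1
    ssr_loci = pd.DataFrame(
        ssr_rows, columns=["start", "end", "motif", "copies", "compound_id"]
    ).sort_values("start", ignore_index=True) if ssr_rows else pd.DataFrame(
        columns=["start", "end", "motif", "copies", "compound_id"])

    # segmental homo-duplications: copy background segments elsewhere
    dup_rows = []
    n_seg = int(round(spec.dup_fraction * L / (2 * spec.dup_segment_length)))
    for pair_id in range(n_seg):
        slen = spec.dup_segment_length
        src = alloc.place(slen)
        dst = alloc.place(slen)
        dup_rows.append((src, src + slen, "source", pair_id))
        dup_rows.append((dst, dst + slen, "copy", pair_id))
    for src0, _, _, pid in [r for r in dup_rows if r[2] == "source"]:
        dst0 = next(r[0] for r in dup_rows if r[2] == "copy" and r[3] == pid)
        ancestral[dst0:dst0 + spec.dup_segment_length] = \
            ancestral[src0:src0 + spec.dup_segment_length]
    dup_bed = pd.DataFrame(
        dup_rows, columns=["start", "end", "role", "pair_id"]
    ).sort_values("start", ignore_index=True) if dup_rows else pd.DataFrame(
        columns=["start", "end", "role", "pair_id"])

    # heterozygous SNPs between haplotype copies; SSR tracts (plus their
    # periodicity-breaking flanks) are kept SNP-free so truth intervals
    # stay exact on every haplotype
    allowed = np.ones(L, dtype=bool)
    for s, e in zip(ssr_loci["start"], ssr_loci["end"]):
        allowed[max(0, s - 2):min(L, e + 2)] = False
    n_snps = rng.binomial(L, spec.het_rate) if spec.ploidy > 1 else 0
    idx_allowed = np.flatnonzero(allowed)
    if n_snps > len(idx_allowed):
        raise SizingError("het_rate too high for remaining SNP-eligible positions")
    pos0 = np.sort(rng.choice(idx_allowed, size=n_snps, replace=False)) \
        if n_snps else np.empty(0, dtype=int)
    ref = ancestral[pos0]
    alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
    if spec.ploidy == 2:
        dosage = np.ones(n_snps, dtype=int)
    else:
        dosage = rng.integers(1, spec.ploidy, size=n_snps) if n_snps else \
            np.empty(0, dtype=int)
    carriers = []
    for d in dosage:
        carriers.append(tuple(sorted(rng.permutation(spec.ploidy)[:d].tolist())))

    haplotypes = []
    for h in range(spec.ploidy):
        arr = ancestral.copy()
        if n_snps:
            mask = np.array([h in c for c in carriers])
            arr[pos0[mask]] = alt[mask]
        haplotypes.append(arr)

    snps = pd.DataFrame({
        "contig": "chr1",
        "pos": pos0 + 1,
        "ref": [decode(np.array([b], dtype=np.uint8)) for b in ref],
        "alt": [decode(np.array([b], dtype=np.uint8)) for b in alt],
        "dosage": dosage,
        "carriers": [",".join(map(str, c)) for c in carriers],
    })
    return SimulatedGenome(spec, haplotypes, snps, ssr_loci, te_bed, dup_bed)


def extract_haploid(sim: SimulatedGenome, which: int) -> np.ndarray:
    """One haplotype copy (the in-silico gamete), carrying one allele per SNP."""
    if not 0 <= which < sim.ploidy:
        raise IndexError(f"haplotype index {which} out of range (ploidy {sim.ploidy})")
    return sim.haplotypes[which]


def simulate_reads(haplotypes, rs: ReadSimSpec, dup_intervals=None) -> ReadSet:
    """Draw uniform single-end reads over haplotype copies.

    Total bases approximate ``coverage`` times the haploid genome length.
    When ``amplification_bias`` > 1 and ``dup_intervals`` (0-based half-open
    (start, end) pairs) are given, read starts inside duplicated segments
    are oversampled by that factor, mimicking preferential whole-genome
    amplification of duplicated sequence in single-cell libraries.
    """
    if isinstance(haplotypes, np.ndarray):
        haplotypes = [haplotypes]
    haplotypes = list(haplotypes)
    Lr = rs.read_length
    glen = len(haplotypes[0])
    if any(len(h) < Lr for h in haplotypes):
        raise ValueError("read length exceeds shortest haplotype")
    rng = _substream(rs.seed, _STREAM_READS)

    n_reads = int(round(rs.coverage * glen / Lr))
    hap = rng.integers(0, len(haplotypes), size=n_reads)
    start = rng.integers(0, glen - Lr + 1, size=n_reads)

    if rs.amplification_bias != 1.0 and dup_intervals is not None and len(dup_intervals):
        dup_positions = np.concatenate(
            [np.arange(s, e) for s, e in dup_intervals])
        n_extra = int(round(n_reads * (rs.amplification_bias - 1.0)
                            * len(dup_positions) / glen))
        if n_extra > 0:
            es = dup_positions[rng.integers(0, len(dup_positions), size=n_extra)]
            es = np.minimum(es, glen - Lr)
            start = np.concatenate([start, es])
            hap = np.concatenate([hap, rng.integers(0, len(haplotypes), size=n_extra)])

    n = len(start)
    codes = np.empty((n, Lr), dtype=np.uint8)
    offs = np.arange(Lr)
    for h, arr in enumerate(haplotypes):
        rows = np.flatnonzero(hap == h)
        if rows.size:
            codes[rows] = arr[start[rows, None] + offs]
    strand = rng.random(n) < 0.5
    rev = np.flatnonzero(strand)
    codes[rev] = 3 - codes[rev][:, ::-1]

    if rs.error_rate > 0:
        n_err = rng.binomial(codes.size, rs.error_rate)
        flat = rng.choice(codes.size, size=n_err, replace=False)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        codes.ravel()[flat] = (codes.ravel()[flat] + shift) % 4

    return ReadSet(codes, hap, start, strand.astype(np.uint8), Lr)


def simulate_site_counts(sim: SimulatedGenome, depth: float, n_sites: int,
                         seed: int, error_rate: float = 0.0) -> pd.DataFrame:
    """Multinomial base counts at planted SNP sites.

    Allele probabilities are allele copy-number over ploidy; per-site totals
    are Poisson(``depth``).  For a haploid genome (no planted SNPs) random
    positions are sampled instead and counts are monomorphic up to the
    sequencing ``error_rate``.  Returns a frame with columns
    contig, pos (1-based), A, C, G, T.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _substream(seed, _STREAM_COUNTS)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}

    if len(sim.snps):
        if n_sites > len(sim.snps):
            raise ValueError("n_sites exceeds number of planted SNPs")
        pick = np.sort(rng.choice(len(sim.snps), size=n_sites, replace=False))
        sub = sim.snps.iloc[pick]
        pos = sub["pos"].to_numpy()
        refs = np.array([base_index[b] for b in sub["ref"]])
        alts = np.array([base_index[b] for b in sub["alt"]])
        dosage = sub["dosage"].to_numpy()
    else:
        pos0 = rng.choice(len(sim.haplotypes[0]), size=n_sites, replace=False)
        pos0.sort()
        pos = pos0 + 1
        refs = sim.haplotypes[0][pos0].astype(int)
        alts = refs  # monomorphic
        dosage = np.zeros(n_sites, dtype=int)

    ploidy = sim.ploidy
    totals = np.maximum(rng.poisson(depth, size=n_sites), 1)
    counts = np.zeros((n_sites, 4), dtype=int)
    for i in range(n_sites):
        p = np.zeros(4)
        p[refs[i]] += (ploidy - dosage[i]) / ploidy
        p[alts[i]] += dosage[i] / ploidy
        if error_rate > 0:
            p = p * (1 - error_rate) + (1 - p) * (error_rate / 3)
            p /= p.sum()
        counts[i] = rng.multinomial(totals[i], p)
    out = pd.DataFrame(counts, columns=["A", "C", "G", "T"])
    out.insert(0, "pos", pos)
    out.insert(0, "contig", sim.contig)
    return out


def depth_from_reads(starts, read_length: int, genome_length: int) -> np.ndarray:
    """Per-base depth track from read start positions (single contig)."""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(diff, np.asarray(starts), 1)
    ends = np.minimum(np.asarray(starts) + read_length, genome_length)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])
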