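"""Paralog pairing, NG86 synonymous divergence and WGD-peak detection.

A whole-genome duplication leaves a burst of paralog pairs of similar
age, visible as an interior mode in the distribution of per-pair
synonymous-site divergence (Ks); ongoing small-scale duplication alone
yields an L-shaped distribution concentrated near zero.  The pipeline:
pair proteins by reciprocal best hit under exact pairwise alignment,
back-translate a global protein alignment to codons, drop gap columns and
their neighbourhoods, estimate Ks per pair by the Nei-Gojobori (1986)
counting method with Jukes-Cantor correction, and classify the Ks
histogram shape.

The NG86 estimator is exact and dependency-free; its Ks values differ
numerically from likelihood estimators (e.g. codon-model ML) but the
distribution shape, which is what the WGD call uses, is preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy.signal import find_peaks

from .kmerspec import moving_average

L_SHAPED = "L_shaped"
WGD_PEAK = "wgd_peak"
INCONCLUSIVE = "inconclusive"

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NTS = "ACGT"

#: codons whose third position is fourfold degenerate and whose first and
#: second positions admit no synonymous change (S = 1 site per codon)
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT")


def _translate(codon: str) -> Optional[str]:
    return None if codon in _STOPS else _CODON_TABLE.get(codon)


def _syn_fraction(codon: str) -> np.ndarray:
    """Per-position fraction of single-nt changes that are synonymous.

    Changes producing stop codons count as nonsynonymous, so site counts
    always satisfy S + N = 3 per codon.
    """
    aa = _CODON_TABLE[codon]
    out = np.zeros(3)
    for pos in range(3):
        syn = 0
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                syn += 1
        out[pos] = syn / 3
    return out


_SYN_SITES = {c: _syn_fraction(c) for c in _CODON_TABLE}


def _codon_differences(c1: str, c2: str):
    """Average (syn, nonsyn) differences over all minimal mutation paths.

    Paths passing through stop codons are excluded; if every path hits a
    stop, all paths are used (a rare degenerate case).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # all paths traverse stops
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                same = nxt not in _STOPS and cur not in _STOPS and \
                    _CODON_TABLE.get(cur) == _CODON_TABLE.get(nxt)
                sd, nd = (sd + 1, nd) if same else (sd, nd + 1)
                cur = nxt
            results.append((sd, nd))
    arr = np.asarray(results, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


@dataclass
class GenePair:
    """Aligned, filtered codon columns of two coding sequences."""

    codons_a: list
    codons_b: list

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class KsEstimate:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float
    pn: float
    ds: float  # Ks (nan when invalid)
    dn: float  # Ka
    valid: bool
    n_codons: int = 0


def _protein_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def rbh_pairs(proteins: list) -> list:
    """Reciprocal-best-hit pairs under exact pairwise local alignment.

    ``proteins`` is a list of amino-acid strings.  Pair (i, j) is kept iff
    j is i's best-scoring non-self hit and vice versa; score ties break to
    the smaller index.  Each sequence appears in at most one pair.
    """
    n = len(proteins)
    if n == 0:
        raise ValueError("empty protein set")
    if n == 1:
        return []
    aligner = _protein_aligner("local")
    scores = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            scores[i, j] = scores[j, i] = aligner.score(proteins[i], proteins[j])
    best = scores.argmax(axis=1)  # argmax takes the smallest index on ties
    pairs = []
    for i in range(n):
        j = int(best[i])
        if j > i and int(best[j]) == i:
            pairs.append((i, j))
    return pairs


def align_codons(cds_a: str, cds_b: str, gap_flank: int = 3) -> GenePair:
    """Codon alignment via global protein alignment, with gap-region filtering.

    Both CDS must be in frame (length divisible by 3) with no internal
    stop codon.  Gap columns and every column within ``gap_flank`` codons
    of a gap column are removed, a simplified well-aligned-region filter.
    """
    codons = []
    for name, cds in (("a", cds_a), ("b", cds_b)):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS {name} length not divisible by 3")
        cs = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if cs and cs[-1] in _STOPS:
            cs = cs[:-1]  # trailing stop is fine
        for k, c in enumerate(cs):
            if c in _STOPS:
                raise ValueError(f"premature stop codon at codon {k + 1} of CDS {name}")
        codons.append(cs)
    prot_a = str(Seq("".join(codons[0])).translate())
    prot_b = str(Seq("".join(codons[1])).translate())
    aln = _protein_aligner("global").align(prot_a, prot_b)[0]
    ga, gb = str(aln[0]), str(aln[1])

    cols_a, cols_b, gap_cols = [], [], []
    ia = ib = 0
    for col, (x, y) in enumerate(zip(ga, gb)):
        if x == "-" or y == "-":
            gap_cols.append(col)
            cols_a.append(None)
            cols_b.append(None)
        else:
            cols_a.append(codons[0][ia])
            cols_b.append(codons[1][ib])
        ia += x != "-"
        ib += y != "-"
    drop = set()
    for g in gap_cols:
        drop.update(range(g - gap_flank, g + gap_flank + 1))
    keep = [c for c in range(len(cols_a))
            if c not in drop and cols_a[c] is not None]
    return GenePair([cols_a[c] for c in keep], [cols_b[c] for c in keep])


def ng86_ks(gp: GenePair) -> KsEstimate:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Synonymous site counts come from single-nucleotide mutation scanning
    of the universal code, averaged over the two sequences; multi-hit
    codons average differences over all minimal mutation paths.  The
    estimate is flagged invalid when ps >= 0.75 (JC correction undefined).
    """
    sites_a = sites_b = 0.0
    Sd = Nd = 0.0
    for ca, cb in zip(gp.codons_a, gp.codons_b):
        sites_a += _SYN_SITES[ca].sum()
        sites_b += _SYN_SITES[cb].sum()
        sd, nd = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (sites_a + sites_b) / 2
    N = 3 * gp.n_codons - S
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0

    def jc(p):
        if p >= 0.75:
            return float("nan"), False
        return -0.75 * np.log(1 - 4 * p / 3), True

    ds, ok_s = jc(ps)
    dn, _ = jc(pn)
    return KsEstimate(S, N, Sd, Nd, ps, pn, ds, dn,
                      valid=ok_s and gp.n_codons > 0, n_codons=gp.n_codons)


def ks_pipeline(cds_pairs: list) -> list:
    """align_codons + ng86_ks over (cds_a, cds_b) tuples."""
    return [ng86_ks(align_codons(a, b)) for a, b in cds_pairs]


@dataclass
class KsDistributionVerdict:
    call: str
    mode: Optional[float] = None  # interior mode position, if any
    n_values: int = 0
    warning: Optional[str] = None
    params: dict = field(default_factory=dict)


def classify_ks(ks_values, bin_width: float = 0.05, ks_max: float = 3.0,
                p_min: float = 0.05, smooth_window: int = 3,
                noise_z: float = 4.0, head_bins: int = 4,
                min_values: int = 100) -> KsDistributionVerdict:
    """Classify a Ks distribution as L-shaped or WGD-peaked.

    The histogram over (0, ks_max] is smoothed; the call is L_shaped when
    the global maximum sits in the head region (the first ``head_bins``
    bins, where per-pair estimation noise smears the zero-divergence
    excess) and no interior peak qualifies; wgd_peak when one does;
    inconclusive otherwise (including too few values).  A qualifying
    interior peak lies beyond the head region and needs prominence of at
    least ``p_min`` times the tallest bin *and* ``noise_z`` times the
    Poisson counting noise at its own height (sqrt of the bin count), so
    random fluctuations along an L-shaped tail do not masquerade as a
    duplication burst.
    """
    vals = np.asarray([v for v in ks_values if np.isfinite(v) and 0 < v <= ks_max])
    params = {"bin_width": bin_width, "ks_max": ks_max, "p_min": p_min,
              "noise_z": noise_z, "head_bins": head_bins}
    if len(vals) < min_values:
        return KsDistributionVerdict(INCONCLUSIVE, None, len(vals),
                                     f"only {len(vals)} valid Ks values "
                                     f"(< {min_values})", params)
    n_bins = int(round(ks_max / bin_width))
    hist, edges = np.histogram(vals, bins=n_bins, range=(0, ks_max))
    sm = moving_average(hist.astype(float), smooth_window)
    centers = (edges[:-1] + edges[1:]) / 2

    idx, props = find_peaks(sm, prominence=p_min * sm.max())
    interior = [(centers[i], sm[i]) for i, prom in
                zip(idx, props["prominences"])
                if i >= head_bins and prom >= noise_z * np.sqrt(max(sm[i], 1.0))]
    if interior:
        mode = max(interior, key=lambda t: t[1])[0]
        return KsDistributionVerdict(WGD_PEAK, float(mode), len(vals),
                                     params=params)
    if sm.argmax() < head_bins:
        return KsDistributionVerdict(L_SHAPED, None, len(vals), params=params)
    return KsDistributionVerdict(INCONCLUSIVE, None, len(vals), params=params)


def simulate_paralog_pairs(n_pairs: int, n_codons: int, ks, seed: int) -> list:
    """Synthetic paralog pairs with planted synonymous divergence.

    Each pair duplicates a random CDS built from fourfold-degenerate
    codons (so every third position is a neutral site and S = n_codons
    exactly) and evolves the third positions of the two copies apart under
    a Jukes-Cantor process to total synonymous distance ``ks`` (a scalar
    or per-pair array).  Returns (cds_a, cds_b) tuples.
    """
    rng = np.random.default_rng(seed)
    ks = np.broadcast_to(np.asarray(ks, dtype=float), (n_pairs,))
    pairs = []
    for d in ks:
        prefixes = rng.integers(0, len(FOURFOLD_PREFIXES), size=n_codons)
        thirds = rng.integers(0, 4, size=n_codons)
        p_diff = 0.75 * (1 - np.exp(-4 * d / 3))
        mut = rng.random(n_codons) < p_diff
        thirds_b = thirds.copy()
        thirds_b[mut] = (thirds[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        cds_a = "".join(FOURFOLD_PREFIXES[p] + _NTS[t]
                        for p, t in zip(prefixes, thirds))
        cds_b = "".join(FOURFOLD_PREFIXES[p] + _NTS[t]
                        for p, t in zip(prefixes, thirds_b))
        pairs.append((cds_a, cds_b))
    return pairs
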