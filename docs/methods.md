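# Methods

`gsurvey` implements the computational core of a short-read genome survey
for genomes that are hard to assemble — high heterozygosity, abundant
segmental homo-duplication, and extreme microsatellite (SSR) content, the
combination found in penaeid shrimp. Every analysis runs end to end on
synthetic data generated by the package itself, so each detector is
validated against exact planted truth.

## K-mer spectrum model (`kmerspec`)

Reads are decomposed into canonical k-mers (the lexicographic minimum of a
k-mer and its reverse complement; default K = 19, capped at 31 so a k-mer
packs into 64 bits). The depth spectrum `hist[d]` counts distinct k-mers
seen at depth d. For a diploid sequenced at base coverage C with read
length L, k-mer coverage is M = C·(L−K+1)/L; homozygous single-copy k-mers
mode at M, heterozygous k-mers at M/2 (each haplotype contributes its own
allele), and two-copy duplicated k-mers at 2M. Counting is exact (packed
codes, sort, run-length encode); windows containing non-ACGT characters
are skipped; the histogram is truncated at depth 10,000 with deeper k-mers
binned in the last cell.

**Peak calling.** The error valley is the first depth where the raw
histogram turns upward. Peaks are local maxima of the moving-average
smoothed histogram (window 3, edge-replicated padding so no artificial
dips appear at the boundaries) beyond the valley, with prominence at least
1% of the segment maximum. **Peak A is the first *major* peak** — the
first whose ±25% depth-window mass reaches 10% of the largest peak's mass.
The mass condition matters: trace heterozygosity always produces a small
half-depth bump that a pure first-local-maximum rule would promote to
Peak A, doubling the genome-size estimate and inverting the duplication
diagnosis. Minor bumps remain listed in the peak call. Peak B is the first
later peak within ±20% of twice Peak A's depth ("about twice" being the
only constraint the doubling relation imposes).

**Genome size.** G = N·(L−K+1)/(L·M), where N is the number of sequenced
bases and M the chosen k-mer peak depth. Because the window count equals
N·(L−K+1)/L, this is exactly (total k-mer count)/M. Interpreting N as the
*window* count instead would bias the estimate by (L−K+1)/L (≈ 12% at
L=150, K=19), which both parameter recovery on simulations and agreement
with flow-cytometry sizes rule out. Flow-cytometry masses convert at
1 pg ≈ 978 Mb; the combined estimate is the unweighted mean with a 15%
agreement flag, plus a diagnostic note when the k-mer value is ~half the
flow value (the signature of using the doubled peak for M).

**Heterozygosity proxy.** Per isolated heterozygous site, each haplotype
contributes K private k-mers, so h ≈ (half-depth distinct mass)/(2K ×
full-depth distinct mass). Masses are ±25% window sums for both peaks so
the window-truncation bias largely cancels; when only the homozygous peak
exists, the half-depth window is read directly off the histogram, making
the zero-heterozygosity limit return ≈0. This is a spectrum-based
approximation validated only by parameter recovery on simulations (planted
0.005 recovered as ≈0.0045–0.0049); it is not a mixture-model fit and
carries a mild (~10%) downward bias from window truncation and SNP
clustering.

## Duplication vs heterozygosity (`crosskmer`)

A bimodal spectrum is ambiguous: the lower peak is either heterozygous
k-mers (conventional reading) or homozygous single-copy k-mers under a
two-copy duplication peak. A haploid sample (single gamete) resolves it.
Each distinct haploid k-mer is looked up in the bulk depth table; the
evidence ratio r compares the haploid set's share in Peak A's ±25% window
with the bulk's own distinct-k-mer share, both renormalized over depths at
or above the error valley (depth-0 and sub-valley k-mers — dominated by
sequencing and single-cell amplification artifacts — are excluded; the
depth-0 bucket is still reported).

If Peak A is homozygous, the haploid genome contains every one of its
k-mers: r ≈ 1. If Peak A is heterozygous, the haploid sample carries one
allele per site and retains exactly half of the bulk's heterozygous
distinct mass while keeping all homozygous mass, which pushes r into
[0.5, 0.7) (0.5 in the low-h limit, ≈0.67 at h = 0.02; the drift with h
comes from the haploid set's smaller renormalization denominator).
Duplication keeps r ≈ 1.00–1.05. The default thresholds r_hi = 0.85 and
r_lo = 0.75 sit in the gap, derived from this analysis before any test was
run; simulated scenarios give r ≈ 1.02 (duplication) and ≈ 0.67
(heterozygosity) with per-seed scatter well under 0.01 at 1 Mb / 50×.
Amplification bias only reshapes peak heights, so the verdict — which
weights each distinct k-mer once — is insensitive to it.

## AFS ploidy classification (`afsploidy`)

Per SNP site the four base counts become sorted fractions (rank 1–4).
Sites pass SNP-quality surrogates: total depth ≥ 10, minor count ≥ 3,
minor fraction ≥ 0.05 (the counts are assumed pre-called; read mapping and
variant calling are out of scope, and a pileup-style TSV or an AD-bearing
VCF feeds the module). An input whose every site fails the filters yields
an *empty* spectrum rather than an error: after quality filtering a
haploid produces no credible polymorphic sites, and that emptiness is the
haploid signature.

Mode search runs on the combined rank-1 + rank-2 histogram (bin width
0.01) inside the interior window [0.15, 0.85] — the flanks collect the
truncated peaks that population-level variation produces in real data.
Because site fractions are multiples of 1/depth, the raw histogram is a
comb; the moving-average window automatically spans ~4 granularity steps
(≥5 bins). A mode must clear a height of 1× the mean interior bin mass
(rejects near-empty/flat interiors) and a prominence of 10% of the
interior maximum (rejects residual comb ripple). Stricter rules — e.g. a
2×-mean height floor or 25%-of-max prominence — reject genuine tetraploid
data at depth 30–60, where the 0.25/0.5/0.75 dosage modes are broad and
overlapping (interior maximum only ≈1.3× the interior mean). Calls:
no interior modes → haploid; modes near 0.25 *and* 0.75 (±0.05) →
polyploid; modes only near 0.5 → diploid; otherwise inconclusive. The
defaults were frozen after a 180-classification sweep (20 seeds ×
ploidy {1,2,4} × depth {30,60,100}, 10⁴ sites) scored 180/180, and the
diploid call survives 5% uniform-random contamination.

## SSR landscape (`ssrscan`)

Perfect tandem repeats only: a locus is a maximal, non-extendable run of a
primitive 1–6 bp motif meeting MISA-like minimum copies (mono ≥12, di ≥6,
tri ≥4, tetra ≥3, penta ≥3, hexa ≥3). Perfect-only keeps the scanner
bit-exact against a quadratic brute-force oracle; interrupted repeats
surface as compounds of their perfect pieces. Motifs pool by canonical
form (minimum over rotations of the motif and of its reverse complement),
making the per-motif content table strand-invariant. Overlapping calls of
different periods resolve to the longer run, ties to the shorter motif,
then the leftmost. Loci on the same contig separated by ≤ d_max (default
10 bp; 100 approximates MISA-style compounds) chain head-to-tail into
compound SSRs. Summary statistics: genome content fraction, loci per Mb,
mean locus length, compound membership fraction, per-canonical-motif
content. `coverage_by_region` partitions every base into SSR / TE / other
(SSR wins overlaps) and reports class mean depths, with empty classes
`None` rather than zero.

## Ks and WGD detection (`kswgd`)

Paralogs pair by reciprocal best hit under exact pairwise local alignment
(BLOSUM62, affine gaps −10/−1); desk-scale inputs make full dynamic
programming affordable, removing any heuristic search dependency. Codon
alignments come from global protein alignment back-translated to codons;
gap columns and every column within 3 codons of one are dropped (a
simplified well-aligned-region filter). Ks is estimated by Nei–Gojobori
(1986) counting: per-codon synonymous site fractions from single-nt
mutation scanning of the universal code (mutations to stops count as
nonsynonymous, so S + N = 3 × codons exactly), differences averaged over
all minimal mutation paths excluding stop-traversing ones, Jukes–Cantor
correction ds = −(3/4)·ln(1 − (4/3)ps), invalid when ps ≥ 0.75. NG86 is a
deliberate substitution for likelihood estimators: values differ
numerically from ML, but the distribution *shape* — what the WGD call
uses — is preserved. The implementation agrees exactly with an independent
NG86 implementation on single-substitution pairs; multi-hit codons follow
the stated path rule.

**Shape call.** Histogram on (0, 3] with 0.05 bins, smoothed (window 3).
The first 4 bins form the L-head: per-pair estimation noise (sd ≈ 0.05 at
200–300 codons) smears the zero-divergence excess across them, so the
"global maximum in the first bin" idea is evaluated over the head region.
A WGD mode is an interior peak beyond the head with prominence ≥ 5% of the
tallest bin *and* ≥ 4× the Poisson counting noise at its height (√count);
without the noise floor, pure exponential samples of 2,000 values are
mis-called as peaked in a large fraction of seeds. Calls: qualifying
interior peak → wgd_peak (mode = tallest such peak); head-region maximum
and no qualifying peak → L_shaped; fewer than 100 valid values or anything
else → inconclusive. Validation: 40/40 exponential samples L-shaped, 20/20
exponential+Gaussian mixtures peaked at 1.0 ± 0.1, 30/30 end-to-end
no-WGD simulations L-shaped, planted-WGD mode recovered within 2.5%.

**Paralog simulator.** Synthetic CDS use only codons whose third position
is fourfold degenerate and whose first two positions admit no synonymous
change (Ala/Gly/Pro/Thr/Val), so S = n_codons exactly; the two copies
diverge at third positions under Jukes–Cantor to the planted distance.
This isolates the estimator from alignment ambiguity, which end-to-end
tests exercise separately via planted insertions.

## Synthetic data (`simgenome`): what it emulates and what it does not

One integer seed drives named sub-streams (genome, reads, counts), so any
stage can be regenerated independently and identical spec+seed gives
byte-identical output. The generator plants, in order: identical-copy TE
families, SSR tracts (flanked by periodicity-breaking bases so planted
runs are maximal, with a 12 bp exclusion pad so distinct planted features
never sit within compound-merging distance of each other), and two-copy
segmental duplications (background segments copied to new loci; both
copies appear in the truth BED). Heterozygous SNPs are Binomial(G, h)
between haplotype copies, excluded from SSR tracts ±2 bp so repeat truth
stays exact on every haplotype; for ploidy > 2 each SNP gets a uniform
dosage in 1..ploidy−1 and a random carrier subset. Reads are single-end
(paired-end layout adds nothing to any computation here), uniform over
haplotypes, strand-randomized, with uniform substitution errors and
constant quality; amplification bias is a simple oversampling multiplier
on duplicated-segment starts, standing in for single-cell amplification
preference whose magnitude the upstream literature does not quantify.
Site base counts are multinomial with allele probabilities =
copy-number/ploidy and Poisson totals.

Real data differ in ways the generator deliberately omits: indels and
structural variants, GC-dependent and positionally biased coverage,
quality-score structure, PCR chimeras, diverged repeat copies, and
population-level variation beyond a uniform-contamination stress test.
Passing tests therefore demonstrate correctness of the *computations*
under the stated statistical model, not robustness to every artifact of
real libraries.

## Default study conditions

Simulation sizes were chosen as the smallest that leave comfortable
statistical margins for each check: cross-k-mer scenarios use 1 Mb
genomes, 50× bulk and 25× haploid coverage (error 0.001), 20 seeds per
scenario; genome-size recovery 500 kb at 40× error-free; the AFS grid
10⁴ sites per cell; SSR oracle equivalence 100 random 10 kb sequences;
Ks checks 300 pairs of 200–300 codons. Scenario parameters (dup 0.3 /
het 0.001 vs het 0.02 / dup 0) mirror the study conditions the package is
built around: a duplication-rich, low-heterozygosity genome versus the
conventional high-heterozygosity reading.

## Known limitations

- The heterozygosity proxy underestimates by ~10% by construction and is
  unreliable when SNP spacing approaches K (h ≳ 1/K).
- The cross-k-mer verdict assumes comparable error-valley behaviour in
  bulk and haploid libraries; heavy single-cell dropout would shift mass
  to depth 0, which is excluded, but extreme nonuniformity is not modeled.
- NG86 saturates near ps = 0.75; pairs beyond Ks ≈ 2 are flagged invalid
  rather than rescued.
- SSR calling is perfect-repeat only; a mismatch-tolerant mode would
  require a different oracle and is intentionally out of scope.
- `coverage_by_region` expects single-contig depth tracks; multi-contig
  inputs are handled by calling it per contig.
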