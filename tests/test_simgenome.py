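import numpy as np
import pandas as pd
import pytest

import gsurvey as g
from gsurvey.dna import decode
from gsurvey.simgenome import SizingError, depth_from_reads


def test_zero_het_haplotypes_identical():
    sim = g.simulate_genome(g.SyntheticGenomeSpec(seed=5, genome_length=20_000,
                                                  het_rate=0.0))
    assert np.array_equal(sim.haplotypes[0], sim.haplotypes[1])
    assert len(sim.snps) == 0


def test_planted_snp_count_binomial():
    spec = g.SyntheticGenomeSpec(seed=1, genome_length=1_000_000, het_rate=0.0026)
    sim = g.simulate_genome(spec)
    mean, sd = 2600, np.sqrt(1_000_000 * 0.0026 * 0.9974)
    assert abs(len(sim.snps) - mean) < 3 * sd
    # haplotypes really differ at exactly the planted positions
    diff = np.flatnonzero(sim.haplotypes[0] != sim.haplotypes[1])
    assert np.array_equal(diff + 1, sim.snps["pos"].to_numpy())


def test_determinism_byte_identical(tmp_path):
    spec = g.SyntheticGenomeSpec(seed=9, genome_length=30_000, het_rate=0.003,
                                 dup_fraction=0.1, dup_segment_length=1000,
                                 ssr_config=(("AC", 8, 5),), compound_rate=0.5)
    for i in (0, 1):
        g.simulate_genome(spec).write_fasta(tmp_path / f"run{i}.fasta")
    assert (tmp_path / "run0.fasta").read_bytes() == \
        (tmp_path / "run1.fasta").read_bytes()


def test_truth_intervals_disjoint_and_in_bounds():
    spec = g.SyntheticGenomeSpec(seed=2, genome_length=100_000, het_rate=0.001,
                                 dup_fraction=0.2, dup_segment_length=2000,
                                 ssr_config=(("AT", 10, 10), ("AAG", 6, 10)),
                                 te_families=((500, 10),), compound_rate=0.3)
    sim = g.simulate_genome(spec)
    for bed in (sim.ssr_loci, sim.te_bed, sim.dup_bed):
        iv = sorted(zip(bed["start"], bed["end"]))
        assert all(0 <= s < e <= 100_000 for s, e in iv)
        assert all(a_end <= b_start for (_, a_end), (b_start, _)
                   in zip(iv, iv[1:]))


def test_oversized_content_raises():
    with pytest.raises(SizingError):
        g.simulate_genome(g.SyntheticGenomeSpec(
            seed=0, genome_length=5_000, ssr_config=(("AC", 100, 50),)))


def test_error_free_reads_are_substrings(small_diploid):
    rs = g.ReadSimSpec(coverage=2, read_length=80, error_rate=0.0, seed=4)
    reads = g.simulate_reads([small_diploid.haplotypes[0]], rs)
    genome = decode(small_diploid.haplotypes[0])
    from gsurvey.dna import revcomp
    for seq in list(reads.sequences())[:200]:
        assert seq in genome or revcomp(seq) in genome


def test_read_count_matches_coverage(small_diploid):
    rs = g.ReadSimSpec(coverage=50, read_length=150, seed=1)
    reads = g.simulate_reads(small_diploid.haplotypes, rs)
    expected = 50 * 50_000 / 150
    assert abs(len(reads) - expected) / expected < 0.01


def test_read_length_longer_than_contig_raises():
    with pytest.raises(ValueError):
        g.simulate_reads([np.zeros(100, dtype=np.uint8)],
                         g.ReadSimSpec(coverage=1, read_length=150, seed=0))


def test_amplification_bias_doubles_dup_depth():
    spec = g.SyntheticGenomeSpec(seed=8, genome_length=200_000, het_rate=0.0,
                                 dup_fraction=0.25, dup_segment_length=5000)
    sim = g.simulate_genome(spec)
    dup_iv = list(zip(sim.dup_bed["start"], sim.dup_bed["end"]))
    rs = g.ReadSimSpec(coverage=40, read_length=100, seed=8,
                       amplification_bias=2.0)
    reads = g.simulate_reads([sim.haplotypes[0]], rs, dup_iv)
    track = depth_from_reads(reads.start, 100, 200_000)
    mask = np.zeros(200_000, dtype=bool)
    for s, e in dup_iv:
        mask[s:e] = True
    ratio = track[mask].mean() / track[~mask].mean()
    assert abs(ratio - 2.0) <= 0.2


def test_extract_haploid_alleles_and_bounds(small_diploid):
    hap0 = g.extract_haploid(small_diploid, 0)
    hap1 = g.extract_haploid(small_diploid, 1)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for _, row in small_diploid.snps.head(50).iterrows():
        carriers = {int(c) for c in row["carriers"].split(",")}
        want0 = row["alt"] if 0 in carriers else row["ref"]
        want1 = row["alt"] if 1 in carriers else row["ref"]
        assert hap0[row["pos"] - 1] == base_index[want0]
        assert hap1[row["pos"] - 1] == base_index[want1]
    with pytest.raises(IndexError):
        g.extract_haploid(small_diploid, 2)


def test_extract_haploid_zero_het_symmetric():
    sim = g.simulate_genome(g.SyntheticGenomeSpec(seed=5, genome_length=20_000,
                                                  het_rate=0.0))
    assert np.array_equal(g.extract_haploid(sim, 0), g.extract_haploid(sim, 1))


def test_extract_haploid_keeps_dup_copies():
    spec = g.SyntheticGenomeSpec(seed=6, genome_length=100_000, het_rate=0.0,
                                 dup_fraction=0.2, dup_segment_length=2000)
    sim = g.simulate_genome(spec)
    hap = g.extract_haploid(sim, 0)
    for pid, grp in sim.dup_bed.groupby("pair_id"):
        src = grp[grp.role == "source"].iloc[0]
        cpy = grp[grp.role == "copy"].iloc[0]
        assert np.array_equal(hap[src.start:src.end], hap[cpy.start:cpy.end])


class TestSiteCounts:
    def test_diploid_alt_fraction_mean(self):
        # fraction of the planted alt allele averages 0.5 over many sites
        # (the rank-1 maximum itself is biased above 0.5 by |p_hat - 0.5|)
        spec = g.SyntheticGenomeSpec(seed=12, genome_length=500_000,
                                     het_rate=0.05)
        sim = g.simulate_genome(spec)
        df = g.simulate_site_counts(sim, depth=60, n_sites=10_000, seed=12)
        sub = sim.snps.set_index("pos").loc[df["pos"]]
        alt = df[["A", "C", "G", "T"]].to_numpy(float)[
            np.arange(len(df)), ["ACGT".index(b) for b in sub["alt"]]]
        frac = alt / df[["A", "C", "G", "T"]].sum(axis=1).to_numpy()
        assert 0.49 <= frac.mean() <= 0.51

    def test_tetraploid_dosage_fractions(self):
        spec = g.SyntheticGenomeSpec(seed=13, genome_length=400_000, ploidy=4,
                                     het_rate=0.05)
        sim = g.simulate_genome(spec)
        df = g.simulate_site_counts(sim, depth=100, n_sites=5_000, seed=13)
        sub = sim.snps.set_index("pos").loc[df["pos"]]
        alt = df[["A", "C", "G", "T"]].to_numpy(float)[
            np.arange(len(df)), ["ACGT".index(b) for b in sub["alt"]]]
        frac = alt / df[["A", "C", "G", "T"]].sum(axis=1).to_numpy()
        for dose, expected in ((1, 0.25), (3, 0.75)):
            sel = (sub["dosage"] == dose).to_numpy()
            assert abs(frac[sel].mean() - expected) < 0.01

    def test_haploid_sites_monomorphic(self):
        sim = g.simulate_genome(g.SyntheticGenomeSpec(seed=14,
                                                      genome_length=50_000,
                                                      ploidy=1))
        df = g.simulate_site_counts(sim, depth=60, n_sites=1_000, seed=14)
        counts = df[["A", "C", "G", "T"]].to_numpy(float)
        assert (np.sort(counts, axis=1)[:, -1] == counts.sum(axis=1)).all()

    def test_depth_must_be_positive(self, small_diploid):
        with pytest.raises(ValueError):
            g.simulate_site_counts(small_diploid, depth=0, n_sites=10, seed=0)
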