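import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gsurvey as g
from gsurvey.dna import decode, revcomp
from gsurvey.ssrscan import (DEFAULT_THRESHOLDS, canonical_motif, coverage_by_region,
                             find_ssrs, merge_compound, primitive_period,
                             ssr_summary)
from conftest import brute_force_ssrs

motifs = st.text(alphabet="ACGT", min_size=1, max_size=6)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("TG", "AC"),  # min over {TG, GT, CA, AC}
        ("A", "A"),
        ("AACCT", "AACCT"),  # telomeric-like pentamer
        ("ATAT", "AT"),  # non-primitive reduced first
    ])
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    @settings(derandomize=True, max_examples=100)
    @given(motifs)
    def test_matches_rotation_enumeration(self, m):
        p = primitive_period(m)
        rc = revcomp(p)
        cands = {(p * 2)[i:i + len(p)] for i in range(len(p))} | \
                {(rc * 2)[i:i + len(p)] for i in range(len(p))}
        assert canonical_motif(m) == min(cands)

    @settings(derandomize=True, max_examples=150)
    @given(motifs)
    def test_rotation_and_revcomp_invariant(self, m):
        assert canonical_motif(m) == canonical_motif(revcomp(m))
        rot = m[1:] + m[0]
        assert canonical_motif(m) == canonical_motif(rot)

    @settings(derandomize=True, max_examples=100)
    @given(motifs)
    def test_idempotent_and_primitive(self, m):
        c = canonical_motif(m)
        assert canonical_motif(c) == c
        assert primitive_period(c) == c


class TestFindSsrs:
    def test_di_repeat_example(self):
        loci = find_ssrs("G" + "AC" * 6 + "G")
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.motif, l.copy_number) == (1, 13, "AC", 6.0)

    def test_below_threshold_not_called(self):
        assert find_ssrs("G" + "AC" * 5 + "G") == []

    def test_repeat_free_input(self):
        assert find_ssrs("ACGTACGGTCAG") == []  # too short for any threshold

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            find_ssrs("ACACACACACAC", thresholds={2: 0})

    def test_oracle_equivalence_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), p=[.35, .15, .15, .35],
                                     size=10_000))
            mine = [(l.start, l.end, l.motif) for l in find_ssrs(seq)]
            assert mine == brute_force_ssrs(seq, DEFAULT_THRESHOLDS)

    def test_planted_loci_recovered_exactly(self, ssr_genome):
        found = find_ssrs(decode(ssr_genome.haplotypes[0]))
        fset = {(l.start, l.end, l.motif) for l in found}
        for row in ssr_genome.ssr_loci.itertuples():
            assert (row.start, row.end, row.motif) in fset

    def test_motif_content_revcomp_invariant(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), p=[.35, .15, .15, .35],
                                 size=20_000))
        def content(s):
            loci = find_ssrs(s)
            out = {}
            for l in loci:
                out[l.canonical] = out.get(l.canonical, 0) + l.length
            return out
        assert content(seq) == content(revcomp(seq))


class TestMergeCompound:
    def _locus(self, start, end, motif, contig="c"):
        from gsurvey.ssrscan import SSRLocus
        return SSRLocus(contig, start, end, motif, canonical_motif(motif),
                        (end - start) / len(motif))

    def test_head_to_tail_merge(self):
        loci = [self._locus(0, 14, "AT"), self._locus(16, 28, "AC")]
        singles, compounds = merge_compound(loci, d_max=10)
        assert singles == [] and len(compounds) == 1
        assert compounds[0].n_members == 2
        assert (compounds[0].start, compounds[0].end) == (0, 28)

    def test_gap_just_beyond_dmax_stays_single(self):
        loci = [self._locus(0, 14, "AT"), self._locus(25, 37, "AC")]
        singles, compounds = merge_compound(loci, d_max=10)
        assert len(singles) == 2 and compounds == []

    def test_single_locus_passthrough(self):
        singles, compounds = merge_compound([self._locus(5, 19, "AT")], 10)
        assert len(singles) == 1 and compounds == []

    def test_unsorted_input_rejected(self):
        loci = [self._locus(20, 34, "AT"), self._locus(0, 12, "AC")]
        with pytest.raises(ValueError):
            merge_compound(loci, 10)

    def test_every_locus_in_exactly_one_group(self, ssr_genome):
        found = find_ssrs(decode(ssr_genome.haplotypes[0]))
        singles, compounds = merge_compound(found, 10)
        regrouped = sorted([(l.start, l.end) for l in singles] +
                           [(m.start, m.end) for c in compounds
                            for m in c.members])
        assert regrouped == sorted((l.start, l.end) for l in found)


class TestSummary:
    def test_toy_arithmetic(self):
        loci = [TestMergeCompound()._locus(*iv, "AC")
                for iv in ((0, 20), (100, 120), (200, 220))]
        s = ssr_summary(loci, [], genome_length=10_000)
        assert s.genome_content_fraction == pytest.approx(0.006)
        assert s.density_per_mb == pytest.approx(300.0)
        assert s.mean_locus_length == pytest.approx(20.0)
        assert s.compound_fraction == 0.0

    def test_all_loci_in_compounds(self):
        mk = TestMergeCompound()._locus
        loci = [mk(0, 14, "AT"), mk(16, 28, "AC")]
        _, compounds = merge_compound(loci, 10)
        s = ssr_summary(loci, compounds, 1_000)
        assert s.compound_fraction == 1.0

    def test_zero_loci_flagged(self):
        s = ssr_summary([], [], 1_000)
        assert s.flagged_empty and s.n_loci == 0

    def test_compound_spans_longer_than_singles(self, ssr_genome):
        found = find_ssrs(decode(ssr_genome.haplotypes[0]))
        singles, compounds = merge_compound(found, 10)
        mean_single = np.mean([l.length for l in singles])
        mean_comp = np.mean([c.span for c in compounds])
        assert mean_comp > mean_single


class TestCoverage:
    def test_flat_track(self):
        track = np.full(1000, 50.0)
        out = coverage_by_region(track, [(10, 50)], [(100, 200)])
        assert out == {"SSR": 50.0, "TE": 50.0, "other": 50.0}

    def test_constructed_deficit(self):
        track = np.full(1000, 100.0)
        ssr = [(0, 100), (500, 600)]
        for s, e in ssr:
            track[s:e] = 10.0
        out = coverage_by_region(track, ssr, [(200, 300)])
        assert out == {"SSR": 10.0, "TE": 100.0, "other": 100.0}

    def test_ssr_precedence_and_empty_class(self):
        track = np.arange(100, dtype=float)
        out = coverage_by_region(track, [(0, 100)], [(20, 40)])
        assert out["SSR"] == pytest.approx(track.mean())
        assert out["TE"] is None and out["other"] is None

    def test_unmappable_ssr_reads_depress_coverage(self, ssr_genome):
        # reads falling wholly inside an SSR tract are unplaceable: drop
        # them and the SSR class mean falls below the rest of the genome
        from gsurvey.simgenome import depth_from_reads
        sim = ssr_genome
        reads = g.simulate_reads([sim.haplotypes[0]],
                                 g.ReadSimSpec(30, 50, 0.0, 17))
        inside = np.zeros(200_000 + 1, dtype=bool)
        for row in sim.ssr_loci.itertuples():
            inside[row.start:row.end] = True
        starts = reads.start
        keep = ~(inside[starts] & inside[np.minimum(starts + 50, 200_000)])
        track = depth_from_reads(starts[keep], 50, 200_000)
        ssr_iv = list(zip(sim.ssr_loci["start"], sim.ssr_loci["end"]))
        te_iv = list(zip(sim.te_bed["start"], sim.te_bed["end"]))
        out = coverage_by_region(track, ssr_iv, te_iv)
        assert out["SSR"] < out["other"]
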