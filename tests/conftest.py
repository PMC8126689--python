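import numpy as np
import pytest

import gsurvey as g


@pytest.fixture(scope="session")
def small_diploid():
    """50 kb diploid with moderate heterozygosity, reused across tests."""
    spec = g.SyntheticGenomeSpec(seed=42, genome_length=50_000, het_rate=0.005)
    return g.simulate_genome(spec)


@pytest.fixture(scope="session")
def ssr_genome():
    """200 kb genome with planted single and compound SSR tracts."""
    spec = g.SyntheticGenomeSpec(
        seed=3, genome_length=200_000, het_rate=0.002,
        ssr_config=(("AC", 10, 40), ("AT", 12, 40), ("AAG", 8, 30),
                    ("AGAT", 6, 20), ("A", 15, 20)),
        compound_rate=0.6)
    return g.simulate_genome(spec)


def brute_force_ssrs(seq, thresholds):
    """Independent quadratic SSR oracle: maximal perfect runs per period,
    primitive motifs, same documented overlap-resolution rule."""
    from gsurvey.ssrscan import primitive_period
    n = len(seq)
    cands = []
    for m, minc in thresholds.items():
        i = 0
        while i + m < n:
            if seq[i] == seq[i + m]:
                j = i
                while j + m < n and seq[j] == seq[j + m]:
                    j += 1
                start, end = i, j + m
                motif = seq[start:start + m]
                if (end - start) // m >= minc and len(primitive_period(motif)) == m:
                    cands.append((start, end, motif))
                i = j + 1
            else:
                i += 1
    cands.sort(key=lambda t: (-(t[1] - t[0]), len(t[2]), t[0]))
    occupied = [False] * n
    out = []
    for s, e, motif in cands:
        if not any(occupied[s:e]):
            out.append((s, e, motif))
            occupied[s:e] = [True] * (e - s)
    out.sort()
    return out
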