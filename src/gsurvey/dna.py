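"""Low-level DNA utilities shared across the package.

Sequences are held internally as ``uint8`` numpy arrays with the 2-bit
encoding A=0, C=1, G=2, T=3.  The sentinel value 4 marks any non-ACGT
character (N, separators); k-mer windows touching a sentinel are skipped.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
SENTINEL = 4

_ENC = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT(N) string into a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGTN string."""
    return _DEC[np.minimum(codes, SENTINEL)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (sentinels stay sentinels)."""
    out = codes[::-1].copy()
    valid = out < SENTINEL
    out[valid] = 3 - out[valid]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def random_codes(rng: np.random.Generator, n: int,
                 composition=(0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    """Draw a random sequence of length ``n`` with the given base probabilities."""
    p = np.asarray(composition, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base composition must be four probabilities summing to 1")
    return rng.choice(4, size=n, p=p).astype(np.uint8)
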