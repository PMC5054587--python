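"""Nucleotide sequence helpers shared across the pipeline.

Sequences are plain Python strings over {A,C,G,T,N}; numerical code paths
encode them as uint8 arrays where A,C,G,T map to 0..3 and N to 255 so that
an N never compares equal to any tag base.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.full(arr.shape, ord("N"), dtype=np.uint8)
    ok = arr < 4
    out[ok] = lut[arr[ok]]
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMP)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T so RNA-style input joins the DNA alphabet."""
    return seq.upper().replace("U", "T")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int((encode(a) != encode(b)).sum())
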