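"""Base encoding shared across the package.

Bases are held as small integer codes in numpy arrays: A=0, C=1, G=2, T=3,
N=4.  Everything downstream (consensus, pileups, the simulator) works on
codes; strings appear only at format boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a base string into uint8 codes (unknown characters -> N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into a base string."""
    return "".join(BASES[c] for c in np.asarray(codes, dtype=np.uint8))


def is_acgt(seq: str) -> bool:
    """True when every character of ``seq`` is an unambiguous A/C/G/T."""
    return len(seq) > 0 and all(ch in "ACGT" for ch in seq)
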