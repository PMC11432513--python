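"""Nucleotide encoding helpers.

Sequences are held as uint8 arrays with A=0, C=1, G=2, T=3 and 255 for
anything that is not an unambiguous base (gaps, N, IUPAC ambiguity codes).
With this encoding the transition partner of a base ``b`` is ``b ^ 2``
(A<->G, C<->T), and purines are exactly the even codes.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
MISSING = 255

_ENCODE_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(NUCLEOTIDES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
# RNA input is tolerated: U reads as T.
_ENCODE_LUT[ord("U")] = 3
_ENCODE_LUT[ord("u")] = 3

_DECODE_LUT = np.full(256, ord("N"), dtype=np.uint8)
for _i, _b in enumerate(NUCLEOTIDES):
    _DECODE_LUT[_i] = ord(_b)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to the internal uint8 representation."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 array back to a string; non-bases render as N."""
    return _DECODE_LUT[arr].tobytes().decode("ascii")


def encode_matrix(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n_samples, n_columns) matrix."""
    return np.vstack([encode(s) for s in sequences])


def is_unambiguous(arr: np.ndarray) -> np.ndarray:
    return arr < 4
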