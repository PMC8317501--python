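"""Encoding and distance helpers for aligned nucleotide sequences.

Sequences are positionally homologous strings over ``A C G T -`` plus ``N``
for missing data.  The gap ``-`` is a fifth character state everywhere
(entropy, splitting, Hamming distances, network medians); ``N`` is missing.
"""

from __future__ import annotations

import numpy as np

#: residue states that carry information, in canonical order
RESIDUES = "ACGT-"
MISSING = "N"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(RESIDUES):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("N")] = 5
_CODE[ord("n")] = 5

N_CODE = 5


def encode(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into a (n, L) uint8 code matrix.

    Codes 0..4 map to ``A C G T -``; 5 is ``N``.  Unknown characters raise.
    """
    if not seqs:
        raise ValueError("no sequences to encode")
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _CODE[arr].reshape(len(seqs), L)
    if (mat == 255).any():
        bad = sorted({chr(c) for c in arr[_CODE[arr] == 255]})
        raise ValueError(f"unexpected characters in sequences: {bad}")
    return mat


def decode(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode`."""
    lut = np.frombuffer((RESIDUES + MISSING).encode("ascii"), dtype=np.uint8)
    return ["".join(map(chr, lut[row])) for row in np.asarray(mat, dtype=np.uint8)]


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise Hamming distances between equal-length sequences.

    Every distinct character state counts as a difference (gap included);
    positions where either sequence is ``N`` are skipped.
    """
    mat = encode(seqs)
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    valid = mat != N_CODE
    for i in range(n):
        diff = (mat[i] != mat) & valid[i] & valid
        d[i] = diff.sum(axis=1)
    return d


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences (N skipped)."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return int(hamming_matrix([a, b])[0, 1])
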