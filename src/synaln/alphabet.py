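"""Amino-acid alphabet, background frequencies and BLOSUM62 helpers.

The canonical column order used throughout the package (profiles, PSSMs,
substitution matrices) is the PSI-BLAST order ``ARNDCQEGHILKMFPSTWYV``.
``X`` is accepted in sequences as the unknown residue; it never scores.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: k for k, aa in enumerate(AA_ORDER)}
VALID_RESIDUES = frozenset(AA_ORDER) | {"X"}
GAP_CHARS = frozenset("-.")

# BLOSUM62 marginal (background) amino-acid frequencies, AA_ORDER order.
BACKGROUND_FREQS = np.array(
    [
        0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
        0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


@functools.cache
def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 float array in ``AA_ORDER`` order
    (NCBI half-bit integer scores)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = mat[a, b]
    return out


@functools.cache
def blosum62_exchange_probs() -> np.ndarray:
    """Conditional substitution probabilities ``C[a, b] = P(b | a, b != a)``.

    Derived from the BLOSUM62 half-bit log-odds ``s(a,b) = 2 log2 q_ab/(p_a p_b)``:
    the off-diagonal target frequency is proportional to ``p_b * 2**(s/2)``,
    normalised per source residue with a zero diagonal.
    """
    s = blosum62()
    q = BACKGROUND_FREQS[None, :] * np.exp2(s / 2.0)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


def encode(residues: str) -> np.ndarray:
    """Map residues to AA_ORDER indices; ``X`` (or anything unknown) -> -1."""
    return np.array([AA_INDEX.get(ch, -1) for ch in residues], dtype=np.int64)
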