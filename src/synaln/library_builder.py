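"""Rank normalization of raw pair scores and T-Coffee library packaging.

Raw synonym (or profile) scores have heavy tails; to keep a few residue pairs
from dominating the alignment they are rank-normalized: all alignable pairs
(nonzero raw score) are sorted by score and split into N equal groups, the top
group scoring N, the next N-1, down to 1.  N defaults to 500, capped at the
number of alignable pairs.
"""

from __future__ import annotations

from typing import Iterable

from .core_io import Sequence, TCLibrary
from .errors import ConsistencyError, ParameterError
from .synonym_engine import PairScoreMatrix

DEFAULT_N_MAX = 500


def normalize_scores(raw: PairScoreMatrix, n_max: int = DEFAULT_N_MAX) -> PairScoreMatrix:
    """Rank-then-bucket normalization.

    Alignable pairs are cells with raw score > 0.  ``N = min(n_max,
    #alignable)``; pairs sorted by raw score descending (ties broken by (i, j)
    ascending) are partitioned into N contiguous groups of equal size, the
    remainder going one extra to the highest-scoring groups; group g (1-based
    from the top) scores ``N - g + 1``.
    """
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    alignable = [(v, i, j) for (i, j), v in raw.cells.items() if v > 0]
    n_cells = len(alignable)
    n_groups = min(n_max, n_cells)
    out: dict[tuple[int, int], float] = {}
    if n_groups:
        alignable.sort(key=lambda t: (-t[0], t[1], t[2]))
        base, extra = divmod(n_cells, n_groups)
        pos = 0
        for g in range(1, n_groups + 1):
            size = base + (1 if g <= extra else 0)
            for (_, i, j) in alignable[pos : pos + size]:
                out[(i, j)] = float(n_groups - g + 1)
            pos += size
    return PairScoreMatrix(
        seq_a_id=raw.seq_a_id,
        seq_b_id=raw.seq_b_id,
        shape=raw.shape,
        cells=out,
        kind="normalized",
        n_groups=n_groups,
    )


def build_library(
    pairs: Iterable[tuple[Sequence, Sequence, PairScoreMatrix]]
) -> TCLibrary:
    """Package normalized matrices as a T-Coffee library: one entry per cell
    with weight = normalized score, residue indices converted to 1-based."""
    sequences: list[Sequence] = []
    seen: dict[str, Sequence] = {}
    entries: list[tuple[str, str, int, int, int]] = []
    for (seq_a, seq_b, mat) in pairs:
        if mat.kind not in ("normalized", "extended"):
            raise ParameterError(
                f"matrix for ({seq_a.id}, {seq_b.id}) has kind {mat.kind!r}; "
                "normalize before building a library"
            )
        if (mat.seq_a_id, mat.seq_b_id) != (seq_a.id, seq_b.id):
            raise ConsistencyError("matrix ids do not match the given sequences")
        for s in (seq_a, seq_b):
            if s.id in seen:
                if seen[s.id].residues != s.residues:
                    raise ConsistencyError(
                        f"conflicting sequences under id {s.id!r}"
                    )
            else:
                seen[s.id] = s
                sequences.append(s)
        for (i, j) in sorted(mat.cells):
            w = int(round(mat.cells[(i, j)]))
            if w >= 1:
                entries.append((seq_a.id, seq_b.id, i + 1, j + 1, w))
    return TCLibrary(sequences=sequences, entries=entries)
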