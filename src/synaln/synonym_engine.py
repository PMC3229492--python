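"""Synonymous protein words and the residue-pair similarity they induce.

A *synonym* of the length-``l`` word starting at position ``i`` of a target
sequence is the homolog fragment aligned gaplessly against that window in a
high-identity homolog alignment.  Two target words (one per sequence) sharing
a synonym string are synonymous by transitivity, and each shared synonym
``sw`` contributes ``sim = (F_S(sw) + F_T(sw)) / 2`` — the mean of its
occurrence frequencies in the two homolog sets — to every residue pair along
the word diagonal.  The final raw score of a residue pair is the sum of these
contributions over all shared synonyms covering it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .core_io import Sequence
from .errors import ParameterError
from .homologs import HomologSet

DEFAULT_WORD_LENGTH = 7


@dataclass
class SynonymTable:
    """Per-position synonym frequencies for one target sequence.

    ``entries[i][sw] = F`` — the number of appearances of synonym string
    ``sw`` (length ``word_length``) for the target word starting at 0-based
    position ``i``.
    """

    target_id: str
    target_length: int
    word_length: int
    entries: dict[int, dict[str, int]] = field(default_factory=dict)

    def n_synonyms(self) -> int:
        return sum(len(d) for d in self.entries.values())

    def to_tsv(self, path: str | Path, target: Optional[Sequence] = None) -> None:
        """Dump as TSV (target_id, position, word, synonym, F) for inspection."""
        with open(path, "w") as fh:
            fh.write("target_id\tposition\tword\tsynonym\tF\n")
            for i in sorted(self.entries):
                word = (
                    target.residues[i : i + self.word_length] if target is not None else "."
                )
                for sw in sorted(self.entries[i]):
                    fh.write(
                        f"{self.target_id}\t{i}\t{word}\t{sw}\t{self.entries[i][sw]}\n"
                    )


@dataclass
class PairScoreMatrix:
    """Sparse residue-pair scores for one sequence pair.

    ``kind`` is ``raw`` (accumulated similarity, exact rationals kept as
    floats of half-integers), ``counts`` (shared-synonym counts),
    ``normalized`` (rank groups, 1..N) or ``extended`` (after the consistency
    transform).  Absent cells score 0.
    """

    seq_a_id: str
    seq_b_id: str
    shape: tuple[int, int]
    cells: dict[tuple[int, int], float] = field(default_factory=dict)
    kind: str = "raw"
    n_groups: int = 0  # N used by normalization (normalized/extended kinds)

    def __post_init__(self) -> None:
        m, n = self.shape
        for (i, j) in self.cells:
            if not (0 <= i < m and 0 <= j < n):
                raise ParameterError(f"cell ({i}, {j}) outside matrix shape {self.shape}")

    def score(self, i: int, j: int) -> float:
        return self.cells.get((i, j), 0.0)

    def transpose(self) -> "PairScoreMatrix":
        return PairScoreMatrix(
            seq_a_id=self.seq_b_id,
            seq_b_id=self.seq_a_id,
            shape=(self.shape[1], self.shape[0]),
            cells={(j, i): v for (i, j), v in self.cells.items()},
            kind=self.kind,
            n_groups=self.n_groups,
        )

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for (i, j), v in self.cells.items():
            out[i, j] = v
        return out

    @classmethod
    def from_dense(
        cls,
        seq_a_id: str,
        seq_b_id: str,
        dense: np.ndarray,
        kind: str = "raw",
        keep_zeros: bool = False,
    ) -> "PairScoreMatrix":
        cells = {}
        for i in range(dense.shape[0]):
            for j in range(dense.shape[1]):
                v = float(dense[i, j])
                if keep_zeros or v != 0.0:
                    cells[(i, j)] = v
        return cls(seq_a_id, seq_b_id, tuple(dense.shape), cells, kind=kind)


def extract_synonyms(
    hs: HomologSet,
    word_length: int = DEFAULT_WORD_LENGTH,
    self_seed: bool = True,
) -> SynonymTable:
    """Slide a length-``l`` window over every homolog alignment and record the
    gaplessly aligned homolog words as synonyms of the target word.

    A window counts only when all ``l`` columns align residue to residue with
    no gap in either row (so the homolog positions are consecutive).  ``F``
    accumulates one per aligned occurrence.  With ``self_seed`` every target
    word is additionally its own synonym with F = 1, so identical targets
    share synonyms even without homologs.
    """
    target = hs.target
    l = word_length
    if l < 2:
        raise ParameterError("word_length must be >= 2")
    if l > len(target):
        raise ParameterError(
            f"word_length {l} exceeds target {target.id!r} length {len(target)}"
        )
    entries: dict[int, dict[str, int]] = {}

    def add(i: int, sw: str) -> None:
        entries.setdefault(i, {})
        entries[i][sw] = entries[i].get(sw, 0) + 1

    if self_seed:
        for i in range(len(target) - l + 1):
            add(i, target.residues[i : i + l])

    for member in hs.members:
        aln = member.alignment
        # Runs of consecutive residue-residue columns; a gap in either row
        # breaks the run, so no synonym window ever spans a gap.
        run_t: list[int] = []
        run_h: list[str] = []
        ti, hi = aln.a_start, aln.b_start
        hom = aln.ungapped_b

        def flush() -> None:
            for off in range(len(run_t) - l + 1):
                add(run_t[off], "".join(run_h[off : off + l]))
            run_t.clear()
            run_h.clear()

        for ca, cb in zip(aln.row_a, aln.row_b):
            ga, gb = ca in "-.", cb in "-."
            if not ga and not gb:
                run_t.append(ti)
                run_h.append(cb)
            else:
                flush()
            if not ga:
                ti += 1
            if not gb:
                hi += 1
        flush()
    return SynonymTable(
        target_id=target.id,
        target_length=len(target),
        word_length=l,
        entries=entries,
    )


def _accumulate_shared(
    ts: SynonymTable,
    tt: SynonymTable,
    contribution: Callable[[int, int], Fraction],
) -> dict[tuple[int, int], Fraction]:
    if ts.word_length != tt.word_length:
        raise ParameterError(
            f"word_length mismatch: {ts.word_length} != {tt.word_length}"
        )
    l = ts.word_length
    # Invert tt: synonym string -> positions where it occurs (with F).
    index: dict[str, list[tuple[int, int]]] = {}
    for q, syns in tt.entries.items():
        for sw, f in syns.items():
            index.setdefault(sw, []).append((q, f))
    cells: dict[tuple[int, int], Fraction] = {}
    for p, syns in ts.entries.items():
        for sw, fs in syns.items():
            for (q, ft) in index.get(sw, ()):
                c = contribution(fs, ft)
                for k in range(l):
                    key = (p + k, q + k)
                    cells[key] = cells.get(key, Fraction(0)) + c
    return cells


def raw_pair_scores(ts: SynonymTable, tt: SynonymTable) -> PairScoreMatrix:
    """Raw residue-pair similarity: sum of ``(F_S + F_T) / 2`` over all shared
    synonyms whose word diagonal covers the pair.  Exact (half-integer)
    accumulation; no rounding before normalization."""
    cells = _accumulate_shared(ts, tt, lambda fs, ft: Fraction(fs + ft, 2))
    return PairScoreMatrix(
        seq_a_id=ts.target_id,
        seq_b_id=tt.target_id,
        shape=(ts.target_length, tt.target_length),
        cells={k: float(v) for k, v in cells.items()},
        kind="raw",
    )


def shared_synonym_counts(ts: SynonymTable, tt: SynonymTable) -> PairScoreMatrix:
    """Like :func:`raw_pair_scores` but each shared synonym contributes 1
    (the quantity shown by the dot-matrix view)."""
    cells = _accumulate_shared(ts, tt, lambda fs, ft: Fraction(1))
    return PairScoreMatrix(
        seq_a_id=ts.target_id,
        seq_b_id=tt.target_id,
        shape=(ts.target_length, tt.target_length),
        cells={k: float(v) for k, v in cells.items()},
        kind="counts",
    )
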