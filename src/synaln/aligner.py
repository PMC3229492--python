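"""Alignment engines over residue-pair score matrices.

* :func:`pairwise_align` — global Needleman-Wunsch over an arbitrary
  position-specific score matrix with affine gaps (a gap of length k costs
  ``gap_open + gap_extend * k``) and deterministic traceback (diagonal, then
  up, then left).
* :func:`consistency_transform` — T-Coffee-style triplet extension: each
  residue-pair score is augmented by the minimum-support route through every
  third sequence.
* :func:`progressive_msa` — UPGMA guide tree plus profile-profile merges
  scored by the extended library (or by a substitution matrix for the
  baseline), an internal stand-in for running genuine T-Coffee on an
  exported library.

Library-based DP uses zero gap costs by default: normalized consistency
scores already encode positional support, so unsupported regions are free to
gap (standard T-Coffee practice).  The substitution-matrix baseline defaults
to BLOSUM62 with gap open 11, extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence as TSeq

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .alphabet import blosum62, encode
from .core_io import MultipleAlignment, PairwiseAlignment, Sequence, TCLibrary
from .errors import ConsistencyError, LookupFailure, ParameterError
from .synonym_engine import PairScoreMatrix

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Global pairwise DP


def _affine_nw(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, list[tuple[int, int]]]:
    """Needleman-Wunsch with affine gaps on a dense (m, n) score matrix.

    Returns (optimal score, aligned index pairs).  Traceback prefers the
    diagonal, then up (gap in the second sequence), then left; within a gap
    run, closing the gap is preferred.  A gap of length k costs
    ``gap_open + gap_extend * k`` (0 if both costs are 0).
    """
    m, n = S.shape
    oe = gap_open + gap_extend
    H = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)  # vertical: consumes rows of S ("up")
    Iy = np.full((m + 1, n + 1), NEG_INF)  # horizontal ("left")
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        Iy[0, j] = -(gap_open + gap_extend * j)
        H[0, j] = Iy[0, j]
    for i in range(1, m + 1):
        Ix[i, 0] = -(gap_open + gap_extend * i)
        H[i, 0] = Ix[i, 0]
        Ix[i, 1:] = np.maximum(H[i - 1, 1:] - oe, Ix[i - 1, 1:] - gap_extend)
        diag = H[i - 1, :-1] + S[i - 1, :]
        other = np.maximum(diag, Ix[i, 1:])
        # Iy is a left-to-right scan within the row.
        Hrow = H[i]
        Iyrow = Iy[i]
        prev_h = Hrow[0]
        prev_iy = NEG_INF
        for j in range(1, n + 1):
            iy = max(prev_h - oe, prev_iy - gap_extend)
            h = other[j - 1]
            if iy > h:
                h = iy
            Iyrow[j] = iy
            Hrow[j] = h
            prev_h = h
            prev_iy = iy
    # Traceback over explicit states.
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    state = "H"
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= tol:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif i > 0 and abs(H[i, j] - Ix[i, j]) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            if abs(Ix[i, j] - (H[i - 1, j] - oe)) <= tol:
                state = "H"
            i -= 1
        else:  # Iy
            if abs(Iy[i, j] - (H[i, j - 1] - oe)) <= tol:
                state = "H"
            j -= 1
    pairs.reverse()
    return float(H[m, n]), pairs


def pairwise_align(
    scores: PairScoreMatrix,
    seq_a: Sequence,
    seq_b: Sequence,
    gap_open: float = 0.0,
    gap_extend: float = 0.0,
) -> PairwiseAlignment:
    """Global alignment maximizing the sum of matrix cells over aligned pairs
    minus affine gap costs."""
    _, pairs = align_score_and_pairs(scores, seq_a, seq_b, gap_open, gap_extend)
    return PairwiseAlignment.from_pairs(seq_a, seq_b, pairs)


def align_score_and_pairs(
    scores: PairScoreMatrix,
    seq_a: Sequence,
    seq_b: Sequence,
    gap_open: float = 0.0,
    gap_extend: float = 0.0,
) -> tuple[float, list[tuple[int, int]]]:
    if scores.shape != (len(seq_a), len(seq_b)):
        raise ConsistencyError(
            f"score matrix shape {scores.shape} does not match sequence "
            f"lengths ({len(seq_a)}, {len(seq_b)})"
        )
    return _affine_nw(scores.to_dense(), gap_open, gap_extend)


def substitution_scores(
    seq_a: Sequence, seq_b: Sequence, matrix: Optional[np.ndarray] = None
) -> PairScoreMatrix:
    """Dense substitution-matrix scores (BLOSUM62 default); ``X`` scores 0."""
    M = blosum62() if matrix is None else np.asarray(matrix, dtype=float)
    ea, eb = encode(seq_a.residues), encode(seq_b.residues)
    Mpad = np.zeros((21, 21))
    Mpad[:20, :20] = M
    dense = Mpad[np.ix_(ea, eb)]  # index -1 hits the zero pad row/col
    return PairScoreMatrix.from_dense(seq_a.id, seq_b.id, dense, kind="raw")


def blosum62_align(
    seq_a: Sequence,
    seq_b: Sequence,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """The classic substitution-matrix baseline aligner."""
    return pairwise_align(
        substitution_scores(seq_a, seq_b), seq_a, seq_b, gap_open, gap_extend
    )


# ---------------------------------------------------------------------------
# Consistency transform


def _oriented_dense(
    libs: Mapping[tuple[str, str], PairScoreMatrix], x: str, y: str
) -> np.ndarray:
    if (x, y) in libs:
        return libs[(x, y)].to_dense()
    if (y, x) in libs:
        return libs[(y, x)].to_dense().T
    raise LookupFailure(f"no library matrix for pair ({x!r}, {y!r})")


def consistency_transform(
    libs: Mapping[tuple[str, str], PairScoreMatrix]
) -> dict[tuple[str, str], PairScoreMatrix]:
    """Triplet extension: ``ext(x_i, y_j) = lib(x_i, y_j) +
    sum_z sum_k min(lib(x_i, z_k), lib(z_k, y_j))`` over all third sequences
    ``z``.  Never decreases any cell.  With two sequences it is the identity.
    """
    ids: list[str] = []
    for (a, b) in libs:
        for s in (a, b):
            if s not in ids:
                ids.append(s)
    dense = {key: _oriented_dense(libs, *key) for key in libs}
    out: dict[tuple[str, str], PairScoreMatrix] = {}
    for (x, y), mat in libs.items():
        ext = dense[(x, y)].copy()
        for z in ids:
            if z == x or z == y:
                continue
            Dxz = _oriented_dense(libs, x, z)
            Dzy = _oriented_dense(libs, z, y)
            cols = np.nonzero(Dxz.any(axis=0) & Dzy.any(axis=1))[0]
            for k in cols:
                ext += np.minimum.outer(Dxz[:, k], Dzy[k, :])
        out[(x, y)] = PairScoreMatrix.from_dense(
            x, y, ext, kind="extended"
        )
        out[(x, y)].n_groups = mat.n_groups
    return out


# ---------------------------------------------------------------------------
# Progressive MSA


@dataclass
class _Profile:
    """A partial alignment during progressive merging."""

    seq_ids: list[str]
    rows: list[str]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def col_index(self, row: int) -> np.ndarray:
        """Per-column residue index for one member row; -1 at gaps."""
        out = np.empty(self.length, dtype=np.int64)
        k = 0
        for c, ch in enumerate(self.rows[row]):
            if ch == "-":
                out[c] = -1
            else:
                out[c] = k
                k += 1
        return out


def _pad(dense: np.ndarray) -> np.ndarray:
    """Append a zero row and column so index -1 scores 0."""
    out = np.zeros((dense.shape[0] + 1, dense.shape[1] + 1))
    out[:-1, :-1] = dense
    return out


def _merge(
    A: _Profile,
    B: _Profile,
    pair_dense: Mapping[tuple[str, str], np.ndarray],
    gap_open: float,
    gap_extend: float,
) -> _Profile:
    """Profile-profile alignment scoring a column pair by the mean pair score
    over member residue pairs (gapped members contribute 0)."""
    S = np.zeros((A.length, B.length))
    for ra, x in enumerate(A.seq_ids):
        ia = A.col_index(ra)
        for rb, y in enumerate(B.seq_ids):
            jb = B.col_index(rb)
            S += _pad(pair_dense[(x, y)])[np.ix_(ia, jb)]
    S /= len(A.seq_ids) * len(B.seq_ids)
    _, col_pairs = _affine_nw(S, gap_open, gap_extend)
    rows_a: list[list[str]] = [[] for _ in A.rows]
    rows_b: list[list[str]] = [[] for _ in B.rows]
    u = v = 0
    for (cu, cv) in col_pairs + [(A.length, B.length)]:
        while u < cu:
            for r, row in zip(rows_a, A.rows):
                r.append(row[u])
            for r in rows_b:
                r.append("-")
            u += 1
        while v < cv:
            for r in rows_a:
                r.append("-")
            for r, row in zip(rows_b, B.rows):
                r.append(row[v])
            v += 1
        if cu < A.length and cv < B.length:
            for r, row in zip(rows_a, A.rows):
                r.append(row[u])
            for r, row in zip(rows_b, B.rows):
                r.append(row[v])
            u += 1
            v += 1
    return _Profile(
        seq_ids=A.seq_ids + B.seq_ids,
        rows=["".join(r) for r in rows_a + rows_b],
    )


def _progressive(
    seqs: TSeq[Sequence],
    pair_dense: Mapping[tuple[str, str], np.ndarray],
    distances: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> MultipleAlignment:
    n = len(seqs)
    profiles: dict[int, _Profile] = {
        k: _Profile([s.id], [s.residues]) for k, s in enumerate(seqs)
    }
    if n == 2:
        merged = _merge(profiles[0], profiles[1], pair_dense, gap_open, gap_extend)
    else:
        Z = linkage(squareform(distances, checks=False), method="average")
        next_id = n
        for (a, b, _, _) in Z:
            pa, pb = profiles.pop(int(a)), profiles.pop(int(b))
            profiles[next_id] = _merge(pa, pb, pair_dense, gap_open, gap_extend)
            next_id += 1
        merged = profiles[next_id - 1]
    by_id = dict(zip(merged.seq_ids, merged.rows))
    return MultipleAlignment(rows={s.id: by_id[s.id] for s in seqs})


def _all_pair_dense(
    seqs: TSeq[Sequence], libs: Mapping[tuple[str, str], PairScoreMatrix]
) -> dict[tuple[str, str], np.ndarray]:
    dense = {}
    for a in range(len(seqs)):
        for b in range(len(seqs)):
            if a == b:
                continue
            x, y = seqs[a].id, seqs[b].id
            dense[(x, y)] = _oriented_dense(libs, x, y)
    return dense


def progressive_msa(
    seqs: TSeq[Sequence],
    extended_libs: Mapping[tuple[str, str], PairScoreMatrix],
    gap_open: float = 0.0,
    gap_extend: float = 0.0,
) -> MultipleAlignment:
    """Progressive alignment over consistency-extended libraries.

    The UPGMA guide tree uses distance ``1 - score / (min(m, n) * N)`` where
    ``score`` is the pairwise library DP score and N the pair's normalization
    group count; merges score column pairs by the mean extended-library score
    over member residue pairs (gaps 0).  Deterministic.
    """
    if len(seqs) < 2:
        raise ParameterError("progressive_msa needs at least 2 sequences")
    pair_dense = _all_pair_dense(seqs, extended_libs)
    n = len(seqs)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            x, y = seqs[a], seqs[b]
            dxy = pair_dense[(x.id, y.id)]
            score, _ = _affine_nw(dxy, gap_open, gap_extend)
            key = (x.id, y.id) if (x.id, y.id) in extended_libs else (y.id, x.id)
            n_groups = max(extended_libs[key].n_groups, 1)
            d = 1.0 - score / (min(len(x), len(y)) * n_groups)
            D[a, b] = D[b, a] = min(max(d, 0.0), 1.0)
    return _progressive(seqs, pair_dense, D, gap_open, gap_extend)


def progressive_msa_matrix(
    seqs: TSeq[Sequence],
    matrix: Optional[np.ndarray] = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MultipleAlignment:
    """Substitution-matrix progressive baseline (BLOSUM62 / affine gaps):
    guide tree from pairwise alignment identities, merges scored by the mean
    substitution score over member residue pairs."""
    if len(seqs) < 2:
        raise ParameterError("progressive_msa_matrix needs at least 2 sequences")
    from .evaluation import seq_identity

    pair_dense: dict[tuple[str, str], np.ndarray] = {}
    n = len(seqs)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            mat = substitution_scores(seqs[a], seqs[b], matrix)
            pair_dense[(seqs[a].id, seqs[b].id)] = mat.to_dense()
    for a in range(n):
        for b in range(a + 1, n):
            aln = pairwise_align(
                PairScoreMatrix.from_dense(
                    seqs[a].id, seqs[b].id, pair_dense[(seqs[a].id, seqs[b].id)]
                ),
                seqs[a],
                seqs[b],
                gap_open,
                gap_extend,
            )
            d = 1.0 - seq_identity(aln) / 100.0
            D[a, b] = D[b, a] = min(max(d, 0.0), 1.0)
    return _progressive(seqs, pair_dense, D, gap_open, gap_extend)


def library_to_matrices(lib: TCLibrary) -> dict[tuple[str, str], PairScoreMatrix]:
    """Convert a T-Coffee library (e.g. read from disk) into per-pair score
    matrices so the internal engines can align genuine T-Coffee output."""
    by_id = {s.id: s for s in lib.sequences}
    cells: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for (ida, idb, ra, rb, w) in lib.entries:
        cells.setdefault((ida, idb), {})[(ra - 1, rb - 1)] = float(w)
    out = {}
    for (ida, idb), cc in cells.items():
        mat = PairScoreMatrix(
            seq_a_id=ida,
            seq_b_id=idb,
            shape=(len(by_id[ida]), len(by_id[idb])),
            cells=cc,
            kind="normalized",
        )
        mat.n_groups = int(max(cc.values())) if cc else 0
        out[(ida, idb)] = mat
    return out
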