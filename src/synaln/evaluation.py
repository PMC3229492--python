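"""Alignment quality metrics and study protocols.

Reference-dependent: Q-score (fraction of reference residue pairs
reproduced).  Reference-free, structure-based: backbone RMSD after optimal
rigid superposition (Kabsch), its average over MSA member pairs, and a
simplified superposition-free iRMSD built from differences of intra-molecular
CA-CA distances.  Plus the fold-identification precision/recall protocol
(TM-score >= 0.5 labels proven positives) and the outlier-injection set
builder used to probe robustness of progressive alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence as TSeq, Union

import numpy as np

from .core_io import (
    BACKBONE_ATOMS,
    MultipleAlignment,
    PairwiseAlignment,
    Structure,
)
from .errors import ConsistencyError, ParameterError, UndefinedResultError

Alignment = Union[PairwiseAlignment, MultipleAlignment]


@dataclass(frozen=True)
class StructurePairLabel:
    """Fold-similarity ground truth for a sequence pair: proven positive (PP)
    iff TM-score >= 0.5, proven negative (PN) otherwise."""

    id_a: str
    id_b: str
    tm_score: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tm_score <= 1.0:
            raise ParameterError(f"TM-score {self.tm_score} outside (0, 1]")

    @property
    def label(self) -> str:
        return "PP" if self.tm_score >= 0.5 else "PN"


@dataclass
class EvaluationReport:
    q_score: Optional[float] = None  # percent
    rmsd: Optional[float] = None  # Angstrom
    irmsd: Optional[float] = None  # Angstrom
    identity: Optional[float] = None  # percent
    n_pairs_used: int = 0

    def to_dict(self) -> dict:
        return {
            "q_score": self.q_score,
            "rmsd": self.rmsd,
            "irmsd": self.irmsd,
            "identity": self.identity,
            "n_pairs_used": self.n_pairs_used,
        }


def _pair_set(aln: Alignment) -> set:
    if isinstance(aln, PairwiseAlignment):
        ids = tuple(sorted((aln.seq_a_id, aln.seq_b_id)))
        flip = ids != (aln.seq_a_id, aln.seq_b_id)
        return {
            (ids[0], ids[1]) + ((j, i) if flip else (i, j)) for (i, j) in aln.pairs
        }
    return aln.pair_set()


def _ids(aln: Alignment) -> set[str]:
    if isinstance(aln, PairwiseAlignment):
        return {aln.seq_a_id, aln.seq_b_id}
    return set(aln.rows)


def q_score(test: Alignment, ref: Alignment) -> float:
    """100 x |pairs(test) & pairs(ref)| / |pairs(ref)|, pooling projected
    pairs over all sequence pairs for MSAs."""
    shared_ids = _ids(test) & _ids(ref)
    if not shared_ids:
        raise ConsistencyError("test and reference alignments share no sequences")
    tp = _pair_set(test)
    rp = _pair_set(ref)
    if not rp:
        raise UndefinedResultError("reference alignment has no aligned pairs")
    return 100.0 * len(tp & rp) / len(rp)


def seq_identity(aln: PairwiseAlignment) -> float:
    """Percent identical residue pairs among aligned (non-gap) columns;
    0 when nothing aligns."""
    aligned = ident = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        if ca not in "-." and cb not in "-.":
            aligned += 1
            if ca == cb:
                ident += 1
    return 100.0 * ident / aligned if aligned else 0.0


# ---------------------------------------------------------------------------
# Structure-based metrics


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD over proper rotations + translations (SVD Kabsch with
    reflection correction)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ParameterError(f"point sets must share shape (n, 3); got {A.shape}, {B.shape}")
    if A.shape[0] < 1:
        raise ParameterError("point sets must be nonempty")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    diff = A @ R - B
    return float(np.sqrt((diff * diff).sum() / A.shape[0]))


def _aligned_complete_pairs(
    aln: PairwiseAlignment, sa: Structure, sb: Structure
) -> list[tuple[int, int]]:
    out = []
    for (i, j) in aln.pairs:
        if i < len(sa) and j < len(sb):
            if sa.residues[i].complete and sb.residues[j].complete:
                out.append((i, j))
    return out


def alignment_rmsd(
    aln: PairwiseAlignment, sa: Structure, sb: Structure
) -> tuple[float, int]:
    """Backbone RMSD of an alignment: pool the 4 backbone atoms of every
    aligned residue pair with complete backbones on both sides, then Kabsch.
    Returns (rmsd, number of residue pairs used)."""
    usable = _aligned_complete_pairs(aln, sa, sb)
    if not usable:
        raise UndefinedResultError(
            f"no aligned residue pairs with complete backbones for "
            f"({aln.seq_a_id!r}, {aln.seq_b_id!r})"
        )
    pa = np.array(
        [getattr(sa.residues[i], atom) for (i, _) in usable for atom in BACKBONE_ATOMS]
    )
    pb = np.array(
        [getattr(sb.residues[j], atom) for (_, j) in usable for atom in BACKBONE_ATOMS]
    )
    return kabsch_rmsd(pa, pb), len(usable)


def msa_avg_rmsd(
    msa: MultipleAlignment, structures: Mapping[str, Structure]
) -> tuple[float, int]:
    """Unweighted mean of :func:`alignment_rmsd` over all unordered sequence
    pairs with structures; pairs failing RMSD are skipped and counted.
    Returns (mean rmsd, number of pairs skipped)."""
    vals = []
    skipped = 0
    ids = [s for s in msa.rows if s in structures]
    for id_a, id_b in itertools.combinations(ids, 2):
        try:
            r, _ = alignment_rmsd(msa.project(id_a, id_b), structures[id_a], structures[id_b])
            vals.append(r)
        except UndefinedResultError:
            skipped += 1
    if not vals:
        raise UndefinedResultError("no structure pair yielded an RMSD")
    return float(np.mean(vals)), skipped


def irmsd(
    aln: PairwiseAlignment,
    sa: Structure,
    sb: Structure,
    radius: float = 10.0,
) -> float:
    """Simplified intra-molecular RMSD (APDB-like, superposition-free).

    For every two aligned residue pairs (i, j), (i', j') whose CA-CA distance
    in structure A is below ``radius`` (Angstrom), accumulate
    ``(d_A(i,i') - d_B(j,j'))**2``; return the root mean.  Invariant under
    independent rigid transforms of either structure.
    """
    pairs = [
        (i, j)
        for (i, j) in aln.pairs
        if i < len(sa)
        and j < len(sb)
        and sa.residues[i].CA is not None
        and sb.residues[j].CA is not None
    ]
    acc = 0.0
    count = 0
    for (i, j), (i2, j2) in itertools.combinations(pairs, 2):
        da = float(np.linalg.norm(sa.residues[i].CA - sa.residues[i2].CA))
        if da >= radius:
            continue
        db = float(np.linalg.norm(sb.residues[j].CA - sb.residues[j2].CA))
        acc += (da - db) ** 2
        count += 1
    if count == 0:
        raise UndefinedResultError("no CA pairs within the neighborhood radius")
    return float(np.sqrt(acc / count))


# ---------------------------------------------------------------------------
# Fold identification and outlier protocol


def precision_recall(
    records: Iterable[tuple[float, str]], threshold: float
) -> tuple[Optional[float], float]:
    """Precision/recall (percent) of predicting structural similarity by
    ``identity > threshold`` (strict).  ``records`` are (identity percent,
    label) with label PP/PN.  Precision is None when nothing is predicted
    positive."""
    tp = fp = fn = 0
    for identity, label in records:
        predicted = identity > threshold
        if label == "PP":
            if predicted:
                tp += 1
            else:
                fn += 1
        elif label == "PN":
            if predicted:
                fp += 1
        else:
            raise ParameterError(f"unknown label {label!r}")
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else None
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    return precision, recall


def build_outlier_set(
    test_set: TSeq[str],
    pool: TSeq[str],
    seqidy: Mapping[tuple[str, str], float],
    tm: Mapping[tuple[str, str], float],
    rescale_identity: bool = True,
) -> list[str]:
    """For each member pick the pool candidate maximizing the gap between
    sequence identity and TM-score (identity rescaled to [0, 1] so the two
    terms are commensurable; ``rescale_identity=False`` subtracts the raw
    percentage).  Ties break lexicographically by candidate id.  Returns the
    original ids followed by the chosen outliers; the outliers join the MSA
    but are excluded from downstream scoring.
    """
    if not pool:
        raise ParameterError("outlier pool is empty")

    def get(m: Mapping[tuple[str, str], float], a: str, b: str) -> float:
        if (a, b) in m:
            return m[(a, b)]
        if (b, a) in m:
            return m[(b, a)]
        raise ConsistencyError(f"missing matrix value for pair ({a!r}, {b!r})")

    chosen = []
    for p in test_set:
        best = None
        for cand in sorted(pool):
            idy = get(seqidy, p, cand)
            if rescale_identity:
                idy /= 100.0
            diff = idy - get(tm, p, cand)
            if best is None or diff > best[0]:
                best = (diff, cand)
        chosen.append(best[1])
    return list(test_set) + chosen


def reference_alignment_rmsd(
    msa: MultipleAlignment, structures: Mapping[str, Structure]
) -> tuple[float, int]:
    """Average pairwise backbone RMSD induced by a reference alignment over
    all member pairs with structures (the reference-quality figure computed
    for benchmark sets)."""
    return msa_avg_rmsd(msa, structures)
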