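from __future__ import annotations

import numpy as np
import pytest

from synaln.core_io import (
    PairwiseAlignment,
    ResidueRecord,
    Sequence,
    Structure,
)
from synaln.homologs import HomologMember, HomologSet

AA = "ARNDCQEGHILKMFPSTWYV"


def random_sequence(rng: np.random.Generator, sid: str, n: int) -> Sequence:
    return Sequence(sid, "".join(AA[k] for k in rng.integers(0, 20, size=n)))


def random_homolog_set(
    rng: np.random.Generator, target: Sequence, n_members: int
) -> HomologSet:
    """Random gapped homolog alignments against a target (arbitrary content,
    valid structure) — input generator for oracle comparisons."""
    members = []
    for h in range(n_members):
        i = j = 0
        pairs = []
        hom_res = []
        while i < len(target):
            r = rng.random()
            if r < 0.15:
                i += 1  # target residue unaligned
            elif r < 0.3:
                hom_res.append(AA[rng.integers(0, 20)])
                j += 1  # homolog insertion
            else:
                # aligned column; homolog residue equals target's with p=0.6
                if rng.random() < 0.6:
                    hom_res.append(target.residues[i])
                else:
                    hom_res.append(AA[rng.integers(0, 20)])
                pairs.append((i, j))
                i += 1
                j += 1
        if not hom_res:
            hom_res.append(AA[rng.integers(0, 20)])
        hom = Sequence(f"{target.id}_h{h}", "".join(hom_res))
        aln = PairwiseAlignment.from_pairs(target, hom, pairs)
        ident = 100.0 * sum(
            1 for (i, j) in pairs if target.residues[i] == hom.residues[j]
        ) / max(len(aln.row_a), 1)
        members.append(HomologMember(hom.id, aln, ident))
    return HomologSet(target=target, members=members)


def toy_structure(seq_id: str, coords: np.ndarray, resnames: str | None = None) -> Structure:
    """Structure with one residue per CA coordinate; N/C/O at fixed offsets."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = resnames or "A" * n
    residues = []
    for k in range(n):
        ca = coords[k]
        residues.append(
            ResidueRecord(
                resname=names[k],
                N=ca + np.array([-1.2, 0.3, 0.0]),
                CA=ca.copy(),
                C=ca + np.array([1.1, 0.4, 0.2]),
                O=ca + np.array([1.5, 1.4, 0.1]),
            )
        )
    return Structure(seq_id=seq_id, residues=residues)


def transform_structure(st: Structure, R: np.ndarray, t: np.ndarray) -> Structure:
    residues = []
    for r in st.residues:
        residues.append(
            ResidueRecord(
                resname=r.resname,
                **{
                    a: (R @ getattr(r, a) + t) if getattr(r, a) is not None else None
                    for a in ("N", "CA", "C", "O")
                },
            )
        )
    return Structure(seq_id=st.seq_id, residues=residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
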