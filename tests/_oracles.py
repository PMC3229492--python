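"""Independent reference implementations used to check the package.

Everything here is deliberately naive (triple loops, exhaustive enumeration,
eigen-decomposition instead of SVD) and shares no code with the package's
own computation paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_force_pair_scores(ts, tt, contribution):
    """Triple loop over (word position p, word position q, synonym string):
    the textbook reading of the shared-synonym score."""
    l = ts.word_length
    cells = {}
    for p, syns_p in ts.entries.items():
        for q, syns_q in tt.entries.items():
            for sw in syns_p:
                if sw in syns_q:
                    c = contribution(syns_p[sw], syns_q[sw])
                    for k in range(l):
                        key = (p + k, q + k)
                        cells[key] = cells.get(key, Fraction(0)) + c
    return {k: float(v) for k, v in cells.items()}


def rank_bucket_normalize(cells, n_max):
    """Straightforward rank-then-bucket reimplementation."""
    alignable = sorted(
        ((i, j, v) for (i, j), v in cells.items() if v > 0),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    n = min(n_max, len(alignable))
    if n == 0:
        return {}
    base, extra = divmod(len(alignable), n)
    out = {}
    idx = 0
    for g in range(1, n + 1):
        size = base + (1 if g <= extra else 0)
        for (i, j, _) in alignable[idx : idx + size]:
            out[(i, j)] = n - g + 1
        idx += size
    return out


def enumerate_alignments(m, n):
    """All monotone sets of aligned index pairs for sequences of length m, n.

    The affine cost of a pair set is minimized by the canonical column layout
    (one maximal gap run per sequence between consecutive pairs), which is how
    :func:`alignment_cost` lays columns out, so enumerating pair sets covers
    all optima."""

    def rec(i0, j0):
        yield []
        for i in range(i0, m):
            for j in range(j0, n):
                for rest in rec(i + 1, j + 1):
                    yield [(i, j)] + rest

    yield from rec(0, 0)


def alignment_cost(pairs, m, n, score, gap_open, gap_extend):
    """Score of an alignment under the package's gap model: sum of cell
    scores minus open + extend * k per maximal gap run (computed from the
    explicit column layout)."""
    # reconstruct column operations
    ops = []
    i = j = 0
    for (pi, pj) in pairs:
        while i < pi:
            ops.append("I")  # unpaired residue of A
            i += 1
        while j < pj:
            ops.append("J")
            j += 1
        ops.append("M")
        i += 1
        j += 1
    while i < m:
        ops.append("I")
        i += 1
    while j < n:
        ops.append("J")
        j += 1
    total = 0.0
    i = j = 0
    for op in ops:
        if op == "M":
            total += score(i, j)
            i += 1
            j += 1
        elif op == "I":
            i += 1
        else:
            j += 1
    run = None
    for op in ops + ["M"]:
        if op == "M":
            if run is not None:
                total -= gap_open + gap_extend * run[1]
                run = None
        else:
            if run is None or run[0] != op:
                if run is not None:
                    total -= gap_open + gap_extend * run[1]
                run = [op, 0]
            run[1] += 1
    return total


def best_alignment_score(dense, gap_open=0.0, gap_extend=0.0):
    m, n = dense.shape
    best = -np.inf
    for pairs in enumerate_alignments(m, n):
        s = alignment_cost(
            pairs, m, n, lambda i, j: dense[i, j], gap_open, gap_extend
        )
        best = max(best, s)
    return best


def brute_force_extension(libs_dense, ids, x, y):
    """Triplet extension by explicit loops."""
    Dxy = libs_dense[(x, y)]
    out = Dxy.copy()
    m, n = Dxy.shape
    for z in ids:
        if z in (x, y):
            continue
        Dxz = libs_dense[(x, z)]
        Dzy = libs_dense[(z, y)]
        for i in range(m):
            for j in range(n):
                for k in range(Dxz.shape[1]):
                    out[i, j] += min(Dxz[i, k], Dzy[k, j])
    return out


def quaternion_rmsd(A, B):
    """Horn's quaternion method for optimal rigid superposition RMSD."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (A * A).sum() + (B * B).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / A.shape[0]))


def random_rigid_transform(rng):
    """A uniform-ish random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=10.0, size=3)
    return R, t
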