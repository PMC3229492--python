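"""Dot-matrix visualization of shared-synonym support.

Each residue pair with at least one shared synonym becomes a dot whose
darkness grows with the number of shared synonyms (linear by default,
optionally log-scaled for heavy-tailed counts).  Pairs annotated as
equivalent in a reference alignment are drawn on a red scale instead of
gray, so well-supported alternative (sub-optimal) alignments stand out next
to the reference path.  Sequence A runs down the vertical axis, B along the
horizontal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core_io import PairwiseAlignment
from .errors import ParameterError
from .synonym_engine import PairScoreMatrix


def dot_matrix(
    counts: PairScoreMatrix,
    path: str | Path,
    ref: Optional[PairwiseAlignment] = None,
    log_scale: bool = False,
    text_path: Optional[str | Path] = None,
    dpi: int = 150,
) -> None:
    """Render shared-synonym counts as a grayscale dot matrix, reference
    pairs on a red scale at the same intensity mapping.

    Reference pairs with zero shared synonyms are drawn at the faintest
    nonzero intensity so the reference path stays visible.  With ``text_path``
    the counts are also dumped as TSV (i, j, count, in_ref) — a stabler test
    surface than image bytes.  Rendering is deterministic: identical inputs
    produce identical files.
    """
    m, n = counts.shape
    ref_pairs: set[tuple[int, int]] = set()
    if ref is not None:
        ref_pairs = set(ref.pairs)
        for (i, j) in ref_pairs:
            if not (0 <= i < m and 0 <= j < n):
                raise ParameterError(f"reference pair ({i}, {j}) outside matrix {counts.shape}")
    max_count = max(counts.cells.values(), default=0.0)

    def intensity(c: float) -> float:
        if max_count <= 0:
            return 0.0
        if log_scale:
            return float(np.log1p(c) / np.log1p(max_count))
        return float(c / max_count)

    img = np.ones((m, n, 3))
    floor = intensity(1.0) if max_count > 0 else 1.0
    for (i, j), c in counts.cells.items():
        w = 1.0 - intensity(c)
        img[i, j] = (w, w, w)
    for (i, j) in ref_pairs:
        c = counts.cells.get((i, j), 0.0)
        w = 1.0 - max(intensity(c), floor)
        img[i, j] = (1.0, w, w)

    fig, ax = plt.subplots(figsize=(max(3.0, n / 40), max(3.0, m / 40)))
    ax.imshow(img, origin="upper", interpolation="nearest", aspect="equal")
    ax.set_xlabel(counts.seq_b_id)
    ax.set_ylabel(counts.seq_a_id)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)

    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write("i\tj\tcount\tin_ref\n")
            for (i, j) in sorted(set(counts.cells) | ref_pairs):
                c = counts.cells.get((i, j), 0.0)
                fh.write(f"{i}\t{j}\t{c:g}\t{int((i, j) in ref_pairs)}\n")
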