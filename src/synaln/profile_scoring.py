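"""Profile-profile baseline scorers computed from PSI-BLAST PSSMs.

Two classic fold-recognition scoring functions, both producing a dense
:class:`~synaln.synonym_engine.PairScoreMatrix` comparable with the synonym
scores:

* BASIC — the bilinear form of the two log-odds profile rows through a
  background substitution matrix (BLOSUM62 by default):
  ``D(i,j) = sum_kl A(i,k) M(k,l) B(j,l)``.
* B-DHIP — the symmetric cross dot-product of log-odds and estimated
  probabilities: ``D(i,j) = (A(i)·B~(j) + A~(i)·B(j)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import AA_ORDER, BACKGROUND_FREQS, blosum62
from .errors import FormatError, ParameterError
from .synonym_engine import PairScoreMatrix


@dataclass
class Profile:
    """A sequence profile: per-position log-odds scores and estimated
    amino-acid probabilities, columns in ``AA_ORDER``."""

    seq_id: str
    residues: str
    logodds: np.ndarray  # (m, 20) float
    probs: np.ndarray  # (m, 20) float, rows sum to 1
    background_rows: list[int] = field(default_factory=list)  # rows that had
    # all-zero observed percentages, replaced by background frequencies

    def __post_init__(self) -> None:
        m = len(self.residues)
        if self.logodds.shape != (m, 20) or self.probs.shape != (m, 20):
            raise ParameterError(
                f"profile {self.seq_id!r}: matrix shapes must be ({m}, 20)"
            )
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ParameterError(
                f"profile {self.seq_id!r}: probability rows must sum to 1"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def parse_pssm(path: str | Path, seq_id: Optional[str] = None) -> Profile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``).

    Both the 20 log-odds columns and the 20 percentage columns are read;
    percentages are divided by 100 (and renormalized, since PSI-BLAST prints
    truncated integers); all-zero percentage rows fall back to background
    frequencies and are flagged.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for k, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 40 and all(p in AA_ORDER for p in parts):
            header_idx = k
            break
    if header_idx is None:
        raise FormatError(f"{path}: no PSSM column header found")
    residues: list[str] = []
    logodds: list[list[float]] = []
    percents: list[list[float]] = []
    expected = 1
    for line in lines[header_idx + 1 :]:
        parts = line.split()
        if len(parts) < 42:
            break  # footer (K/Lambda statistics) or blank
        try:
            idx = int(parts[0])
            row_lo = [float(x) for x in parts[2:22]]
            row_pc = [float(x) for x in parts[22:42]]
        except ValueError:
            break
        if idx != expected:
            raise FormatError(f"{path}: unexpected position {idx} (wanted {expected})")
        residues.append(parts[1].upper())
        logodds.append(row_lo)
        percents.append(row_pc)
        expected += 1
    if not residues:
        raise FormatError(f"{path}: truncated PSSM, no data rows")
    pc = np.array(percents)
    probs = pc / 100.0
    background_rows = []
    for r in range(probs.shape[0]):
        s = probs[r].sum()
        if s <= 0.0:
            probs[r] = BACKGROUND_FREQS
            background_rows.append(r)
        else:
            probs[r] /= s
    return Profile(
        seq_id=seq_id or path.stem,
        residues="".join(residues),
        logodds=np.array(logodds),
        probs=probs,
        background_rows=background_rows,
    )


def write_pssm(profile: Profile, path: str | Path) -> None:
    """Internal ASCII PSSM writer (round-trips through :func:`parse_pssm`,
    up to integer truncation of the percentage columns)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for r in range(profile.length):
            lo = " ".join(f"{int(round(v)):3d}" for v in profile.logodds[r])
            pc = " ".join(f"{int(round(v * 100)):3d}" for v in profile.probs[r])
            fh.write(f"{r + 1:5d} {profile.residues[r]}  {lo}  {pc}\n")
        fh.write("\n")


def _check_profiles(pa: Profile, pb: Profile) -> None:
    for p in (pa, pb):
        if p.logodds.shape[1] != 20:
            raise ParameterError(f"profile {p.seq_id!r}: alphabet size must be 20")


def basic_score(
    pa: Profile, pb: Profile, matrix: Optional[np.ndarray] = None
) -> PairScoreMatrix:
    """BASIC: bilinear log-odds comparison through a background substitution
    matrix (BLOSUM62 by default).  Dense m x n matrix, negatives kept."""
    _check_profiles(pa, pb)
    M = blosum62() if matrix is None else np.asarray(matrix, dtype=float)
    if M.shape != (20, 20):
        raise ParameterError(f"substitution matrix must be 20x20, got {M.shape}")
    dense = pa.logodds @ M @ pb.logodds.T
    return PairScoreMatrix.from_dense(
        pa.seq_id, pb.seq_id, dense, kind="raw", keep_zeros=False
    )


def bdhip_score(pa: Profile, pb: Profile) -> PairScoreMatrix:
    """B-DHIP: symmetric dot-product of log-odds with probabilities,
    ``D(i,j) = (A(i)·B~(j) + A~(i)·B(j)) / 2``."""
    _check_profiles(pa, pb)
    dense = 0.5 * (pa.logodds @ pb.probs.T + pa.probs @ pb.logodds.T)
    return PairScoreMatrix.from_dense(
        pa.seq_id, pb.seq_id, dense, kind="raw", keep_zeros=False
    )


def profile_from_sequence(seq_id: str, residues: str) -> Profile:
    """Degenerate one-hot profile for a bare sequence (unit log-odds rows and
    unit probabilities); under BASIC this reduces to plain substitution
    scoring.  ``X`` rows fall back to background probabilities."""
    m = len(residues)
    logodds = np.zeros((m, 20))
    probs = np.zeros((m, 20))
    background_rows = []
    for r, ch in enumerate(residues):
        k = AA_ORDER.find(ch)
        if k >= 0:
            logodds[r, k] = 1.0
            probs[r, k] = 1.0
        else:
            probs[r] = BACKGROUND_FREQS
            background_rows.append(r)
    return Profile(seq_id, residues, logodds, probs, background_rows)
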