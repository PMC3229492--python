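"""Domain types and file I/O.

Types: :class:`Sequence`, :class:`PairwiseAlignment`, :class:`MultipleAlignment`,
:class:`Structure` and :class:`TCLibrary`.  Readers/writers: FASTA, reference
alignments (MSF / aligned FASTA), PDB backbone coordinates, and the T-Coffee
residue-pair library format (``TC_LIB_FORMAT_01``).

All residue coordinates are 0-based half-open internally; the T-Coffee library
format alone uses 1-based indices, converted at the single read/write boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TSequence

import gemmi
import numpy as np
from Bio import AlignIO, SeqIO

from .alphabet import GAP_CHARS, VALID_RESIDUES
from .errors import ConsistencyError, FormatError, LookupFailure

GAP = "-"


def _degap(row: str) -> str:
    return "".join(ch for ch in row if ch not in GAP_CHARS)


@dataclass(frozen=True)
class Sequence:
    """An ungapped protein sequence.

    ``residues`` is a string over the 20 amino-acid letters plus ``X``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows over a (possibly local) region of two sequences.

    ``a_start``/``b_start`` are the 0-based ungapped offsets of the first
    residue of each row within its full sequence, so local BLAST HSPs carry
    correct global coordinates.  ``pairs`` lists 0-based global residue index
    pairs for columns where both rows hold a residue.
    """

    seq_a_id: str
    seq_b_id: str
    row_a: str
    row_b: str
    a_start: int = 0
    b_start: int = 0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise FormatError(
                f"alignment rows for {self.seq_a_id!r}/{self.seq_b_id!r} "
                f"have unequal lengths {len(self.row_a)} != {len(self.row_b)}"
            )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        out = []
        i, j = self.a_start, self.b_start
        for ca, cb in zip(self.row_a, self.row_b):
            ga, gb = ca in GAP_CHARS, cb in GAP_CHARS
            if not ga and not gb:
                out.append((i, j))
            if not ga:
                i += 1
            if not gb:
                j += 1
        return out

    @property
    def ungapped_a(self) -> str:
        return _degap(self.row_a)

    @property
    def ungapped_b(self) -> str:
        return _degap(self.row_b)

    @classmethod
    def from_pairs(
        cls,
        seq_a: Sequence,
        seq_b: Sequence,
        pairs: Iterable[tuple[int, int]],
    ) -> "PairwiseAlignment":
        """Global alignment whose aligned columns are exactly ``pairs``
        (strictly increasing in both coordinates); everything else is gapped."""
        ra, rb = [], []
        i = j = 0
        for (pi, pj) in pairs:
            if pi < i or pj < j:
                raise ConsistencyError("pairs must be strictly increasing in both coordinates")
            while i < pi:
                ra.append(seq_a.residues[i]); rb.append(GAP); i += 1
            while j < pj:
                ra.append(GAP); rb.append(seq_b.residues[j]); j += 1
            ra.append(seq_a.residues[i]); rb.append(seq_b.residues[j])
            i += 1; j += 1
        while i < len(seq_a):
            ra.append(seq_a.residues[i]); rb.append(GAP); i += 1
        while j < len(seq_b):
            ra.append(GAP); rb.append(seq_b.residues[j]); j += 1
        return cls(seq_a.id, seq_b.id, "".join(ra), "".join(rb))


@dataclass
class MultipleAlignment:
    """Mapping from sequence id to gapped row, all rows equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("a multiple alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def project(self, id_a: str, id_b: str) -> PairwiseAlignment:
        """Induced pairwise alignment of two member sequences (columns gapped
        in both rows are dropped)."""
        try:
            ra, rb = self.rows[id_a], self.rows[id_b]
        except KeyError as exc:
            raise LookupFailure(f"sequence {exc.args[0]!r} not in alignment") from exc
        cols = [
            (ca, cb)
            for ca, cb in zip(ra, rb)
            if not (ca in GAP_CHARS and cb in GAP_CHARS)
        ]
        return PairwiseAlignment(
            id_a, id_b, "".join(c[0] for c in cols), "".join(c[1] for c in cols)
        )

    def pair_set(self) -> set[tuple[str, str, int, int]]:
        """All projected residue pairs pooled over unordered sequence pairs,
        with ids ordered lexicographically inside each tuple."""
        out: set[tuple[str, str, int, int]] = set()
        for id_a, id_b in itertools.combinations(sorted(self.rows), 2):
            for (i, j) in self.project(id_a, id_b).pairs:
                out.add((id_a, id_b, i, j))
        return out


BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueRecord:
    """One residue's backbone coordinates; missing atoms are ``None``."""

    resname: str
    N: Optional[np.ndarray] = None
    CA: Optional[np.ndarray] = None
    C: Optional[np.ndarray] = None
    O: Optional[np.ndarray] = None

    @property
    def complete(self) -> bool:
        return all(getattr(self, a) is not None for a in BACKBONE_ATOMS)


@dataclass
class Structure:
    """Ordered backbone records for one chain, mapped positionally to the
    sequence (k-th structure residue <-> k-th sequence residue)."""

    seq_id: str
    residues: list[ResidueRecord]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TCLibrary:
    """A T-Coffee residue-pair library: sequences plus weighted residue pairs.

    Entries hold 1-based residue indices (the library format's convention);
    everything else in the package is 0-based.
    """

    sequences: list[Sequence]
    entries: list[tuple[str, str, int, int, int]]

    def __post_init__(self) -> None:
        by_id = {s.id: s for s in self.sequences}
        if len(by_id) != len(self.sequences):
            raise ConsistencyError("duplicate sequence ids in library")
        for (ida, idb, ra, rb, w) in self.entries:
            for sid, r in ((ida, ra), (idb, rb)):
                if sid not in by_id:
                    raise LookupFailure(f"library entry references unknown sequence {sid!r}")
                if not 1 <= r <= len(by_id[sid]):
                    raise FormatError(
                        f"residue index {r} out of range for {sid!r} (1-based contract)"
                    )
            if w < 1:
                raise FormatError(f"library weight must be >= 1, got {w}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read protein sequences; ids are the header up to the first whitespace,
    residues are upper-cased and trailing ``*`` stripped."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seqs = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("*", "")
        try:
            seqs.append(Sequence(rec.id, residues))
        except FormatError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for k in range(0, len(s.residues), width):
                fh.write(s.residues[k : k + width] + "\n")


def read_reference_alignment(path: str | Path, dialect: str = "aligned_fasta") -> MultipleAlignment:
    """Read an MSF or aligned-FASTA reference alignment; ``.`` and ``-`` gaps
    are both normalised to ``-``."""
    fmt = {"msf": "msf", "aligned_fasta": "fasta"}.get(dialect)
    if fmt is None:
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows = {
        rec.id: str(rec.seq).upper().replace(".", GAP) for rec in aln
    }
    if len(rows) != len(aln):
        raise FormatError(f"{path}: duplicate row ids")
    return MultipleAlignment(rows)


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, row in msa.rows.items():
            fh.write(f">{sid}\n")
            for k in range(0, len(row), width):
                fh.write(row[k : k + width] + "\n")


def write_clustal(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    """ClustalW-format output (without the conservation line)."""
    name_w = max(len(s) for s in msa.rows) + 3
    with open(path, "w") as fh:
        fh.write("CLUSTAL W multiple sequence alignment\n\n")
        for k in range(0, msa.length, width):
            for sid, row in msa.rows.items():
                fh.write(f"{sid:<{name_w}}{row[k : k + width]}\n")
            fh.write("\n")


def read_pdb_backbone(path: str | Path, chain_id: str) -> Structure:
    """Extract N/CA/C/O coordinates of a chain's standard residues.

    ATOM records only (HETATM skipped); for alternate locations the first
    occurrence of each atom name wins; residues with missing backbone atoms
    are kept with the gap recorded as ``None``.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise LookupFailure(
            f"{path}: chain {chain_id!r} not found (have {[c.name for c in model]})"
        )
    residues = []
    for res in chain:
        if res.het_flag != "A":  # skip HETATM (waters, ligands)
            continue
        info = gemmi.find_tabulated_residue(res.name)
        one = "X"
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                one = code
        rec = ResidueRecord(resname=one)
        for atom in res:
            if atom.name in BACKBONE_ATOMS and getattr(rec, atom.name) is None:
                setattr(
                    rec,
                    atom.name,
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float),
                )
        residues.append(rec)
    return Structure(seq_id=chain_id, residues=residues)


TC_HEADER = "! TC_LIB_FORMAT_01"
TC_FOOTER = "! SEQ_1_TO_N"


def write_tc_lib(lib: TCLibrary, path: str | Path) -> None:
    """Emit the T-Coffee library text format (1-based residue indices)."""
    index = {s.id: k + 1 for k, s in enumerate(lib.sequences)}
    blocks: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for (ida, idb, ra, rb, w) in lib.entries:
        ia, ib = index[ida], index[idb]
        if ia <= ib:
            blocks.setdefault((ia, ib), []).append((ra, rb, w))
        else:
            blocks.setdefault((ib, ia), []).append((rb, ra, w))
    with open(path, "w") as fh:
        fh.write(TC_HEADER + "\n")
        fh.write(f"{len(lib.sequences)}\n")
        for s in lib.sequences:
            fh.write(f"{s.id} {len(s)} {s.residues}\n")
        for (ia, ib) in sorted(blocks):
            fh.write(f"#{ia} {ib}\n")
            for (ra, rb, w) in blocks[(ia, ib)]:
                fh.write(f"{ra} {rb} {w}\n")
        fh.write(TC_FOOTER + "\n")


def read_tc_lib(path: str | Path) -> TCLibrary:
    """Inverse of :func:`write_tc_lib` (round-trip identity up to block order)."""
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, 1))

    def next_content() -> tuple[int, str]:
        for n, raw in it:
            line = raw.strip()
            if line:
                return n, line
        raise FormatError(f"{path}: unexpected end of file")

    n, line = next_content()
    if line != TC_HEADER:
        raise FormatError(f"{path}:{n}: expected {TC_HEADER!r}, got {line!r}")
    n, line = next_content()
    try:
        nseq = int(line)
    except ValueError:
        raise FormatError(f"{path}:{n}: expected sequence count, got {line!r}")
    seqs = []
    for _ in range(nseq):
        n, line = next_content()
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{n}: expected 'name length sequence'")
        name, slen, residues = parts
        if int(slen) != len(residues):
            raise FormatError(f"{path}:{n}: declared length {slen} != {len(residues)}")
        seqs.append(Sequence(name, residues.upper()))
    entries: list[tuple[str, str, int, int, int]] = []
    cur: Optional[tuple[str, str]] = None
    for n, raw in it:
        line = raw.strip()
        if not line:
            continue
        if line == TC_FOOTER:
            break
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{n}: malformed pair header {line!r}")
            ia, ib = (int(p) for p in parts)
            if not (1 <= ia <= nseq and 1 <= ib <= nseq):
                raise FormatError(f"{path}:{n}: sequence index out of range")
            cur = (seqs[ia - 1].id, seqs[ib - 1].id)
        else:
            if cur is None:
                raise FormatError(f"{path}:{n}: entry before any '#a b' header")
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{n}: malformed entry {line!r}")
            ra, rb, w = (int(p) for p in parts[:3])
            entries.append((cur[0], cur[1], ra, rb, w))
    try:
        return TCLibrary(sequences=seqs, entries=entries)
    except (FormatError, LookupFailure, ConsistencyError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
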