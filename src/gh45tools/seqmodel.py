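"""Sequence and alignment data model plus the pairwise primitives.

This module provides the containers every other stage works on — annotated
protein/CDS records, multiple alignments read from aligned FASTA — and the
three primitives the downstream analyses rely on: optimal global alignment
with affine gap costs, pairwise percent identity (CD-HIT style denominator:
the shorter ungapped sequence), and gap-aware p-distance between alignment
rows.  Column trimming removes alignment columns whose gap fraction exceeds
a threshold (default: drop columns with more than 50% gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import _align

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"
GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_SUBMAT = np.zeros((20, 20))
for _a, _i in _AA_INDEX.items():
    for _b, _j in _AA_INDEX.items():
        _SUBMAT[_i, _j] = _BLOSUM62[_a, _b]


class SequenceError(ValueError):
    """Raised for malformed sequences or alignments."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein (or CDS) sequence with taxonomy annotations.

    ``lineage`` is an ordered tuple of labels from broad to narrow
    (e.g. kingdom, order, superfamily, family, subfamily); it may be
    partial or empty.
    """

    id: str
    residues: str
    taxon: str = ""
    lineage: tuple[str, ...] = ()
    moltype: str = "protein"

    def __post_init__(self):
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} has no residues")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet and ch != GAP:
                raise SequenceError(
                    f"unknown residue {ch!r} at position {pos + 1} of "
                    f"sequence {self.id!r}"
                )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise SequenceError("aligned strings differ in length")
        for k, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            if x == GAP and y == GAP:
                raise SequenceError(f"column {k} is gap-in-both")

    @property
    def ncol(self) -> int:
        return len(self.aligned_a)

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.aligned_a, self.aligned_b)


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise SequenceError("alignment has no rows")
        ncol = len(self.rows[0].residues)
        seen = set()
        for r in self.rows:
            if len(r.residues) != ncol:
                raise SequenceError(
                    f"row {r.id!r} has length {len(r.residues)}, expected {ncol}"
                )
            if r.id in seen:
                raise SequenceError(f"duplicate row id {r.id!r}")
            seen.add(r.id)

    @property
    def ncol(self) -> int:
        return len(self.rows[0].residues)

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == rid:
                return r
        raise KeyError(f"no alignment row with id {rid!r}")

    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def to_matrix(self) -> np.ndarray:
        """Rows as a (nrow, ncol) array of single characters."""
        return np.array([list(r.residues) for r in self.rows])


def _encode(seq: SequenceRecord | str, label: str) -> np.ndarray:
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise SequenceError(f"{label} sequence is empty")
    out = np.empty(len(residues), dtype=np.int64)
    for pos, ch in enumerate(residues):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise SequenceError(
                f"unknown residue {ch!r} at position {pos + 1} of {label} sequence"
            )
        out[pos] = idx
    return out


def global_align(a: SequenceRecord | str, b: SequenceRecord | str,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global (end-to-end) alignment under BLOSUM62 + affine gaps.

    A gap run of length L costs ``gap_open + L * gap_extend``.  Traceback
    ties are broken substitution > gap-in-b > gap-in-a, so the reported
    alignment is deterministic.
    """
    ea = _encode(a, "first")
    eb = _encode(b, "second")
    score, cols = _align.gotoh_align(ea, eb, _SUBMAT, gap_open, gap_extend)
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    out_a = "".join(sa[i] if i >= 0 else GAP for i, _ in cols)
    out_b = "".join(sb[j] if j >= 0 else GAP for _, j in cols)
    return PairwiseAlignment(out_a, out_b, score)


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str,
                      gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Fraction of identical aligned residue pairs over the shorter length.

    The denominator is the ungapped length of the shorter input (the
    CD-HIT convention), so a perfect fragment scores 1.0 against its
    full-length parent.
    """
    aln = global_align(a, b, gap_open, gap_extend)
    matches = sum(1 for x, y in aln.columns() if x == y and x != GAP)
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    return matches / min(len(sa), len(sb))


def trim_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    A column at exactly the threshold is retained.  Row order is preserved.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise SequenceError("max_gap_fraction must lie in [0, 1]")
    mat = aln.to_matrix()
    gap_frac = (mat == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    rows = [
        replace(r, residues="".join(np.array(list(r.residues))[keep]))
        for r in aln.rows
    ]
    return Alignment(rows)


def p_distance(row_a: SequenceRecord | str, row_b: SequenceRecord | str) -> float:
    """Proportion of differing sites, excluding sites gapped in either row."""
    sa = row_a.residues if isinstance(row_a, SequenceRecord) else row_a
    sb = row_b.residues if isinstance(row_b, SequenceRecord) else row_b
    if len(sa) != len(sb):
        raise SequenceError("p-distance requires rows of equal aligned length")
    a = np.array(list(sa))
    b = np.array(list(sb))
    comparable = (a != GAP) & (b != GAP)
    n = int(comparable.sum())
    if n == 0:
        raise SequenceError("no comparable (gap-free) sites between rows")
    return float((a[comparable] != b[comparable]).sum() / n)


def p_distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    """All-pairs p-distance over alignment rows (vectorised)."""
    mat = aln.to_matrix()
    gaps = mat == GAP
    n = aln.nrow
    d = np.zeros((n, n))
    for i in range(n):
        comparable = ~gaps[i] & ~gaps[i + 1:]
        mism = (mat[i] != mat[i + 1:]) & comparable
        counts = comparable.sum(axis=1)
        if (counts == 0).any():
            bad = int(np.where(counts == 0)[0][0]) + i + 1
            raise SequenceError(
                f"no comparable sites between rows {aln.rows[i].id!r} "
                f"and {aln.rows[bad].id!r}"
            )
        d[i, i + 1:] = mism.sum(axis=1) / counts
    d = d + d.T
    return aln.ids(), d


# ---------------------------------------------------------------------------
# FASTA + taxonomy I/O
# ---------------------------------------------------------------------------

def _parse_description(desc: str) -> tuple[str, tuple[str, ...]]:
    """Extract taxon=... and lineage=a;b;c tokens from a FASTA description."""
    taxon = ""
    lineage: tuple[str, ...] = ()
    for token in desc.split()[1:]:
        if token.startswith("taxon="):
            taxon = token[len("taxon="):]
        elif token.startswith("lineage="):
            lineage = tuple(
                lv for lv in token[len("lineage="):].split(";") if lv
            )
    return taxon, lineage


def read_fasta(path: str | Path, moltype: str = "protein",
               taxonomy_tsv: str | Path | None = None,
               aligned: bool = False) -> list[SequenceRecord]:
    """Read (optionally aligned) FASTA into SequenceRecords.

    Taxonomy comes from ``key=value`` tokens on the description line, or from
    a sidecar TSV with columns id, taxon, lineage ('/' or ';' separated); the
    TSV takes precedence.  '.' gap characters are normalised to '-'.
    """
    sidecar: dict[str, tuple[str, tuple[str, ...]]] = {}
    if taxonomy_tsv is not None:
        for line in Path(taxonomy_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rid = parts[0]
            taxon = parts[1] if len(parts) > 1 else ""
            lineage = tuple(
                lv for lv in parts[2].replace("/", ";").split(";") if lv
            ) if len(parts) > 2 else ()
            sidecar[rid] = (taxon, lineage)

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(".", GAP)
        if not aligned:
            residues = residues.replace(GAP, "")
        taxon, lineage = _parse_description(rec.description)
        if rec.id in sidecar:
            taxon, lineage = sidecar[rec.id]
        records.append(SequenceRecord(rec.id, residues, taxon, lineage, moltype))
    if not records:
        raise SequenceError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise SequenceError(f"duplicate sequence id {dup!r} in {path}")
    return records


def read_alignment(path: str | Path, moltype: str = "protein",
                   taxonomy_tsv: str | Path | None = None) -> Alignment:
    return Alignment(read_fasta(path, moltype, taxonomy_tsv, aligned=True))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with taxonomy tokens in the description line."""
    out = []
    for r in records:
        desc = []
        if r.taxon:
            desc.append(f"taxon={r.taxon}")
        if r.lineage:
            desc.append("lineage=" + ";".join(r.lineage))
        out.append(_BioSeqRecord(Seq(r.residues), id=r.id,
                                 description=" ".join(desc)))
    SeqIO.write(out, str(path), "fasta")


def write_taxonomy_tsv(records: Iterable[SequenceRecord],
                       path: str | Path) -> None:
    lines = ["#id\ttaxon\tlineage"]
    for r in records:
        lines.append(f"{r.id}\t{r.taxon}\t{';'.join(r.lineage)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        taxon = parts[1] if len(parts) > 1 else ""
        lineage = tuple(
            lv for lv in parts[2].replace("/", ";").split(";") if lv
        ) if len(parts) > 2 else ()
        out[parts[0]] = (taxon, lineage)
    return out
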