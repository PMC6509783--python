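"""Intron phases from CDS exon coordinates and cross-species conservation.

An intron's phase is the number of CDS nucleotides upstream of it modulo 3
(phase 1 = the intron falls after the first nucleotide of a codon).  Each
intron is anchored to the 0-based residue index of the codon it interrupts
(phase-0 introns anchor to the codon immediately following the boundary),
then projected onto a protein alignment so that introns of different genes
become comparable by column.  Single-linkage grouping of projected introns
(same phase, columns within a tolerance) recovers introns conserved across
species — e.g. an ancestral phase-1 intron inside the signal-peptide-coding
region shared by descendants of a single ancestral gene.

Coordinates: GFF3 intervals are 1-based inclusive; residue indices are
0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .seqmodel import Alignment, GAP


class GeneModelError(ValueError):
    """Raised for inconsistent gene models or projections."""


@dataclass
class GeneModel:
    """CDS exon coordinates of one gene, in translation order."""

    gene_id: str
    protein_id: str
    strand: str                      # '+' or '-'
    cds_exons: list[tuple[int, int]]  # 1-based inclusive genomic intervals
    signal_peptide_len: int | None = None
    seqid: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_exons:
            raise GeneModelError(f"{self.gene_id}: no CDS exons")
        for s, e in self.cds_exons:
            if e < s:
                raise GeneModelError(f"{self.gene_id}: exon ({s},{e}) inverted")
        ordered = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise GeneModelError(
                    f"{self.gene_id}: exons ({s1},{e1}) and ({s2},{e2}) overlap"
                )
        # translation order: ascending on '+', descending on '-'
        expect = ordered if self.strand == "+" else ordered[::-1]
        if self.cds_exons != expect:
            raise GeneModelError(
                f"{self.gene_id}: exons not in translation order for "
                f"strand {self.strand!r}"
            )
        if self.cds_len % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_len} not divisible by 3"
            )

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.cds_exons]

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lengths)


@dataclass(frozen=True)
class IntronRecord:
    """One intron: phase, interrupted codon, and (once projected) column."""

    gene_id: str
    index: int
    phase: int
    anchor_codon: int                      # 0-based residue index
    anchor_column: int | None = None       # alignment column, once projected
    in_signal_peptide: bool | None = None

    @property
    def projected(self) -> bool:
        return self.anchor_column is not None


@dataclass
class IntronGroup:
    """Introns linked by shared phase and (near-)identical column."""

    phase: int
    introns: list[IntronRecord]

    @property
    def gene_ids(self) -> list[str]:
        return [i.gene_id for i in self.introns]

    @property
    def columns(self) -> list[int]:
        return sorted({i.anchor_column for i in self.introns})

    @property
    def n_genes(self) -> int:
        return len({i.gene_id for i in self.introns})

    @property
    def in_signal_peptide(self) -> bool:
        """True iff every annotated member lies in the signal peptide."""
        flags = [i.in_signal_peptide for i in self.introns
                 if i.in_signal_peptide is not None]
        return bool(flags) and all(flags)


def compute_introns(gm: GeneModel) -> list[IntronRecord]:
    """One record per gap between consecutive CDS exons.

    phase = (upstream CDS nucleotides) mod 3;
    anchor_codon = floor(upstream CDS nucleotides / 3).
    Minus-strand genes are handled by walking exons in translation order,
    so coordinates never enter the formulas.
    """
    records = []
    upstream = 0
    for idx, length in enumerate(gm.exon_lengths[:-1]):
        upstream += length
        records.append(IntronRecord(
            gene_id=gm.gene_id,
            index=idx,
            phase=upstream % 3,
            anchor_codon=upstream // 3,
        ))
    return records


def project_introns(introns: Sequence[IntronRecord], aln: Alignment,
                    gene_models: Mapping[str, GeneModel] | None = None,
                    protein_ids: Mapping[str, str] | None = None,
                    ) -> list[IntronRecord]:
    """Set anchor_column (and in_signal_peptide, when annotated).

    The protein encoded by each gene must be a row of ``aln``; by default
    the row id is taken from the gene model's ``protein_id`` (or the gene id
    itself when no models are given).  ``protein_ids`` overrides the
    gene-id -> row-id mapping.
    """
    out = []
    for rec in introns:
        gm = gene_models.get(rec.gene_id) if gene_models else None
        rid = rec.gene_id
        if protein_ids and rec.gene_id in protein_ids:
            rid = protein_ids[rec.gene_id]
        elif gm is not None:
            rid = gm.protein_id
        try:
            row = aln.row(rid)
        except KeyError:
            raise GeneModelError(
                f"protein row {rid!r} (gene {rec.gene_id}) missing from alignment"
            ) from None
        # walk the row to the anchor residue's column
        res_no = -1
        column = None
        for col, ch in enumerate(row.residues):
            if ch != GAP:
                res_no += 1
                if res_no == rec.anchor_codon:
                    column = col
                    break
        if column is None:
            raise GeneModelError(
                f"gene {rec.gene_id}: anchor codon {rec.anchor_codon} beyond "
                f"protein length {res_no + 1}"
            )
        sp_len = gm.signal_peptide_len if gm is not None else None
        out.append(replace(
            rec,
            anchor_column=column,
            in_signal_peptide=None if sp_len is None
            else rec.anchor_codon < sp_len,
        ))
    return out


def conserved_intron_groups(introns: Sequence[IntronRecord],
                            column_tolerance: int = 0) -> list[IntronGroup]:
    """Single-linkage groups: same phase, columns within the tolerance.

    Output is deterministic (ordered by phase, then leftmost column) and
    invariant to the input order of introns.
    """
    for rec in introns:
        if not rec.projected:
            raise GeneModelError(
                f"intron {rec.gene_id}:{rec.index} not projected onto the alignment"
            )
    recs = sorted(introns,
                  key=lambda r: (r.phase, r.anchor_column, r.gene_id, r.index))
    groups: list[IntronGroup] = []
    for rec in recs:
        # single linkage on a sorted list: link to the current group iff the
        # nearest member (max column seen) is within tolerance
        if groups and groups[-1].phase == rec.phase and \
                rec.anchor_column - max(i.anchor_column
                                        for i in groups[-1].introns) \
                <= column_tolerance:
            groups[-1].introns.append(rec)
        else:
            groups.append(IntronGroup(phase=rec.phase, introns=[rec]))
    return groups


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3: CDS features grouped by their Parent.

    Recognised attributes on the parent (mRNA/gene) feature:
    ``protein_id`` (defaults to the parent ID) and ``signal_peptide_len``.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", from_string=False,
                            merge_strategy="create_unique", keep_order=True)
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id])
        for p in parents:
            by_parent.setdefault(p, []).append(cds)
    models = []
    for parent_id in sorted(by_parent):
        cdss = by_parent[parent_id]
        strand = cdss[0].strand
        exons = sorted((c.start, c.end) for c in cdss)
        if strand == "-":
            exons = exons[::-1]
        protein_id, sp_len = parent_id, None
        try:
            parent = db[parent_id]
            protein_id = parent.attributes.get("protein_id", [parent_id])[0]
            sp = parent.attributes.get("signal_peptide_len")
            sp_len = int(sp[0]) if sp else None
        except gffutils.FeatureNotFoundError:
            pass
        models.append(GeneModel(
            gene_id=parent_id, protein_id=protein_id, strand=strand,
            cds_exons=exons, signal_peptide_len=sp_len,
            seqid=cdss[0].seqid,
        ))
    if not models:
        raise GeneModelError(f"no CDS features found in {path}")
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gm in models:
        start = min(s for s, _ in gm.cds_exons)
        end = max(e for _, e in gm.cds_exons)
        attrs = f"ID={gm.gene_id};protein_id={gm.protein_id}"
        if gm.signal_peptide_len is not None:
            attrs += f";signal_peptide_len={gm.signal_peptide_len}"
        seqid = gm.seqid or gm.gene_id + "_scaffold"
        lines.append("\t".join([
            seqid, "gh45tools", "mRNA", str(start), str(end), ".",
            gm.strand, ".", attrs,
        ]))
        upstream = 0
        for k, (s, e) in enumerate(gm.cds_exons):
            gff_phase = (3 - upstream % 3) % 3
            lines.append("\t".join([
                seqid, "gh45tools", "CDS", str(s), str(e), ".",
                gm.strand, str(gff_phase),
                f"ID={gm.gene_id}.cds{k};Parent={gm.gene_id}",
            ]))
            upstream += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")


def write_intron_tsv(introns: Sequence[IntronRecord], path: str | Path) -> None:
    lines = [
        "# residue indices 0-based; alignment columns 0-based; "
        "phase = upstream CDS nt mod 3",
        "#gene_id\tindex\tphase\tanchor_codon\tanchor_column\tin_signal_peptide",
    ]
    for r in introns:
        lines.append("\t".join([
            r.gene_id, str(r.index), str(r.phase), str(r.anchor_codon),
            "." if r.anchor_column is None else str(r.anchor_column),
            "." if r.in_signal_peptide is None else str(r.in_signal_peptide),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
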