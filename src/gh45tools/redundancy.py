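"""Greedy identity-threshold clustering (CD-HIT style redundancy removal).

Sequences are sorted by length (longest first, input order breaking ties)
and scanned once: each sequence joins the first existing cluster — in
cluster-creation order — whose representative it matches at or above the
identity threshold, otherwise it founds a new cluster.  With the default
threshold of 0.90 this reproduces the usual "remove redundancy at 90%
identity" preprocessing applied to protein families before tree building.

Every comparison is a full global alignment (no k-mer prefilter): exact at
the scale of curated gene families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seqmodel import SequenceRecord, pairwise_identity, write_fasta


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)  # member -> rep

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    def ids(self) -> list[str]:
        return [self.representative.id] + [m.id for m in self.members]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representatives(self) -> list[SequenceRecord]:
        return [c.representative for c in self.clusters]

    def membership(self) -> dict[str, int]:
        """Map every sequence id to its 0-based cluster index."""
        out: dict[str, int] = {}
        for k, c in enumerate(self.clusters):
            for sid in c.ids():
                out[sid] = k
        return out


def greedy_cluster(seqs: Sequence[SequenceRecord],
                   threshold: float = 0.90) -> ClusterSet:
    """Cluster sequences greedily at an identity threshold.

    Deterministic: representatives are cluster founders (the longest
    sequences), and assignment scans clusters in creation order.
    """
    if not seqs:
        raise ValueError("greedy_cluster requires at least one sequence")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i].residues), i))
    clusters: list[Cluster] = []
    for i in order:
        seq = seqs[i]
        for c in clusters:
            ident = pairwise_identity(seq, c.representative)
            if ident >= threshold:
                c.members.append(seq)
                c.identities.append(ident)
                break
        else:
            clusters.append(Cluster(representative=seq))
    return ClusterSet(clusters, threshold)


def write_cluster_tsv(cs: ClusterSet, path: str | Path) -> None:
    lines = ["#cluster_id\trepresentative\tmember\tidentity"]
    for k, c in enumerate(cs.clusters):
        lines.append(f"{k}\t{c.representative.id}\t{c.representative.id}\t1.0000")
        for m, ident in zip(c.members, c.identities):
            lines.append(f"{k}\t{c.representative.id}\t{m.id}\t{ident:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_representatives(cs: ClusterSet, path: str | Path) -> None:
    write_fasta(cs.representatives(), path)
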