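"""Synthetic gene families with implanted ground truth.

The generator evolves a protein family along a guide tree and implants the
three signals the analysis stages must recover:

* a donor -> recipient horizontal transfer: the recipient subtree's
  ancestral sequence is re-sourced from the donor lineage, so recipient
  leaves end up phylogenetically nested next to the donor clade;
* per-leaf diagnostic-residue states encoding a known substrate-class
  label at the five GH45 active-site positions (implanted after the
  substitution process so chance hits never corrupt a label);
* an ancestral phase-1 intron inside the signal-peptide-coding region,
  inherited by a designated clade, plus lineage-specific extra introns
  acquired along branches at a per-branch rate (always outside the signal
  peptide, so the ancestral intron is the only one there).

Substitution model: along a branch of length t each site substitutes with
probability 1 - exp(-rate * t); the new residue is uniform over the other
19 amino acids.  No indels are simulated, so the true alignment is the
leaf sequences themselves.  One seeded RNG stream drives every draw in a
fixed documented order (tree traversal, HGT re-simulation, codon choice,
intron placement, strand choice), making output byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .genestruct import GeneModel, write_gff3
from .seqmodel import (Alignment, PROTEIN_ALPHABET, SequenceRecord,
                       write_fasta, write_taxonomy_tsv)
from .treescan import read_newick, write_newick

# diagnostic positions (1-based, reference numbering) and the residue states
# implanted for each function-label key
DIAGNOSTIC_POSITIONS = {"tyr": 8, "cat_base": 10, "ala": 74,
                        "stabilizer": 114, "cat_acid": 121}
FUNCTION_RESIDUES = {
    "glucanase":                {"tyr": "Y", "cat_base": "D", "ala": "A",
                                 "stabilizer": "D", "cat_acid": "D"},
    "xyloglucanase_stabilizer": {"tyr": "Y", "cat_base": "D", "ala": "A",
                                 "stabilizer": "E", "cat_acid": "D"},
    "xyloglucanase_acid":       {"tyr": "Y", "cat_base": "D", "ala": "A",
                                 "stabilizer": "D", "cat_acid": "E"},
    "inactive_dyad":            {"tyr": "Y", "cat_base": "D", "ala": "A",
                                 "stabilizer": "D", "cat_acid": "V"},
    "inactive_ala":             {"tyr": "Y", "cat_base": "D", "ala": "G",
                                 "stabilizer": "D", "cat_acid": "D"},
}
# the substrate-class label the classifier should assign to each key
EXPECTED_CLASS = {
    "glucanase": "glucanase",
    "xyloglucanase_stabilizer": "xyloglucanase",
    "xyloglucanase_acid": "xyloglucanase",
    "inactive_dyad": "inactive",
    "inactive_ala": "inactive",
}

_AA = np.array(list(PROTEIN_ALPHABET))
_AA_IDX = {a: i for i, a in enumerate(PROTEIN_ALPHABET)}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_CODONS_FOR = {aa: sorted(cs) for aa, cs in _CODONS_FOR.items()}


class ScenarioError(ValueError):
    """Raised for inconsistent scenario configurations."""


@dataclass
class ScenarioConfig:
    """Everything needed to simulate one family, reproducibly."""

    guide_tree: str                                   # newick, branch lengths
    lineage: dict[str, tuple[str, ...]] = field(default_factory=dict)
    hgt_events: list[tuple[str, str]] = field(default_factory=list)
    function_labels: dict[str, str] = field(default_factory=dict)
    ancestral_intron: tuple[int, int, str] | None = None  # (codon, phase, clade)
    extra_intron_rate: float = 0.0                    # per unit branch length
    subst_rate: float = 1.0                           # subs/site/unit length
    seq_length: int = 200
    signal_peptide_len: int = 16
    include_reference_row: bool = True                # pad scheme reference
    seed: int = 0


@dataclass
class TruthTable:
    """Ground truth for every emitted sequence."""

    function_labels: dict[str, str]          # leaf -> config label key
    expected_class: dict[str, str]           # leaf -> classifier label
    lineage: dict[str, tuple[str, ...]]
    intron_groups: list[dict]                # genes, anchor_codon, phase, in_sp
    hgt: list[dict]                          # donor_leaves, recipient_leaves

    def to_json(self) -> str:
        doc = {
            "function_labels": self.function_labels,
            "expected_class": self.expected_class,
            "lineage": {k: list(v) for k, v in self.lineage.items()},
            "intron_groups": [
                {**g, "genes": sorted(g["genes"])} for g in self.intron_groups
            ],
            "hgt": [
                {"donor_leaves": sorted(h["donor_leaves"]),
                 "recipient_leaves": sorted(h["recipient_leaves"])}
                for h in self.hgt
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


@dataclass
class SimulatedFamily:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    gene_models: list[GeneModel]
    alignment: Alignment                 # family rows only (for distances)
    tree: dendropy.Tree
    truth: TruthTable
    config: ScenarioConfig
    # the same alignment with the diagnostic scheme's reference appended as
    # a gap-padded row, so residue diagnosis can run in from-MSA mode; this
    # is the alignment artifact written to disk
    alignment_with_reference: Alignment | None = None


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for nd in tree.preorder_node_iter():
        if (nd.taxon.label if nd.is_leaf() else nd.label) == label:
            return nd
    raise ScenarioError(f"no node labelled {label!r} in the guide tree")


def _leaves_under(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def _mutate(seq: np.ndarray, t: float, rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """One draw per site: substitute with p = 1 - exp(-rate*t), uniform
    over the 19 other residues."""
    out = seq.copy()
    if t <= 0 or rate <= 0:
        return out
    p = 1.0 - np.exp(-rate * t)
    hit = rng.random(seq.shape[0]) < p
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 20, size=k)) % 20
    return out


def simulate_family(cfg: ScenarioConfig) -> SimulatedFamily:
    """Run the full generator; byte-reproducible for a fixed seed."""
    if cfg.seq_length < max(DIAGNOSTIC_POSITIONS.values()):
        raise ScenarioError(
            f"seq_length {cfg.seq_length} shorter than the last diagnostic "
            f"position ({max(DIAGNOSTIC_POSITIONS.values())})"
        )
    for key in cfg.function_labels.values():
        if key not in FUNCTION_RESIDUES:
            raise ScenarioError(f"unknown function label {key!r}")
    if cfg.ancestral_intron is not None:
        anchor, phase, _ = cfg.ancestral_intron
        if not 0 <= anchor < cfg.seq_length:
            raise ScenarioError(f"ancestral intron anchor {anchor} outside "
                                f"the protein")
        if phase not in (0, 1, 2):
            raise ScenarioError(f"intron phase must be 0/1/2, got {phase}")

    tree = read_newick(cfg.guide_tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length

    # --- root sequence: uniform background, canonical diagnostic states
    root_seq = rng.integers(0, 20, size=L)
    for name, pos in DIAGNOSTIC_POSITIONS.items():
        root_seq[pos - 1] = _AA_IDX[FUNCTION_RESIDUES["glucanase"][name]]

    # --- evolve along the guide tree (preorder)
    seqs: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            seqs[nd] = root_seq
        else:
            seqs[nd] = _mutate(seqs[nd.parent_node], nd.edge.length or 0.0,
                               cfg.subst_rate, rng)

    # --- horizontal transfers: re-source each recipient subtree from its
    # donor's simulated sequence, then re-evolve the subtree (preorder)
    hgt_truth = []
    for donor_label, recipient_label in cfg.hgt_events:
        donor = _find_node(tree, donor_label)
        recipient = _find_node(tree, recipient_label)
        anc = donor
        while anc is not None:
            if anc is recipient:
                raise ScenarioError(
                    f"HGT recipient {recipient_label!r} is an ancestor of "
                    f"donor {donor_label!r}"
                )
            anc = anc.parent_node
        for nd in recipient.preorder_iter():
            parent_seq = seqs[donor] if nd is recipient else seqs[nd.parent_node]
            seqs[nd] = _mutate(parent_seq, nd.edge.length or 0.0,
                               cfg.subst_rate, rng)
        hgt_truth.append({
            "donor_leaves": _leaves_under(donor),
            "recipient_leaves": _leaves_under(recipient),
        })

    # --- leaf proteins with implanted diagnostic states
    label_of = {leaf: cfg.function_labels.get(leaf, "glucanase")
                for leaf in leaves}
    proteins = []
    leaf_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for leaf in leaves:
        arr = seqs[leaf_nodes[leaf]].copy()
        for name, pos in DIAGNOSTIC_POSITIONS.items():
            arr[pos - 1] = _AA_IDX[FUNCTION_RESIDUES[label_of[leaf]][name]]
        proteins.append(SequenceRecord(
            id=leaf,
            residues="".join(_AA[arr]),
            taxon=leaf,
            lineage=tuple(cfg.lineage.get(leaf, ())),
        ))

    # --- introns: ancestral (inside the signal peptide) + per-branch extras
    per_gene: dict[str, list[tuple[int, int]]] = {leaf: [] for leaf in leaves}
    intron_truth = []
    used_sites: set[tuple[int, int]] = set()
    if cfg.ancestral_intron is not None:
        anchor, phase, clade = cfg.ancestral_intron
        carriers = _leaves_under(_find_node(tree, clade))
        for leaf in carriers:
            per_gene[leaf].append((anchor, phase))
        used_sites.add((anchor, phase))
        intron_truth.append({
            "genes": carriers, "anchor_codon": anchor, "phase": phase,
            "in_signal_peptide": anchor < cfg.signal_peptide_len,
        })
    if cfg.extra_intron_rate > 0:
        lo = cfg.signal_peptide_len          # extras stay out of the peptide
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            t = nd.edge.length or 0.0
            for _ in range(rng.poisson(cfg.extra_intron_rate * t)):
                while True:
                    anchor = int(rng.integers(lo, L))
                    phase = int(rng.integers(0, 3))
                    if (anchor, phase) not in used_sites:
                        break
                used_sites.add((anchor, phase))
                carriers = _leaves_under(nd)
                for leaf in carriers:
                    per_gene[leaf].append((anchor, phase))
                intron_truth.append({
                    "genes": carriers, "anchor_codon": anchor, "phase": phase,
                    "in_signal_peptide": False,
                })

    # --- CDS (uniform synonymous codon choice) and gene models
    cds_records = []
    gene_models = []
    for prot in proteins:
        codons = []
        for aa in prot.residues:
            options = _CODONS_FOR[aa]
            codons.append(options[int(rng.integers(0, len(options)))])
        codons.append("TAA")
        cds = "".join(codons)
        cds_records.append(SequenceRecord(
            id=prot.id + "_cds", residues=cds, taxon=prot.taxon,
            lineage=prot.lineage, moltype="dna",
        ))
        breakpoints = sorted(3 * a + p for a, p in per_gene[prot.id])
        intron_lens = [int(rng.integers(60, 200)) for _ in breakpoints]
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = []
        prev = 0
        for b in breakpoints:
            exon_lens.append(b - prev)
            prev = b
        exon_lens.append(len(cds) - prev)
        gene_start = 1001
        total = len(cds) + sum(intron_lens)
        exons = []
        if strand == "+":
            pos = gene_start
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + el - 1))
                pos += el + (intron_lens[k] if k < len(intron_lens) else 0)
        else:
            pos = gene_start + total - 1
            for k, el in enumerate(exon_lens):
                exons.append((pos - el + 1, pos))
                pos -= el + (intron_lens[k] if k < len(intron_lens) else 0)
        gene_models.append(GeneModel(
            gene_id=prot.id + "_gene", protein_id=prot.id, strand=strand,
            cds_exons=exons, signal_peptide_len=cfg.signal_peptide_len,
            seqid="scaf_" + prot.id,
        ))

    truth = TruthTable(
        function_labels=label_of,
        expected_class={leaf: EXPECTED_CLASS[key]
                        for leaf, key in label_of.items()},
        lineage={leaf: tuple(cfg.lineage.get(leaf, ())) for leaf in leaves},
        intron_groups=[
            {**g, "genes": [x + "_gene" for x in g["genes"]]}
            for g in intron_truth
        ],
        hgt=hgt_truth,
    )
    aln_with_ref = None
    if cfg.include_reference_row:
        from .resdiag import default_scheme

        ref = default_scheme().reference
        if len(ref.residues) > L:
            raise ScenarioError(
                f"seq_length {L} shorter than the reference sequence "
                f"({len(ref.residues)}); cannot append the reference row"
            )
        padded = SequenceRecord(
            id=ref.id, residues=ref.residues + "-" * (L - len(ref.residues)),
            taxon=ref.taxon,
        )
        aln_with_ref = Alignment(list(proteins) + [padded])

    return SimulatedFamily(
        proteins=proteins,
        cds=cds_records,
        gene_models=gene_models,
        alignment=Alignment(list(proteins)),
        tree=tree,
        truth=truth,
        config=cfg,
        alignment_with_reference=aln_with_ref,
    )


def write_run(family: SimulatedFamily, outdir: str | Path) -> dict[str, str]:
    """Write the six artifacts plus taxonomy and a manifest; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": "proteins.faa",
        "cds": "cds.fna",
        "gff3": "genes.gff3",
        "alignment": "true_alignment.afa",
        "tree": "guide_tree.nwk",
        "taxonomy": "taxonomy.tsv",
        "truth": "truth.json",
    }
    write_fasta(family.proteins, outdir / paths["proteins"])
    write_fasta(family.cds, outdir / paths["cds"])
    write_gff3(family.gene_models, outdir / paths["gff3"])
    aln = family.alignment_with_reference or family.alignment
    write_fasta(aln.rows, outdir / paths["alignment"])
    write_newick(family.tree, outdir / paths["tree"])
    write_taxonomy_tsv(family.proteins, outdir / paths["taxonomy"])
    (outdir / paths["truth"]).write_text(family.truth.to_json() + "\n")
    manifest = {
        "seed": family.config.seed,
        "n_leaves": len(family.proteins),
        "seq_length": family.config.seq_length,
        "subst_rate": family.config.subst_rate,
        "files": paths,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(outdir / v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Ready-made study-shaped scenarios
# ---------------------------------------------------------------------------

def _balanced(names: Sequence[str], t_term: float, t_int: float,
              label: str | None = None, top: float | None = None) -> str:
    """Balanced-ish newick subtree over ``names``.

    ``label`` names the subtree's root node; ``top`` overrides the length
    of the branch subtending it (defaults to ``t_int``).
    """
    if len(names) == 1:
        return f"{names[0]}:{t_term}"
    half = len(names) // 2
    left = _balanced(names[:half], t_term, t_int)
    right = _balanced(names[half:], t_term, t_int)
    lab = label or ""
    length = t_int if top is None else top
    return f"({left},{right}){lab}:{length}"


def hgt_scenario(seed: int = 0, mean_depth: float = 0.3) -> ScenarioConfig:
    """A 60-leaf family shaped like the beetle GH45 study's global tree.

    Three arthropod groups sit among fungal clades: mites and springtails
    are separate clades already in the guide topology, while the beetle
    clade is re-sourced by an HGT event from a fungal donor clade.  A
    bacterial pair serves as outgroup.  Branch lengths are scaled so the
    mean root-to-leaf path is ``mean_depth`` expected substitutions/site.
    """
    def group(prefix, n):
        return [f"{prefix}{i}" for i in range(1, n + 1)]

    bact = group("bact", 2)
    fA, fB, fC, fD = (group(p, n) for p, n in
                      [("fgA", 10), ("fgB", 6), ("fgC", 8), ("fgD", 6)])
    mites, springtails, beetles = (group(p, n) for p, n in
                                   [("mite", 8), ("coll", 8), ("beet", 12)])

    tt, ti, stem, bb = 0.06, 0.02, 0.05, 0.04   # relative lengths
    A = _balanced(fA, tt, ti, "cladeA", stem)
    B = _balanced(fB, tt, ti, "donor_clade", stem)
    C = _balanced(fC, tt, ti, "cladeC", stem)
    D = _balanced(fD, tt, ti, "cladeD", stem)
    M = _balanced(mites, tt, ti, "mite_clade", stem)
    S = _balanced(springtails, tt, ti, "coll_clade", stem)
    Bt = _balanced(beetles, tt, ti, "beetle_clade", stem)
    newick = (
        f"(({bact[0]}:{tt * 2},{bact[1]}:{tt * 2})bacteria:{stem},"
        f"({A},({B},({C},({M},({D},({S},{Bt})n1:{bb})n2:{bb})n3:{bb})"
        f"n4:{bb})n5:{bb})ingroup:{stem});"
    )
    # scale branch lengths so the mean root-to-leaf depth hits mean_depth
    tree = read_newick(newick)
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    factor = mean_depth / (sum(depths) / len(depths))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = round(edge.length * factor, 6)
    scaled = tree.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True)

    lineage = {}
    for leaf in bact:
        lineage[leaf] = ("Bacteria",)
    for leaf, order in [(x, "Saccharomycetales_A") for x in fA] + \
                       [(x, "Saccharomycetales_B") for x in fB] + \
                       [(x, "Neocallimastigaceae") for x in fC] + \
                       [(x, "Sordariales") for x in fD]:
        lineage[leaf] = ("Fungi", order)
    for leaf in mites:
        lineage[leaf] = ("Arthropoda", "Oribatida")
    for leaf in springtails:
        lineage[leaf] = ("Arthropoda", "Collembola")
    for leaf in beetles:
        lineage[leaf] = ("Arthropoda", "Phytophaga")

    # beetle function labels mirror the assayed diversity: cellulases,
    # both xyloglucanase routes, and both inactivation routes
    function_labels = {}
    keys = ["glucanase", "glucanase", "xyloglucanase_stabilizer",
            "xyloglucanase_acid", "inactive_dyad", "inactive_ala"]
    for i, leaf in enumerate(beetles):
        function_labels[leaf] = keys[i % len(keys)]

    return ScenarioConfig(
        guide_tree=scaled,
        lineage=lineage,
        hgt_events=[("donor_clade", "beetle_clade")],
        function_labels=function_labels,
        ancestral_intron=(5, 1, "beetle_clade"),
        extra_intron_rate=0.5,
        subst_rate=1.0,
        seq_length=200,
        signal_peptide_len=16,
        seed=seed,
    )


def intron_scenario(seed: int = 0) -> ScenarioConfig:
    """A 14-species, one-gene-per-species family for intron conservation.

    Ten species form a clade inheriting one ancestral phase-1 intron
    anchored at codon 5 (inside the 16-residue signal peptide); the other
    four lie outside it.  Extra lineage-specific introns arise along
    branches at a per-branch rate, always outside the signal peptide.
    """
    ingroup = [f"sp{i}" for i in range(1, 11)]
    others = [f"out{i}" for i in range(1, 5)]
    tt, ti, stem = 0.08, 0.03, 0.05
    newick = (
        f"({_balanced(others, tt, ti, 'outer', stem)},"
        f"{_balanced(ingroup, tt, ti, 'carrier_clade', stem)});"
    )
    lineage = {leaf: ("Phytophaga", "carrier") for leaf in ingroup}
    lineage.update({leaf: ("Phytophaga", "other") for leaf in others})
    return ScenarioConfig(
        guide_tree=newick,
        lineage=lineage,
        ancestral_intron=(5, 1, "carrier_clade"),
        extra_intron_rate=2.0,
        subst_rate=1.0,
        seq_length=200,
        signal_peptide_len=16,
        seed=seed,
    )
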