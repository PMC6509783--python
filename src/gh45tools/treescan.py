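"""Tree-level reasoning on gene trees: monophyly, origins, sister clades.

The questions answered here are the ones a horizontal-gene-transfer screen
asks of a gene tree: does a taxon group form a single clade (a bipartition
of the unrooted tree), how many independent origins does the group have
once the tree is rooted on an outgroup, and what is the taxonomic makeup of
a monophyletic group's sister clade (an HGT recipient's sister is dominated
by the donor lineage)?  A deterministic neighbor-joining builder is included
so synthetic scenarios need no external inference tool.

Support values: Newick internal-node labels are parsed as support when
numeric; posterior probabilities (<= 1) and bootstrap percentages (<= 100)
are both accepted, with the scale auto-detected per tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed trees or invalid group/outgroup queries."""


@dataclass
class CladeReport:
    """Summary of one taxon group's placement on a gene tree."""

    group_label: str
    is_monophyletic: bool
    support: float | None
    support_scale: str | None          # 'pp' | 'bootstrap' | None
    n_origins: int | None = None
    origin_subtrees: list[frozenset[str]] = field(default_factory=list)
    sister_composition: dict[str, int] = field(default_factory=dict)
    sister_support: float | None = None

    def to_dict(self) -> dict:
        return {
            "group": self.group_label,
            "is_monophyletic": self.is_monophyletic,
            "support": self.support,
            "support_scale": self.support_scale,
            "n_origins": self.n_origins,
            "origin_subtrees": [sorted(s) for s in self.origin_subtrees],
            "sister_composition": dict(self.sister_composition),
            "sister_support": self.sister_support,
        }


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick from a path or a literal string.

    Internal node labels are kept as raw labels; use ``node_support`` to
    interpret them as support values.
    """
    text = str(source)
    if "(" not in text:  # a path, not a newick literal
        try:
            text = Path(source).read_text()
        except OSError as exc:
            raise TreeError(f"cannot read tree from {source!r}: {exc}")
    elif isinstance(source, Path):
        text = source.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise TreeError(f"duplicate leaf ids in tree: {exc}") from exc
        raise
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise TreeError(f"duplicate leaf id {dup!r} in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)


def support_scale(tree: dendropy.Tree) -> str | None:
    """'bootstrap' if any numeric internal label exceeds 1, else 'pp'."""
    values = []
    for nd in tree.preorder_internal_node_iter():
        if nd.label is not None:
            try:
                values.append(float(nd.label))
            except ValueError:
                continue
    if not values:
        return None
    return "bootstrap" if max(values) > 1 else "pp"


def node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Monophyly / origins / sister composition
# ---------------------------------------------------------------------------

def _leafset(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())

def _check_group(tree: dendropy.Tree, group) -> frozenset[str]:
    group = frozenset(group)
    if not group:
        raise TreeError("group must be non-empty")
    leaves = _leafset(tree)
    unknown = group - leaves
    if unknown:
        raise TreeError(f"unknown leaf ids: {sorted(unknown)}")
    return group


def _node_leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = frozenset([nd.taxon.label])
        else:
            sets[nd] = frozenset().union(*(sets[c] for c in
                                           nd.child_nodes()))
    return sets


def is_monophyletic(tree: dendropy.Tree, group,
                    rooted: bool = False) -> tuple[bool, float | None]:
    """Does ``group`` form a clade (rooted) or a bipartition (unrooted)?

    Returns the verdict and the support of the defining branch (None when
    the branch carries no numeric label, or for trivial single-leaf groups).
    """
    group = _check_group(tree, group)
    leaves = _leafset(tree)
    if len(group) == 1 or (not rooted and group == leaves):
        return True, None
    sets = _node_leafsets(tree)
    for nd, ls in sets.items():
        if nd.parent_node is None:
            continue
        if ls == group or (not rooted and leaves - ls == group):
            return True, node_support(nd)
    if rooted and sets[tree.seed_node] == group:
        return True, node_support(tree.seed_node)
    return False, None


def root_on_outgroup(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Return a copy rooted on the edge separating the outgroup.

    The outgroup must be a leaf or a set of leaves forming one side of a
    branch of the unrooted tree.
    """
    outgroup = _check_group(tree, outgroup)
    rooted = tree.clone(depth=1)
    sets = _node_leafsets(rooted)
    leaves = _leafset(rooted)
    if outgroup == leaves:
        raise TreeError("outgroup cannot contain every leaf")
    target = None
    for nd, ls in sets.items():
        if nd.parent_node is None:
            continue
        if ls == outgroup:
            target = nd
            break
        if leaves - ls == outgroup:
            # outgroup is the complement side: root on the same edge
            target = nd
            break
    if target is None:
        raise TreeError(
            "outgroup does not correspond to a branch of the tree"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half,
                          update_bipartitions=False)
    return rooted


def count_origins(tree: dendropy.Tree, group, outgroup,
                  ) -> tuple[int, list[frozenset[str]]]:
    """Number of maximal subtrees whose leaves all belong to ``group``.

    The tree is rooted on the outgroup first.  A monophyletic group has one
    origin; a group scattered across k maximal clades has k.
    """
    group = _check_group(tree, group)
    outgroup = _check_group(tree, outgroup)
    if group & outgroup:
        raise TreeError(
            f"group and outgroup overlap: {sorted(group & outgroup)}"
        )
    rooted = root_on_outgroup(tree, outgroup)
    sets = _node_leafsets(rooted)

    origins: list[frozenset[str]] = []

    def visit(nd):
        ls = sets[nd]
        if not (ls & group):
            return
        if ls <= group:
            origins.append(ls)
            return
        for c in nd.child_nodes():
            visit(c)

    visit(rooted.seed_node)
    return len(origins), origins


def sister_composition(tree: dendropy.Tree, group,
                       lineage: Mapping[str, str] | None = None,
                       outgroup=None,
                       ) -> tuple[dict[str, int], float | None]:
    """Lineage histogram of the sister clade of a monophyletic group.

    ``lineage`` maps leaf id to the label counted (e.g. a kingdom or order
    label); unmapped leaves count under 'unknown'.  When ``outgroup`` is
    given the tree is rooted on it first; otherwise the tree's existing
    rooting is used.  Raises if the group is not monophyletic under that
    rooting.
    """
    group = _check_group(tree, group)
    rooted = root_on_outgroup(tree, outgroup) if outgroup is not None else tree
    sets = _node_leafsets(rooted)
    target = None
    for nd, ls in sets.items():
        if ls == group:
            target = nd
            break
    if target is None or target.parent_node is None:
        raise TreeError("group is not a (proper) monophyletic clade under "
                        "this rooting")
    sisters: set[str] = set()
    for sib in target.parent_node.child_nodes():
        if sib is not target:
            sisters |= sets[sib]
    hist = Counter(
        (lineage or {}).get(leaf, "unknown") if lineage is not None else leaf
        for leaf in sisters
    )
    return dict(hist), node_support(target)


def clade_report(tree: dendropy.Tree, group_label: str, group,
                 lineage: Mapping[str, str] | None = None,
                 outgroup=None) -> CladeReport:
    """Full report: unrooted monophyly + (with an outgroup) origins/sister."""
    group = _check_group(tree, group)
    mono, supp = is_monophyletic(tree, group, rooted=False)
    report = CladeReport(
        group_label=group_label,
        is_monophyletic=mono,
        support=supp,
        support_scale=support_scale(tree),
    )
    if outgroup is not None:
        n, subtrees = count_origins(tree, group, outgroup)
        report.n_origins = n
        report.origin_subtrees = subtrees
        if mono:
            comp, ssup = sister_composition(tree, group, lineage, outgroup)
            report.sister_composition = comp
            report.sister_support = ssup
    elif mono:
        report.n_origins = 1
    return report


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: Sequence[str], dist: np.ndarray) -> dendropy.Tree:
    """Classic neighbor joining (Saitou-Nei, Studier-Keppler Q-criterion).

    Deterministic: Q-ties are broken by the smallest (i, j) pair in the
    current agglomeration ordering.  Returns an unrooted tree (trifurcating
    seed node).  Branch lengths follow the standard formulas and may be
    negative for non-additive input.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if len(set(labels)) != n:
        raise TreeError("duplicate labels")
    if dist.shape != (n, n):
        raise TreeError(f"distance matrix shape {dist.shape} != ({n}, {n})")
    if n < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")
    if not np.allclose(dist, dist.T):
        raise TreeError("distance matrix is not symmetric")
    if np.any(np.diag(dist) != 0):
        raise TreeError("distance matrix diagonal must be zero")
    if np.any(dist < 0):
        raise TreeError("negative off-diagonal distances")

    tree = dendropy.Tree()
    tns = dendropy.TaxonNamespace()
    tree.taxon_namespace = tns
    nodes = []
    for lab in labels:
        taxon = dendropy.Taxon(label=lab)
        tns.add_taxon(taxon)
        nodes.append(dendropy.Node(taxon=taxon))

    active = list(range(n))
    d = dist.copy()

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) position pair
        best = np.argwhere(q == q.min())
        # q can be microscopically asymmetric (float summation order), so
        # normalise each hit to an ordered pair before tie-breaking
        ai, aj = min((min(int(x), int(y)), max(int(x), int(y)))
                     for x, y in best)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2 + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = (d[i, ak] + d[j, ak] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # closed-form three-taxon lengths
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    center = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = ln
        center.add_child(nodes[idx])
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def nj_from_alignment(aln) -> dendropy.Tree:
    """NJ tree from the p-distance matrix of an alignment."""
    from .seqmodel import p_distance_matrix

    labels, d = p_distance_matrix(aln)
    return nj_tree(labels, d)
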