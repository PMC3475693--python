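"""Neighbor-joining trees, bootstrap support and outgroup rooting.

NJ follows Saitou & Nei with the Studier-Keppler Q-criterion and a
deterministic lowest-index tie-break; trees are dendropy objects, so
newick I/O and bipartition bookkeeping come for free.  Bootstrap support
is mapped onto the point-estimate tree's bipartitions (the way published
NJ figures display it), not onto a consensus tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core_io import Alignment, SequenceRecord
from .evodistance import distance_matrix

__all__ = [
    "PhylogenyError",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "concatenate_alignments",
    "tree_to_newick",
    "tree_from_newick",
]


class PhylogenyError(ValueError):
    pass


def _validate_matrix(dm: pd.DataFrame) -> np.ndarray:
    mat = dm.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] < 3:
        raise PhylogenyError("need a square matrix over >= 3 taxa")
    if np.any(np.isnan(mat)):
        raise PhylogenyError("distance matrix contains undefined entries")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise PhylogenyError("distance matrix is not symmetric (tol 1e-9)")
    if np.any(np.abs(np.diag(mat)) > 1e-12):
        raise PhylogenyError("diagonal must be zero")
    return mat


def neighbor_joining(dm: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a labeled distance matrix.

    Negative branch-length estimates are clamped to zero; the number of
    clamped edges is stored in ``tree.n_clamped``.  The returned tree is
    unrooted (trifurcating "root" node).
    """
    mat = _validate_matrix(dm)
    labels = [str(x) for x in dm.index]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    active = list(range(len(labels)))
    D = mat.copy()
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node (row i is reused for the parent)
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        active.remove(j)
    # final join: the three remaining nodes meet at a trifurcation with
    # closed-form branch lengths
    i, j, k = active
    root = dendropy.Node()
    nodes[i].edge.length = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].edge.length = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].edge.length = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    root.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    tree.n_clamped = n_clamped
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.head_node.is_leaf():
            continue
        out.add(edge.bipartition.split_bitmask)
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree  # point-estimate tree with support on internal nodes
    n_replicates: int
    n_dropped: int  # replicates with undefined distances
    degenerate: bool  # alignment had no variation; supports reported as 0


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = 1000,
    distance_kind: str = "k2p",
    seed: int = 0,
) -> BootstrapResult:
    """Column-resampling bootstrap; support = % of replicates containing
    each internal bipartition of the point-estimate tree."""
    if n_replicates < 1:
        raise PhylogenyError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    dm = distance_matrix(aln, kind=distance_kind)
    if np.isnan(dm.to_numpy()).any():
        raise PhylogenyError("point-estimate distances undefined (saturation)")
    tree = neighbor_joining(dm)
    degenerate = not np.any(dm.to_numpy() > 0)
    counts: dict[int, int] = {b: 0 for b in _bipartitions(tree)}
    n_cols = aln.n_columns
    arr = np.array([list(r.residues) for r in aln.records])
    dropped = 0
    if not degenerate:
        for _ in range(n_replicates):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep = Alignment(
                [
                    SequenceRecord(id=r.id, residues="".join(arr[k][cols]))
                    for k, r in enumerate(aln.records)
                ]
            )
            rep_dm = distance_matrix(rep, kind=distance_kind)
            if np.isnan(rep_dm.to_numpy()).any():
                dropped += 1
                continue
            rep_bip = _bipartitions(neighbor_joining(rep_dm))
            for b in counts:
                if b in rep_bip:
                    counts[b] += 1
    else:
        warnings.warn("alignment has no variation; supports reported as 0")
    used = n_replicates - dropped
    if dropped:
        warnings.warn(f"{dropped} bootstrap replicate(s) dropped (undefined distances)")
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        b = edge.bipartition.split_bitmask
        support = 100.0 * counts.get(b, 0) / used if (used and not degenerate) else 0.0
        node.label = f"{support:.0f}"
    return BootstrapResult(
        tree=tree, n_replicates=n_replicates, n_dropped=dropped, degenerate=degenerate
    )


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the ingroup."""
    outgroup = set(outgroup_labels)
    taxa = {t.label for t in tree.taxon_namespace}
    missing = outgroup - taxa
    if missing:
        raise PhylogenyError(f"outgroup label(s) not in tree: {sorted(missing)}")
    rooted = tree.clone(depth=1)
    # find the edge whose leaf-side set equals the outgroup
    for edge in rooted.preorder_edge_iter():
        node = edge.head_node
        if node is rooted.seed_node:
            continue
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade == outgroup or (taxa - clade) == outgroup:
            length = edge.length or 0.0
            rooted.reroot_at_edge(edge, length1=length / 2, length2=length / 2)
            rooted.is_rooted = True
            return rooted
    raise PhylogenyError(
        f"outgroup {sorted(outgroup)} is not monophyletic in the tree; "
        "no edge induces that bipartition"
    )


def concatenate_alignments(alignments, policy: str = "fill") -> Alignment:
    """Column-wise concatenation of alignment blocks by taxon id.

    ``policy='fill'`` pads taxa missing from a block with gaps;
    ``policy='intersect'`` keeps only taxa present in every block.
    """
    if policy not in ("fill", "intersect"):
        raise PhylogenyError("policy must be 'fill' or 'intersect'")
    alignments = list(alignments)
    if not alignments:
        raise PhylogenyError("no alignments to concatenate")
    if policy == "intersect":
        taxa: list[str] = [
            t for t in alignments[0].ids
            if all(t in a.ids for a in alignments)
        ]
        if not taxa:
            raise PhylogenyError("no taxa shared by all blocks")
    else:
        taxa = []
        for a in alignments:
            for t in a.ids:
                if t not in taxa:
                    taxa.append(t)
    rows = {t: [] for t in taxa}
    for a in alignments:
        ids = set(a.ids)
        for t in taxa:
            rows[t].append(a[t].residues if t in ids else "-" * a.n_columns)
    return Alignment(
        [SequenceRecord(id=t, residues="".join(parts)) for t, parts in rows.items()]
    )


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")
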