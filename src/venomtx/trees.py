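"""Newick tree utilities: parsing, midpoint rooting, clade extraction.

Built on dendropy.  Midpoint rooting places the root halfway along the
longest leaf-to-leaf path, the convention used to present otherwise
unrooted toxin phylogenies; clade extraction returns the subtree under
the most recent common ancestor of a (monophyletic) leaf set.
"""
from __future__ import annotations

import dendropy

PhyloTree = dendropy.Tree


class NewickParseError(ValueError):
    pass


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a tree (underscores preserved)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize to a canonical single-line Newick string."""
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: PhyloTree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def root_to_leaf_distances(tree: PhyloTree) -> dict[str, float]:
    """Path length from the root to every leaf."""
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        dist = 0.0
        node = leaf
        while node.parent_node is not None:
            dist += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = dist
    return out


def _pairwise_leaf_distances(tree: PhyloTree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root a copy of the tree at the midpoint of its longest leaf-leaf path."""
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    rooted = tree.clone(depth=1)
    dists = _pairwise_leaf_distances(rooted)
    if not dists or max(dists.values()) <= 0:
        raise ValueError("longest leaf-to-leaf path has zero length")
    rooted.reroot_at_midpoint(update_bipartitions=True)
    return rooted


def extract_clade(tree: PhyloTree, leaves: set[str]) -> PhyloTree:
    """Subtree induced by the MRCA of ``leaves``.

    Raises ``ValueError`` naming the intruding leaves if the set is not
    monophyletic in the rooted tree.
    """
    leaves = set(leaves)
    tree.is_rooted = True  # clade membership is read off the rooted shape
    known = set(leaf_labels(tree))
    missing = leaves - known
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    mrca = tree.mrca(taxon_labels=leaves)
    under = {l.taxon.label for l in mrca.leaf_iter()}
    intruders = under - leaves
    if intruders:
        raise ValueError(
            f"leaf set is not monophyletic; clade also contains {sorted(intruders)}"
        )
    # pruning to the leaf set and suppressing unifurcations leaves exactly
    # the subtree under the MRCA
    clade = tree.extract_tree_with_taxa_labels(labels=leaves)
    return clade
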