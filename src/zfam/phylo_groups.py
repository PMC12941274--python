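"""Outgroup rooting and anchor-based clade grouping.

Family trees are consumed as newick files (inference is external).  The
tree is rooted on the branch subtending a named outgroup leaf, and each
named group is defined reproducibly as the leaf set of the smallest clade
(MRCA clade) containing all of the group's anchor leaves — a deterministic
surrogate for manual clade delineation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


@dataclass(frozen=True)
class GroupAssignment:
    #: leaf -> group label (unassigned leaves absent)
    leaf_group: dict[str, str]
    #: group -> (anchor leaves, clade size)
    groups: dict[str, tuple[frozenset[str], int]]


def read_tree(path_or_string: str, from_string: bool = False) -> dendropy.Tree:
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        # trees here are clade diagrams: keep the written nesting intact
        rooting="default-rooted",
    )
    if from_string:
        return dendropy.Tree.get(data=path_or_string, **kwargs)
    return dendropy.Tree.get(path=path_or_string, **kwargs)


def _leaf_nodes(tree: dendropy.Tree, label: str) -> list[dendropy.Node]:
    return [
        nd for nd in tree.leaf_node_iter()
        if nd.taxon is not None and nd.taxon.label == label
    ]


def reroot_at_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Root the tree on the branch subtending the named outgroup leaf.

    The leaf must exist and be unique; internal node labels are not
    accepted.  All non-root bipartitions are preserved.
    """
    internal = [
        nd for nd in tree.preorder_internal_node_iter()
        if nd.taxon is not None and nd.taxon.label == outgroup_leaf
    ]
    if internal:
        raise ValueError(f"{outgroup_leaf!r} names an internal node, not a leaf")
    matches = _leaf_nodes(tree, outgroup_leaf)
    if not matches:
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not found in tree")
    if len(matches) > 1:
        raise ValueError(f"outgroup leaf name {outgroup_leaf!r} is ambiguous")
    rooted = tree.clone(depth=1)
    node = _leaf_nodes(rooted, outgroup_leaf)[0]
    # split the outgroup's subtending branch with a new bifurcating root
    length = node.edge.length
    rooted.reroot_at_edge(
        node.edge,
        length1=None if length is None else length / 2,
        length2=None if length is None else length / 2,
        update_bipartitions=True,
    )
    rooted.is_rooted = True
    return rooted


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """The multiset of non-trivial leaf-set splits, as frozensets of the
    smaller side's labels (rotation-independent comparison aid)."""
    all_leaves = frozenset(
        nd.taxon.label for nd in tree.leaf_node_iter() if nd.taxon is not None
    )
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_internal_node_iter():
        clade = frozenset(
            lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
        )
        if 1 < len(clade) < len(all_leaves):
            other = all_leaves - clade
            out.add(clade if len(clade) <= len(other) else other)
    return out


def assign_groups(
    tree: dendropy.Tree, anchors: dict[str, set[str]]
) -> GroupAssignment:
    """Each group = leaf set of the MRCA clade of its anchors.

    Anchor sets must be non-empty and disjoint; overlapping MRCA clades
    are an error (the grouping would be ambiguous).
    """
    seen: dict[str, str] = {}
    for group, aset in anchors.items():
        if not aset:
            raise ValueError(f"group {group!r} has an empty anchor set")
        for a in aset:
            if a in seen:
                raise ValueError(
                    f"anchor {a!r} appears in both {seen[a]!r} and {group!r}"
                )
            seen[a] = group
    taxon_labels = {
        nd.taxon.label for nd in tree.leaf_node_iter() if nd.taxon is not None
    }
    clades: dict[str, frozenset[str]] = {}
    for group, aset in sorted(anchors.items()):
        missing = sorted(aset - taxon_labels)
        if missing:
            raise ValueError(f"group {group!r}: anchors absent from tree: {missing}")
        if len(aset) == 1:
            clades[group] = frozenset(aset)
            continue
        mrca = tree.mrca(taxon_labels=sorted(aset))
        clades[group] = frozenset(
            lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon is not None
        )
    groups = sorted(clades)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            if clades[g1] & clades[g2]:
                raise ValueError(
                    f"groups {g1!r} and {g2!r} resolve to overlapping clades"
                )
    leaf_group = {}
    for group in groups:
        for leaf in clades[group]:
            leaf_group[leaf] = group
    return GroupAssignment(
        leaf_group=leaf_group,
        groups={g: (frozenset(anchors[g]), len(clades[g])) for g in groups},
    )


def group_composition(
    assignment: GroupAssignment, species_of: dict[str, str]
) -> dict[str, dict[str, int]]:
    """Per-group species counts (e.g. to show a clade is dominated by one
    taxon)."""
    out: dict[str, dict[str, int]] = {g: {} for g in assignment.groups}
    for leaf, group in assignment.leaf_group.items():
        sp = species_of.get(leaf, "unknown")
        out[group][sp] = out[group].get(sp, 0) + 1
    return out
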