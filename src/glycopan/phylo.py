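"""Species-tree operations: Newick I/O, rooting, clade filtering, and
minimum gain/loss counting for binary pathway characters.

Trees are :class:`dendropy.Tree` objects read in the FastTree dialect
(support values stored as internal node labels). Gain/loss counting uses
small parsimony: the minimum number of state changes over all ancestral
labelings, generalized to multifurcating nodes with Hartigan-style
majority sets, so FastTree polytomies need no arbitrary resolution.
Gains and losses are counted jointly (no root-state prior, no
gain/loss asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "root_with_outgroup",
    "clade_filter",
    "fitch_changes",
    "summarize_events",
    "bipartition_supports",
    "node_support",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate leaves...)."""


def read_newick(source) -> dendropy.Tree:
    """Read one Newick tree from a path or string.

    Internal node labels (FastTree support dialect) are preserved on
    ``node.label``. Raises :class:`NewickError` on syntax errors or
    duplicate leaf labels.
    """
    try:
        if isinstance(source, str) and ("(" in source or ";" in source):
            tree = dendropy.Tree.get(
                data=source, schema="newick",
                suppress_internal_node_taxa=True,
            )
        else:
            tree = dendropy.Tree.get(
                path=source, schema="newick",
                suppress_internal_node_taxa=True,
            )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick input: {exc}") from exc
    labels = leaf_labels(tree)
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, keeping supports-as-labels and lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    raise KeyError(f"leaf {label!r} not found in tree")


def root_with_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Root (in place) so the root separates the outgroup from all others.

    Re-rooting an already-correctly-rooted tree is a no-op topologically,
    so the operation is idempotent. Returns the tree for chaining.
    """
    leaf = _find_leaf(tree, outgroup_leaf)
    tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def clade_filter(tree: dendropy.Tree, ref_a: str, ref_b: str) -> set[str]:
    """Leaves descending from the LCA of two reference leaves.

    Used to discard genomes falling outside the taxonomic framework
    anchored by two named reference genomes on the rooted marker tree.
    """
    for ref in (ref_a, ref_b):
        _find_leaf(tree, ref)  # raises KeyError when missing
    taxa = [t for t in tree.taxon_namespace if t.label in (ref_a, ref_b)]
    tree.is_rooted = True  # MRCA is only meaningful on a rooted tree
    mrca = tree.mrca(taxa=taxa)
    return {lf.taxon.label for lf in mrca.leaf_iter()}


# ---------------------------------------------------------------------------
# Small parsimony
# ---------------------------------------------------------------------------

def fitch_changes(tree: dendropy.Tree, character: Mapping[str, int]) -> int:
    """Minimum number of state changes explaining a binary character.

    Bottom-up pass assigning each internal node the set of states held by
    the largest number of its children (Hartigan majority sets); each node
    contributes (number of children) - (majority count) changes. On
    bifurcating trees this reduces to classical Fitch counting; on
    multifurcations it still attains the true minimum over all ancestral
    labelings. The count is invariant to root placement.
    """
    changes = 0
    state_sets: dict[dendropy.Node, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in character:
                raise KeyError(f"leaf {label!r} has no character state")
            state = int(character[label])
            if state not in (0, 1):
                raise ValueError(f"leaf {label!r}: state {state} not binary")
            state_sets[node] = frozenset((state,))
        else:
            children = node.child_nodes()
            counts = {0: 0, 1: 0}
            for ch in children:
                for s in state_sets[ch]:
                    counts[s] += 1
            best = max(counts.values())
            state_sets[node] = frozenset(s for s, c in counts.items() if c == best)
            changes += len(children) - best
    return changes


def summarize_events(
    counts: Mapping[str, float], labels: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Per-group median and interquartile range of event counts.

    ``labels`` maps each character id to its group (e.g. core/accessory).
    Quartiles use linear interpolation, the convention under which values
    like 11.75 arise from integer counts.
    """
    groups: dict[str, list[float]] = {}
    for key, value in counts.items():
        if key not in labels:
            raise KeyError(f"no group label for {key!r}")
        groups.setdefault(labels[key], []).append(float(value))
    out = {}
    for name, vals in sorted(groups.items()):
        if not vals:
            raise ValueError(f"group {name!r} is empty")
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[name] = {"n": len(vals), "median": float(med),
                     "q1": float(q1), "q3": float(q3)}
    return out


# ---------------------------------------------------------------------------
# Branch supports
# ---------------------------------------------------------------------------

def node_support(node: dendropy.Node) -> float | None:
    """Support value of an internal node's subtending edge, if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def bipartition_supports(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each internal edge's bipartition to its support value.

    Both leaf-set sides of every supported internal edge are keys, so
    lookups are root-invariant. Built from the tree as read, before any
    re-rooting, which keeps support-edge association intact.
    """
    all_leaves = frozenset(leaf_labels(tree))
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out[side] = sup
        out[all_leaves - side] = sup
    return out
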