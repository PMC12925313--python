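"""Monophyly scoring of target sequences within gene-family trees.

The monophyly score of a target leaf set is the size of the largest
clade composed exclusively of target leaves, divided by the number of
targets: 1 means perfect monophyly, values near 1/|targets| mean the
targets are maximally scattered. "Clade" is taken in the rooting-
invariant sense — each side of each bipartition of the unrooted
topology — so the score does not depend on where FastTree happened to
root the tree. Clades containing any non-target leaf never count, even
if target-dominated.

Families whose last-common-ancestor node has branch support below a
threshold (default 80%) carry unreliable phylogenetic signal and are
flagged excluded; the score is still computed and reported.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from .phylo import bipartition_supports, leaf_labels, summarize_events

__all__ = [
    "MonophylyResult",
    "monophyly_score",
    "lca_support",
    "score_family",
    "summarize_monophyly",
]


@dataclass(frozen=True)
class MonophylyResult:
    family_id: str
    score: float
    lca_support: float | None  # on the fractional [0,1] scale
    included: bool


def _check_targets(tree: dendropy.Tree, targets: Iterable[str]) -> frozenset[str]:
    tset = frozenset(targets)
    if not tset:
        raise ValueError("target set is empty")
    leaves = set(leaf_labels(tree))
    missing = tset - leaves
    if missing:
        raise KeyError(f"targets absent from tree: {sorted(missing)}")
    return tset


def monophyly_score(tree: dendropy.Tree, targets: Iterable[str]) -> float:
    """Largest all-target bipartition side / number of targets.

    Always in [1/|targets|, 1]: a single leaf is itself a clade. Equals 1
    iff the full target set forms a clade of the unrooted topology.
    """
    tset = _check_targets(tree, targets)
    all_leaves = frozenset(leaf_labels(tree))
    best = 1  # any single target leaf is a valid one-leaf clade
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for candidate in (side, all_leaves - side):
            if candidate and candidate <= tset and len(candidate) > best:
                best = len(candidate)
    return best / len(tset)


def lca_support(
    tree: dendropy.Tree,
    targets: Iterable[str],
    rooting: str = "midpoint",
) -> float | None:
    """Branch support of the targets' last common ancestor, or None.

    When the targets are monophyletic the separating bipartition's
    support is used directly (independent of rooting). Otherwise the
    tree is rooted (``midpoint`` by default, ``as-read`` to keep the
    input rooting), the LCA located, and its subtending edge's support
    looked up on the original topology. Returns None when the LCA is
    the root (no subtending edge) or the edge carries no support value.
    """
    tset = _check_targets(tree, targets)
    supports = bipartition_supports(tree)
    all_leaves = frozenset(leaf_labels(tree))
    if tset == all_leaves:
        return None
    if tset in supports or _is_clade(tree, tset):
        return supports.get(tset)

    work = copy.deepcopy(tree)
    if rooting == "midpoint":
        try:
            work.reroot_at_midpoint(update_bipartitions=False)
        except (ValueError, ZeroDivisionError, AttributeError):
            pass  # no usable branch lengths: keep rooting as read
    elif rooting != "as-read":
        raise ValueError(f"unknown rooting mode {rooting!r}")
    work.is_rooted = True
    taxa = [t for t in work.taxon_namespace if t.label in tset]
    mrca = work.mrca(taxa=taxa)
    if mrca is work.seed_node or mrca.parent_node is None:
        return None
    side = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
    return supports.get(side)


def _is_clade(tree: dendropy.Tree, tset: frozenset[str]) -> bool:
    all_leaves = frozenset(leaf_labels(tree))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if side == tset or all_leaves - side == tset:
            return True
    return False


def _support_scale(tree: dendropy.Tree) -> float:
    """Auto-detect support scale: values > 1 anywhere imply percentages."""
    from .phylo import node_support

    for node in tree.preorder_node_iter():
        sup = node_support(node)
        if sup is not None and sup > 1.0:
            return 100.0
    return 1.0


def score_family(
    tree: dendropy.Tree,
    targets: Iterable[str],
    family_id: str = "",
    support_threshold: float = 0.8,
    rooting: str = "midpoint",
) -> MonophylyResult:
    """Score one gene family and apply the LCA-support inclusion filter.

    ``support_threshold`` is on the fractional scale; tree supports on a
    0-100 scale are detected and rescaled automatically. A family whose
    LCA support is below the threshold (strict), undefined, or whose LCA
    is the tree root, is marked excluded. Targets spanning every leaf
    (no background sequences) are uninformative and excluded.
    """
    tset = _check_targets(tree, targets)
    scale = _support_scale(tree)
    score = monophyly_score(tree, tset)
    raw = lca_support(tree, tset, rooting=rooting)
    sup = None if raw is None else raw / scale
    included = sup is not None and sup >= support_threshold
    if tset == frozenset(leaf_labels(tree)):
        included = False
    return MonophylyResult(
        family_id=family_id, score=score, lca_support=sup, included=included
    )


def summarize_monophyly(
    results: Iterable[MonophylyResult], labels: Mapping[str, str]
) -> dict[str, dict[str, float]]:
    """Median and IQR of monophyly scores per core/accessory group,
    restricted to included families."""
    scores = {r.family_id: r.score for r in results if r.included}
    if not scores:
        raise ValueError("no included families to summarize")
    return summarize_events(scores, labels)
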