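"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately written against naive enumeration (itertools, pure-python
statistics, dendropy bitmasks) rather than the package's own algorithms,
so each check is a genuine dual-route comparison.
"""

import itertools
import statistics
from itertools import combinations

from glycopan import phylo


def brute_force_changes(tree, character):
    """Minimum state changes over all internal-node labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for labels in itertools.product([0, 1], repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), labels))
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = character[leaf.taxon.label]
        changes = sum(
            assign[id(n)] != assign[id(n.parent_node)]
            for n in tree.preorder_node_iter() if n.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best


def bipartition_monophyly(tree, targets):
    """Largest all-target bipartition side via dendropy bitmask encoding."""
    tree = phylo.read_newick(phylo.write_newick(tree))  # fresh copy
    tree.encode_bipartitions()
    taxa = {t.label: tree.taxon_namespace.taxon_bitmask(t)
            for t in tree.taxon_namespace}
    full = tree.taxon_namespace.all_taxa_bitmask()
    target_mask = 0
    for lbl in targets:
        target_mask |= taxa[lbl]
    best = 1
    for edge in tree.preorder_edge_iter():
        mask = edge.split_bitmask
        for side in (mask & full, ~mask & full):
            if side and (side | target_mask) == target_mask:
                best = max(best, bin(side).count("1"))
    return best / len(targets)


def enumeration_p_value(a, b):
    """Exact two-sided p: pure-python enumeration of all regroupings."""
    pooled = list(a) + list(b)
    na, n = len(a), len(a) + len(b)
    obs = abs(statistics.median(a) - statistics.median(b))
    hits = total = 0
    for combo in combinations(range(n), na):
        in_a = set(combo)
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(n) if i not in in_a]
        stat = abs(statistics.median(ga) - statistics.median(gb))
        hits += stat >= obs - 1e-12
        total += 1
    return hits / total


def enumerate_routes(reactions, sources, terminal_id):
    """All simple reaction routes ending in the terminal reaction.

    ``reactions``: list of (id, substrate, product). Pure recursive DFS
    over metabolites, independent of any graph library.
    """
    by_substrate = {}
    products = {rid: p for rid, _, p in reactions}
    for rid, s, p in reactions:
        by_substrate.setdefault(s, []).append((rid, p))
    target_met = products[terminal_id]
    routes = []

    def walk(met, seen_mets, path):
        if met == target_met:
            if path and path[-1] == terminal_id:
                routes.append(list(path))
            return
        for rid, nxt in by_substrate.get(met, []):
            if nxt in seen_mets:
                continue
            path.append(rid)
            walk(nxt, seen_mets | {nxt}, path)
            path.pop()

    for src in sources:
        walk(src, {src}, [])
    return routes
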