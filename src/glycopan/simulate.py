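"""Synthetic study generator with known ground truth.

Emulates the shape of a genus-level pangenome survey of nucleotide-sugar
biosynthesis: a marker-gene species tree over 61 genomes, a core set of
sugars present nearly everywhere (rare losses), an accessory set gained
and lost at high per-branch rates, linear biosynthetic pathways whose
genes leave HMMER-style evidence in per-genome domtblout files, gene
trees in which the genomes carrying a family are implanted as k
independent clades among background sequences, CheckM-style quality
records (including planted low-quality decoys), and a kingdom-wide
prevalence table drawn high for core and low for accessory sugars.

Everything is written in the exact text dialects the pipeline parses, so
a generated directory is a complete, self-contained study input. A
``truth.json`` records per-character event counts, implanted clade
sizes, and intended class labels, sufficient to recompute every expected
pipeline output. All randomness flows from one master seed through named
substreams, so each stage is independently reproducible.

Presence characters evolve root-to-tip with per-branch flip
probabilities (a CFN-style process, not rate x branch length): simple,
and sufficient to generate the polyphyletic patterns the analysis is
built to detect.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import phylo

__all__ = [
    "SimConfig",
    "simulate_species_tree",
    "simulate_character",
    "simulate_gene_tree",
    "simulate_dataset",
]

MARKER_FAMILY = "K00937"  # ppk1-style phylogenetic marker


@dataclass
class SimConfig:
    """Study-shaped generator settings.

    Defaults mirror the analysed study's dimensions: 61 curated genomes,
    9 core and 12 accessory sugars. Core pathways start present at the
    root and are lost rarely; accessory pathways start absent and churn.
    """

    n_taxa: int = 61
    n_core: int = 9
    n_accessory: int = 12
    core_loss_prob: float = 0.005
    accessory_gain_prob: float = 0.08
    accessory_loss_prob: float = 0.08
    steps_per_pathway: int = 3
    background_gene_presence_prob: float = 0.1  # stray genes off-pathway
    gene_tree_background: int = 40
    target_clade_count_range: tuple[int, int] = (2, 4)
    support_range: tuple[float, float] = (0.90, 1.0)
    n_decoy_genomes: int = 3  # fail the quality screen by construction
    kingdom_core_beta: tuple[float, float] = (8.0, 2.0)
    kingdom_accessory_beta: tuple[float, float] = (2.0, 8.0)
    kegg_threshold_fraction: float = 0.5  # families with curated bitscore cutoff
    seed: int = 0

    def validate(self) -> None:
        probs = (
            self.core_loss_prob, self.accessory_gain_prob,
            self.accessory_loss_prob, self.background_gene_presence_prob,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for name in ("n_taxa", "n_core", "n_accessory", "steps_per_pathway",
                     "gene_tree_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        lo, hi = self.target_clade_count_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid target_clade_count_range")


def _rng(seed: int, *stream: int | str) -> np.random.Generator:
    """Named substream of the master seed (stable across processes)."""
    tokens = [int(seed)]
    for s in stream:
        tokens.append(zlib.crc32(s.encode()) if isinstance(s, str) else int(s))
    return np.random.default_rng(tokens)


# ---------------------------------------------------------------------------
# Lightweight tree construction (emitted as Newick, reread via phylo)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children", "length", "support")

    def __init__(self, name=None, length=0.1):
        self.name = name
        self.children: list[_Node] = []
        self.length = length
        self.support: float | None = None

    def newick(self, root=True) -> str:
        if not self.children:
            body = self.name
        else:
            inner = ",".join(c.newick(root=False) for c in self.children)
            sup = "" if self.support is None else f"{self.support:.3f}"
            body = f"({inner}){sup}"
        if root:
            return body + ";"
        return f"{body}:{self.length:.6f}"


def _yule(labels: list[str], rng: np.random.Generator,
          support_range: tuple[float, float]) -> _Node:
    """Random bifurcating tree by uniform leaf splitting (Yule shape)."""
    root = _Node()
    leaves = [root]
    while len(leaves) < len(labels):
        i = int(rng.integers(len(leaves)))
        node = leaves.pop(i)
        for _ in range(2):
            child = _Node(length=float(rng.exponential(0.1)) + 1e-3)
            node.children.append(child)
            leaves.append(child)
        if node is not root:
            node.support = float(rng.uniform(*support_range))
    order = rng.permutation(len(labels))
    for leaf, j in zip(leaves, order):
        leaf.name = labels[int(j)]
    return root


def simulate_species_tree(n_taxa: int, seed: int,
                          support_range=(0.90, 1.0)) -> "dendropy.Tree":
    """Random bifurcating species tree with high branch supports."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = _rng(seed, "species-tree")
    labels = [f"G{i:03d}" for i in range(1, n_taxa + 1)]
    return phylo.read_newick(_yule(labels, rng, support_range).newick())


def simulate_character(
    tree, gain_prob: float, loss_prob: float, root_state: int,
    seed_or_rng,
) -> tuple[dict[str, int], dict]:
    """Evolve a binary character root-to-tip with per-branch flip chances.

    Returns the tip states and a truth record with every gain/loss event
    (child clade leaf sets), so the minimum attainable parsimony count
    can be bounded from the simulation itself.
    """
    for p in (gain_prob, loss_prob):
        if not (0.0 <= p <= 1.0):
            raise ValueError("flip probabilities must lie in [0, 1]")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else _rng(int(seed_or_rng), "character"))
    states: dict[int, int] = {}
    events: list[dict] = []
    character: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = int(root_state)
        else:
            parent = states[id(node.parent_node)]
            flip_p = loss_prob if parent == 1 else gain_prob
            if rng.random() < flip_p:
                state = 1 - parent
                events.append({
                    "type": "gain" if state == 1 else "loss",
                    "clade": sorted(
                        lf.taxon.label for lf in node.leaf_iter()
                    ),
                })
            else:
                state = parent
            states[id(node)] = state
        if node.is_leaf():
            character[node.taxon.label] = states[id(node)]
    return character, {"root_state": int(root_state),
                       "n_events": len(events), "events": events}


def simulate_gene_tree(
    family_id: str,
    targets: list[str],
    n_clades: int,
    n_background: int,
    rng: np.random.Generator,
    support_range=(0.90, 1.0),
) -> tuple[str, list[int]]:
    """Gene-family tree with targets implanted as ``n_clades`` clades.

    Background leaves (``BG###``) form a random scaffold; the target
    genomes are partitioned into clades, each grafted onto the pendant
    edge of a distinct background leaf. Graft points are drawn from one
    restricted neighbourhood of the scaffold (a subtree holding roughly
    a third to two thirds of the background), emulating how one genus's
    sequences occupy a region of a kingdom-wide family tree: the
    targets' last common ancestor is then a proper, supported internal
    node rather than the root. Because every graft point is a different
    pendant edge, no all-target bipartition larger than the biggest
    implanted clade can arise, so the construction's monophyly score is
    exactly max(sizes) / len(targets).

    Returns (newick string, implanted clade sizes).
    """
    if not targets:
        raise ValueError("no target leaves to implant")
    k = max(1, min(n_clades, len(targets), n_background))
    bg_labels = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    scaffold = _yule(bg_labels, rng, support_range)

    # partition targets into k non-empty groups
    shuffled = [targets[int(i)] for i in rng.permutation(len(targets))]
    cuts = sorted(rng.choice(np.arange(1, len(targets)), size=k - 1,
                             replace=False).tolist()) if k > 1 else []
    groups, prev = [], 0
    for c in cuts + [len(targets)]:
        groups.append(shuffled[prev:c])
        prev = c

    bg_leaves = _region_leaves(scaffold, k, n_background, rng)
    attach_at = rng.choice(len(bg_leaves), size=k, replace=False)
    for group, leaf_idx in zip(groups, attach_at):
        leaf = bg_leaves[int(leaf_idx)]
        clade = (_Node(group[0]) if len(group) == 1
                 else _yule(group, rng, support_range))
        clade.length = float(rng.exponential(0.1)) + 1e-3
        if clade.children:
            clade.support = float(rng.uniform(*support_range))
        # split the pendant edge: leaf becomes (old leaf, implanted clade)
        moved = _Node(leaf.name, length=leaf.length)
        leaf.name = None
        leaf.children = [moved, clade]
        leaf.support = float(rng.uniform(*support_range))
    sizes = sorted((len(g) for g in groups), reverse=True)
    return scaffold.newick(), sizes


def _region_leaves(scaffold: _Node, k: int, n_background: int,
                   rng: np.random.Generator) -> list[_Node]:
    """Leaves of one mid-sized subtree of the scaffold (graft region)."""
    lo = max(k, int(np.ceil(n_background / 3)))
    hi = max(lo, int(np.floor(2 * n_background / 3)))
    candidates = []

    def walk(node: _Node) -> int:
        if not node.children:
            return 1
        size = sum(walk(c) for c in node.children)
        if node is not scaffold and lo <= size <= hi:
            candidates.append(node)
        return size

    walk(scaffold)
    if not candidates:
        return list(_iter_leaves(scaffold))
    region = candidates[int(rng.integers(len(candidates)))]
    return list(_iter_leaves(region))


def _iter_leaves(node: _Node):
    if not node.children:
        yield node
    for c in node.children:
        yield from _iter_leaves(c)


# ---------------------------------------------------------------------------
# domtblout emission
# ---------------------------------------------------------------------------

_QLEN = 200


def _domtbl_line(orf: str, family: str, score: float, evalue: float,
                 hmm_from: int, hmm_to: int) -> str:
    fields = [
        orf, "-", "350", family, "-", str(_QLEN),
        f"{evalue:.2g}", f"{score:.1f}", "0.1",
        "1", "1", f"{evalue:.2g}", f"{evalue:.2g}",
        f"{score:.1f}", "0.1",
        str(hmm_from), str(hmm_to), "10", "190", "5", "195", "0.95",
        "synthetic ORF",
    ]
    return " ".join(fields)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Generate one complete synthetic study.

    Returns a bundle dict (and, when ``out_dir`` is given, writes
    species.nwk, genetrees/, targets.tsv, domtbl/, checkm.tsv,
    profiles.tsv, kingdom_prevalence.tsv, network.yaml, manifest.json and
    truth.json in the dialects the pipeline parses).
    """
    config.validate()
    seed = config.seed

    # --- species tree and sugar presence characters --------------------
    tree = simulate_species_tree(config.n_taxa, seed,
                                 support_range=config.support_range)
    genomes = sorted(phylo.leaf_labels(tree))
    sugars_core = [f"NS-core{i:02d}" for i in range(1, config.n_core + 1)]
    sugars_acc = [f"NS-acc{i:02d}" for i in range(1, config.n_accessory + 1)]
    sugar_class = {s: "core" for s in sugars_core}
    sugar_class.update({s: "accessory" for s in sugars_acc})

    characters: dict[str, dict[str, int]] = {}
    char_truth: dict[str, dict] = {}
    for i, sugar in enumerate(sugars_core + sugars_acc):
        rng = _rng(seed, "character", i)
        if sugar_class[sugar] == "core":
            char, truth = simulate_character(
                tree, 0.0, config.core_loss_prob, 1, rng)
        else:
            char, truth = simulate_character(
                tree, config.accessory_gain_prob,
                config.accessory_loss_prob, 0, rng)
        characters[sugar] = char
        char_truth[sugar] = truth

    # --- pathways: one linear chain of gene families per sugar ---------
    fam_counter = 910000
    sugar_families: dict[str, list[str]] = {}
    for sugar in sugars_core + sugars_acc:
        fams = []
        for _ in range(config.steps_per_pathway):
            fams.append(f"K{fam_counter}")
            fam_counter += 1
        sugar_families[sugar] = fams
    all_families = [f for fams in sugar_families.values() for f in fams]

    network_cfg = _build_network_config(sugar_families)

    # --- per-genome gene presence (pathway state + stray background hits)
    rng_genes = _rng(seed, "gene-presence")
    gene_presence: dict[str, dict[str, int]] = {g: {} for g in genomes}
    for sugar, fams in sugar_families.items():
        for g in genomes:
            if characters[sugar][g] == 1:
                for f in fams:
                    gene_presence[g][f] = 1
            else:
                for f in fams:
                    gene_presence[g][f] = int(
                        rng_genes.random() < config.background_gene_presence_prob
                    )

    # --- profile metadata (half KEGG-thresholded, half e-value/cover) ---
    rng_prof = _rng(seed, "profiles")
    profiles: dict[str, dict] = {
        MARKER_FAMILY: {"threshold": 150.0, "n_known": 5000},
        "K900001": {"threshold": None, "n_known": 150},  # planted small family
    }
    for f in all_families:
        thr = 100.0 if rng_prof.random() < config.kegg_threshold_fraction else None
        profiles[f] = {"threshold": thr, "n_known": int(rng_prof.integers(200, 4000))}

    # --- domtblout evidence ---------------------------------------------
    rng_hits = _rng(seed, "hits")
    domtbl: dict[str, list[str]] = {}
    for g in genomes:
        lines, orf_n = [], 0
        orf_n += 1
        lines.append(_domtbl_line(f"{g}|orf{orf_n:05d}", MARKER_FAMILY,
                                  score=float(rng_hits.uniform(300, 600)),
                                  evalue=1e-80, hmm_from=5, hmm_to=195))
        for f in all_families:
            if gene_presence[g][f] == 1:
                orf_n += 1
                lines.append(_domtbl_line(
                    f"{g}|orf{orf_n:05d}", f,
                    score=float(rng_hits.uniform(150, 400)),
                    evalue=10.0 ** -float(rng_hits.uniform(40, 90)),
                    hmm_from=6, hmm_to=190))
            elif rng_hits.random() < 0.05:  # sub-threshold noise hit
                orf_n += 1
                lines.append(_domtbl_line(
                    f"{g}|orf{orf_n:05d}", f,
                    score=float(rng_hits.uniform(10, 40)),
                    evalue=10.0 ** -float(rng_hits.uniform(2, 8)),
                    hmm_from=50, hmm_to=110))
        if rng_hits.random() < 0.5:  # occasional hit against the small family
            orf_n += 1
            lines.append(_domtbl_line(f"{g}|orf{orf_n:05d}", "K900001",
                                      score=220.0, evalue=1e-60,
                                      hmm_from=6, hmm_to=190))
        domtbl[g] = lines

    # --- quality table with planted decoys ------------------------------
    rng_q = _rng(seed, "quality")
    checkm_rows = []
    for g in genomes:
        checkm_rows.append((g, float(rng_q.uniform(92, 100)),
                            float(rng_q.uniform(0, 3))))
    decoys = []
    for d in range(1, config.n_decoy_genomes + 1):
        gid = f"DECOY{d:02d}"
        decoys.append(gid)
        if d % 2 == 0:
            row = (gid, float(rng_q.uniform(50, 85)), float(rng_q.uniform(0, 3)))
        else:
            row = (gid, float(rng_q.uniform(92, 100)), float(rng_q.uniform(6, 15)))
        checkm_rows.append(row)
        domtbl[gid] = [_domtbl_line(f"{gid}|orf00001", MARKER_FAMILY,
                                    score=400.0, evalue=1e-80,
                                    hmm_from=5, hmm_to=195)]

    # --- gene trees with implanted target clades ------------------------
    gene_trees: dict[str, str] = {}
    gene_targets: dict[str, list[str]] = {}
    clade_truth: dict[str, dict] = {}
    lo, hi = config.target_clade_count_range
    for j, (sugar, fams) in enumerate(sorted(sugar_families.items())):
        for step, fam in enumerate(fams):
            rng_gt = _rng(seed, "gene-tree", j * 100 + step)
            targets = sorted(g for g in genomes if gene_presence[g][fam] == 1)
            if not targets:
                continue
            k = 1 if sugar_class[sugar] == "core" else int(rng_gt.integers(lo, hi + 1))
            nwk, sizes = simulate_gene_tree(
                fam, targets, k, config.gene_tree_background, rng_gt,
                support_range=config.support_range)
            gene_trees[fam] = nwk
            gene_targets[fam] = targets
            clade_truth[fam] = {
                "sugar": sugar,
                "clade_sizes": sizes,
                "n_targets": len(targets),
                "monophyly": sizes[0] / len(targets),
            }

    # --- kingdom prevalence ---------------------------------------------
    rng_kp = _rng(seed, "kingdom")
    kingdom = {}
    for sugar in sugars_core + sugars_acc:
        a, b = (config.kingdom_core_beta if sugar_class[sugar] == "core"
                else config.kingdom_accessory_beta)
        kingdom[sugar] = float(rng_kp.beta(a, b))

    # --- clade-filter anchors: two leaves spanning the ingroup root -----
    root_children = tree.seed_node.child_nodes()
    ref_a = next(root_children[0].leaf_iter()).taxon.label
    ref_b = next(root_children[-1].leaf_iter()).taxon.label

    # class implied by the realized (noise-free) character under the
    # sugar classification rule; differs from the generative regime when
    # drift pushes prevalence across the 0.9 boundary or to zero
    realized_class = {}
    for sugar, char in characters.items():
        prev = float(np.mean(list(char.values())))
        realized_class[sugar] = (
            "core" if prev > 0.9 else ("accessory" if prev > 0 else "absent")
        )

    truth = {
        "seed": seed,
        "config": asdict(config),
        "genomes": genomes,
        "decoys": decoys,
        "sugar_class": sugar_class,
        "realized_class": realized_class,
        "sugar_families": sugar_families,
        "characters": characters,
        "character_truth": char_truth,
        "gene_clades": clade_truth,
        "kingdom_prevalence": kingdom,
    }
    manifest = {
        "seed": seed,
        "marker_family": MARKER_FAMILY,
        "outgroup": "OUTGROUP",
        "clade_refs": [ref_a, ref_b],
        "excluded_small_families": ["K900001"],
    }

    species_newick = _attach_outgroup(phylo.write_newick(tree))
    bundle = {
        "species_newick": species_newick,
        "characters": characters,
        "gene_trees": gene_trees,
        "gene_targets": gene_targets,
        "domtbl": domtbl,
        "checkm": checkm_rows,
        "profiles": profiles,
        "kingdom_prevalence": kingdom,
        "network_config": network_cfg,
        "manifest": manifest,
        "truth": truth,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _attach_outgroup(newick: str) -> str:
    body = newick.strip().rstrip(";")
    return f"({body},OUTGROUP:0.500000);"


def _build_network_config(sugar_families: dict[str, list[str]]) -> dict:
    """Linear source->...->sugar chain per sugar, one family per step."""
    metabolites = {"F6P"}
    reactions, products = [], {}
    for sugar, fams in sugar_families.items():
        prev = "F6P"
        for step, fam in enumerate(fams):
            met = sugar if step == len(fams) - 1 else f"{sugar}-m{step + 1}"
            metabolites.add(met)
            rid = f"R-{sugar}-{step + 1}"
            reactions.append({"id": rid, "substrate": prev,
                              "product": met, "genes": [[fam]]})
            prev = met
        products[sugar] = f"R-{sugar}-{len(fams)}"
    return {
        "metabolites": sorted(metabolites),
        "sources": ["F6P"],
        "reactions": reactions,
        "products": products,
    }


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "species.nwk").write_text(bundle["species_newick"] + "\n")
    gt_dir = out / "genetrees"
    gt_dir.mkdir(exist_ok=True)
    for fam, nwk in bundle["gene_trees"].items():
        (gt_dir / f"{fam}.nwk").write_text(nwk + "\n")
    with open(out / "targets.tsv", "w") as fh:
        for fam, targets in sorted(bundle["gene_targets"].items()):
            for t in targets:
                fh.write(f"{fam}\t{t}\n")
    dt_dir = out / "domtbl"
    dt_dir.mkdir(exist_ok=True)
    header = "# target name        accession   tlen query name ...\n#\n"
    for g, lines in bundle["domtbl"].items():
        (dt_dir / f"{g}.domtbl").write_text(header + "\n".join(lines) + "\n")
    with open(out / "checkm.tsv", "w") as fh:
        fh.write("Bin Id\tCompleteness\tContamination\n")
        for gid, comp, cont in bundle["checkm"]:
            fh.write(f"{gid}\t{comp:.2f}\t{cont:.2f}\n")
    with open(out / "profiles.tsv", "w") as fh:
        for fam, meta in sorted(bundle["profiles"].items()):
            thr = "NA" if meta["threshold"] is None else f"{meta['threshold']:.1f}"
            fh.write(f"{fam}\t{thr}\t{meta['n_known']}\n")
    with open(out / "kingdom_prevalence.tsv", "w") as fh:
        fh.write("sugar_id\tkingdom_prevalence\n")
        for sugar, prev in sorted(bundle["kingdom_prevalence"].items()):
            fh.write(f"{sugar}\t{prev:.4f}\n")
    with open(out / "network.yaml", "w") as fh:
        yaml.safe_dump(bundle["network_config"], fh, sort_keys=False)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    (out / "truth.json").write_text(json.dumps(bundle["truth"], indent=2))
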