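"""Reference nucleotide-sugar reaction network and pathway-presence calls.

The biosynthetic map is modelled as a directed graph over metabolites
whose edges are enzymatic reactions, each gated by gene families
(OR over isoenzyme alternatives, AND within a multi-gene complex —
the standard KEGG-module convention). Entry points are central-carbon
intermediates (fructose-6-phosphate, ribulose-5-phosphate,
sedoheptulose-7-phosphate); each nucleotide-sugar product is reached by
a terminal reaction.

A pathway is called present in a genome when both detection criteria
hold: (i) some route from a central-carbon source to the sugar is at
least 75% complete in present reactions, and (ii) the terminal enzyme
itself is present. Completeness is the maximum over simple (cycle-free)
routes of the fraction of route reactions whose gene requirement is
satisfied; on a linear pathway this is the intuitive "3 of 4 steps"
reading, and it stays well defined on branched networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "Reaction",
    "ReferenceNetwork",
    "PathwayCall",
    "NetworkValidationError",
    "load_network",
    "reaction_present",
    "pathway_completeness",
    "call_pathway",
    "call_all_pathways",
    "classify_sugar_prevalence",
]


class NetworkValidationError(ValueError):
    """The network config violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrate: str
    product: str
    # alternatives: OR over sets; within a set: AND (enzyme complex)
    gene_requirement: tuple[frozenset[str], ...]


@dataclass
class ReferenceNetwork:
    metabolites: set[str]
    reactions: dict[str, Reaction]
    sources: set[str]
    products: dict[str, str]  # sugar_id -> terminal reaction id
    route_depth_cap: int = 15
    _graph: nx.MultiDiGraph = field(init=False, repr=False)

    def __post_init__(self):
        self._graph = nx.MultiDiGraph()
        self._graph.add_nodes_from(self.metabolites)
        for rxn in self.reactions.values():
            self._graph.add_edge(rxn.substrate, rxn.product, key=rxn.reaction_id)
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in (rxn.substrate, rxn.product):
                if met not in self.metabolites:
                    raise NetworkValidationError(
                        f"reaction {rxn.reaction_id}: undeclared metabolite {met!r}"
                    )
            if rxn.substrate == rxn.product:
                raise NetworkValidationError(
                    f"reaction {rxn.reaction_id}: self-loop on {rxn.substrate!r}"
                )
            if not rxn.gene_requirement or any(not a for a in rxn.gene_requirement):
                raise NetworkValidationError(
                    f"reaction {rxn.reaction_id}: empty gene requirement"
                )
        for src in self.sources:
            if src not in self.metabolites:
                raise NetworkValidationError(f"undeclared source metabolite {src!r}")
        for sugar, rxn_id in self.products.items():
            if rxn_id not in self.reactions:
                raise NetworkValidationError(
                    f"product {sugar!r}: terminal reaction {rxn_id!r} not defined"
                )
            target = self.reactions[rxn_id].product
            if target in self.sources:
                raise NetworkValidationError(
                    f"product {sugar!r} coincides with source metabolite {target!r}"
                )
            if not any(
                nx.has_path(self._graph, s, target) for s in self.sources
            ):
                raise NetworkValidationError(
                    f"product {sugar!r}: no route from any source to {target!r}"
                )

    def terminal_reaction(self, sugar_id: str) -> Reaction:
        return self.reactions[self.products[sugar_id]]

    def routes_to(self, sugar_id: str) -> list[list[str]]:
        """All simple reaction routes source -> sugar ending in the terminal
        reaction, as lists of reaction ids (depth-capped)."""
        terminal = self.terminal_reaction(sugar_id)
        target = terminal.product
        routes = []
        for src in sorted(self.sources):
            if src == target:
                continue
            for epath in nx.all_simple_edge_paths(
                self._graph, src, target, cutoff=self.route_depth_cap
            ):
                rids = [key for (_, _, key) in epath]
                if rids[-1] == terminal.reaction_id:
                    routes.append(rids)
        return routes


def load_network(path_or_dict) -> ReferenceNetwork:
    """Load and validate a network config (YAML path or parsed mapping).

    Expected blocks: ``metabolites`` (list), ``sources`` (list),
    ``reactions`` (list of {id, substrate, product, genes: list of
    lists}), ``products`` (sugar -> terminal reaction id), and optional
    ``route_depth_cap``.
    """
    if isinstance(path_or_dict, Mapping):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    try:
        mets = set(cfg["metabolites"])
        sources = set(cfg["sources"])
        raw_rxns = cfg["reactions"]
        products = dict(cfg["products"])
    except KeyError as exc:
        raise NetworkValidationError(f"missing config block: {exc}") from exc
    reactions = {}
    for r in raw_rxns:
        genes = r["genes"]
        if genes and isinstance(genes[0], str):  # allow flat list of isoenzymes
            genes = [[g] for g in genes]
        rxn = Reaction(
            reaction_id=str(r["id"]),
            substrate=str(r["substrate"]),
            product=str(r["product"]),
            gene_requirement=tuple(frozenset(map(str, alt)) for alt in genes),
        )
        if rxn.reaction_id in reactions:
            raise NetworkValidationError(f"duplicate reaction id {rxn.reaction_id!r}")
        reactions[rxn.reaction_id] = rxn
    return ReferenceNetwork(
        metabolites=mets,
        reactions=reactions,
        sources=sources,
        products=products,
        route_depth_cap=int(cfg.get("route_depth_cap", 15)),
    )


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    sugar_id: str
    completeness: float
    terminal_present: bool
    detected: bool


def reaction_present(reaction: Reaction, genome_row: Mapping[str, int]) -> bool:
    """True iff some isoenzyme alternative has all its families present."""
    for alt in reaction.gene_requirement:
        for fam in alt:
            if fam not in genome_row:
                raise KeyError(
                    f"reaction {reaction.reaction_id}: family {fam!r} "
                    "missing from presence matrix"
                )
    return any(
        all(genome_row[fam] == 1 for fam in alt)
        for alt in reaction.gene_requirement
    )


def pathway_completeness(
    network: ReferenceNetwork,
    sugar_id: str,
    genome_row: Mapping[str, int],
    mode: str = "route",
) -> float:
    """Fraction of the best source-to-sugar route present in a genome.

    ``mode='route'`` (default): maximum over all simple routes of the
    fraction of route reactions present. ``mode='reachability'``: 1.0
    when the sugar is reachable from a source through present reactions
    only, else 0.0 (the coarser connected-component reading).
    """
    if sugar_id not in network.products:
        raise KeyError(f"unknown sugar {sugar_id!r}")
    present = {
        rid: reaction_present(rxn, genome_row)
        for rid, rxn in network.reactions.items()
    }
    if mode == "reachability":
        sub = nx.MultiDiGraph()
        sub.add_nodes_from(network.metabolites)
        for rid, ok in present.items():
            if ok:
                rxn = network.reactions[rid]
                sub.add_edge(rxn.substrate, rxn.product, key=rid)
        target = network.terminal_reaction(sugar_id).product
        reachable = any(nx.has_path(sub, s, target) for s in network.sources)
        return 1.0 if reachable else 0.0
    if mode != "route":
        raise ValueError(f"unknown completeness mode {mode!r}")
    best = 0.0
    for route in network.routes_to(sugar_id):
        frac = sum(present[rid] for rid in route) / len(route)
        best = max(best, frac)
    return best


def call_pathway(
    network: ReferenceNetwork,
    sugar_id: str,
    genome_row: Mapping[str, int],
    genome_id: str = "",
    min_completeness: float = 0.75,
    mode: str = "route",
) -> PathwayCall:
    """Apply the two-criterion detection rule to one genome and sugar."""
    comp = pathway_completeness(network, sugar_id, genome_row, mode=mode)
    term = reaction_present(network.terminal_reaction(sugar_id), genome_row)
    return PathwayCall(
        genome_id=genome_id,
        sugar_id=sugar_id,
        completeness=comp,
        terminal_present=term,
        detected=(comp >= min_completeness) and term,
    )


def call_all_pathways(
    network: ReferenceNetwork,
    matrix,
    min_completeness: float = 0.75,
    mode: str = "route",
) -> list[PathwayCall]:
    """Detection calls for every genome (matrix row) x sugar."""
    calls = []
    for genome_id, row in matrix.iterrows():
        for sugar in sorted(network.products):
            calls.append(
                call_pathway(
                    network, sugar, row, genome_id=genome_id,
                    min_completeness=min_completeness, mode=mode,
                )
            )
    return calls


def classify_sugar_prevalence(
    calls: Sequence[PathwayCall], core_min_fraction: float = 0.9
):
    """Label each sugar core / accessory / absent by detection prevalence.

    The sugar-level core rule is strict: core iff prevalence is greater
    than ``core_min_fraction`` (contrast the inclusive gene-level rule).
    Returns a DataFrame indexed by sugar with prevalence and label.
    """
    import pandas as pd

    by_sugar: dict[str, list[bool]] = {}
    for c in calls:
        by_sugar.setdefault(c.sugar_id, []).append(c.detected)
    rows = {}
    for sugar, flags in sorted(by_sugar.items()):
        prev = sum(flags) / len(flags)
        label = "core" if prev > core_min_fraction else (
            "accessory" if prev > 0 else "absent"
        )
        rows[sugar] = {"prevalence": prev, "label": label}
    return pd.DataFrame.from_dict(rows, orient="index")
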