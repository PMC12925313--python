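"""End-to-end orchestration: screen -> pathways -> events -> monophyly -> tests.

Each stage is a pure function of (inputs, config, seed); the runner
persists every intermediate table as TSV, echoes the configuration into
the output directory, and writes a machine-readable summary so that
every reported number is recomputable from the persisted intermediates.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import monophyly as mono
from . import network as net
from . import permutation as perm
from . import phylo, screen


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the study's defaults.

    Quality screen: completeness >= 90%, contamination <= 5%. Hit filter:
    curated bitscore thresholds where available, else e-value <= 1e-20
    with >= 75% profile coverage; families with < 200 known sequences
    excluded. Core rules: genes inclusive at 90%, sugars strictly above
    90%. Pathway call: >= 75% route completeness AND terminal enzyme.
    Monophyly inclusion: LCA support >= 80%. Tests: 100000 permutations.
    """

    input_dir: str = "."
    out_dir: str = "results"
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    fallback_evalue: float = 1e-20
    min_query_cover: float = 0.75
    min_family_seqs: int = 200
    gene_core_fraction: float = 0.9
    sugar_core_fraction: float = 0.9
    pathway_min_completeness: float = 0.75
    completeness_mode: str = "route"
    support_threshold: float = 0.8
    rooting: str = "midpoint"
    n_permutations: int = 100_000
    seed: int = 17
    marker_family: str = "K00937"
    outgroup: str | None = None
    clade_refs: tuple[str, str] | None = None
    skip_monophyly: bool = False
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dataset(cls, input_dir, out_dir, **overrides) -> "RunConfig":
        """Build a config from a dataset directory, honouring its
        manifest.json (marker family, outgroup, clade anchors)."""
        input_dir = Path(input_dir)
        manifest_path = input_dir / "manifest.json"
        kwargs: dict = {"input_dir": str(input_dir), "out_dir": str(out_dir)}
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            kwargs["marker_family"] = manifest.get("marker_family", "K00937")
            kwargs["outgroup"] = manifest.get("outgroup")
            refs = manifest.get("clade_refs")
            kwargs["clade_refs"] = tuple(refs) if refs else None
        kwargs.update(overrides)
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the summary dict."""
    t0 = time.time()
    inp = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str))
    timings: dict[str, float] = {}

    # ---- stage 1: screen ------------------------------------------------
    t = time.time()
    try:
        stage1 = screen_stage(inp, config)
    except Exception as exc:
        raise PipelineError(f"screen stage failed: {exc}") from exc
    timings["screen"] = time.time() - t
    matrix = stage1["matrix"]
    matrix.to_csv(out / "presence_matrix.tsv", sep="\t")
    stage1["gene_labels"].to_csv(out / "gene_prevalence.tsv", sep="\t")
    (out / "retained_genomes.txt").write_text(
        "\n".join(matrix.index) + "\n")

    # ---- stage 2: pathways ----------------------------------------------
    t = time.time()
    network_path = inp / "network.yaml"
    if not network_path.exists():
        raise PipelineError(f"pathways stage: network file {network_path} missing")
    try:
        network = net.load_network(network_path)
        calls = net.call_all_pathways(
            network, matrix,
            min_completeness=config.pathway_min_completeness,
            mode=config.completeness_mode)
        sugar_labels = net.classify_sugar_prevalence(
            calls, core_min_fraction=config.sugar_core_fraction)
    except Exception as exc:
        raise PipelineError(f"pathways stage failed: {exc}") from exc
    timings["pathways"] = time.time() - t
    calls_df = pd.DataFrame([
        {"genome_id": c.genome_id, "sugar_id": c.sugar_id,
         "completeness": c.completeness,
         "terminal_present": c.terminal_present, "detected": c.detected}
        for c in calls])
    calls_df.to_csv(out / "pathway_calls.tsv", sep="\t", index=False)
    sugar_labels.to_csv(out / "sugar_prevalence.tsv", sep="\t")

    # ---- stage 3: gain/loss events --------------------------------------
    t = time.time()
    try:
        events, event_summary, pruned_tree = events_stage(
            stage1["species_tree"], calls, sugar_labels, matrix.index)
    except Exception as exc:
        raise PipelineError(f"events stage failed: {exc}") from exc
    timings["events"] = time.time() - t
    pd.Series(events, name="min_changes").rename_axis("sugar_id").to_csv(
        out / "event_counts.tsv", sep="\t")
    heat = render_heatmap_table(calls, pruned_tree)
    heat.to_csv(out / "heatmap_table.tsv", sep="\t")

    # ---- stage 4: monophyly ---------------------------------------------
    t = time.time()
    mono_results: list[mono.MonophylyResult] = []
    family_labels = {}
    if not config.skip_monophyly and (inp / "genetrees").is_dir():
        try:
            mono_results, family_labels = monophyly_stage(
                inp, config, stage1["gene_labels"])
        except Exception as exc:
            raise PipelineError(f"monophyly stage failed: {exc}") from exc
    timings["monophyly"] = time.time() - t
    if mono_results:
        pd.DataFrame([
            {"family_id": r.family_id, "score": r.score,
             "lca_support": r.lca_support, "included": r.included}
            for r in mono_results
        ]).to_csv(out / "monophyly.tsv", sep="\t", index=False)

    # ---- stage 5: permutation tests --------------------------------------
    t = time.time()
    try:
        tests = tests_stage(inp, config, events, sugar_labels,
                            mono_results, family_labels)
    except Exception as exc:
        raise PipelineError(f"tests stage failed: {exc}") from exc
    timings["tests"] = time.time() - t

    summary = {
        "n_genomes_retained": int(matrix.shape[0]),
        "n_families": int(matrix.shape[1]),
        "sugar_labels": sugar_labels["label"].to_dict(),
        "n_core_sugars": int((sugar_labels["label"] == "core").sum()),
        "n_accessory_sugars": int((sugar_labels["label"] == "accessory").sum()),
        "event_counts": events,
        "event_summary": event_summary,
        "monophyly_summary": tests.pop("_monophyly_summary", None),
        "tests": tests,
        "seed": config.seed,
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "runtime_sec": round(time.time() - t0, 3),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_tests_tsv(tests, out / "tests.tsv")
    return summary


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def screen_stage(inp: Path, config: RunConfig) -> dict:
    records = screen.read_checkm_table(inp / "checkm.tsv")
    good_quality = set(screen.filter_genomes(
        records, config.min_completeness, config.max_contamination))

    profiles = screen.read_profile_meta(inp / "profiles.tsv")
    kept_profiles = screen.exclude_small_families(
        profiles, min_seqs=config.min_family_seqs)

    hits = []
    for path in sorted((inp / "domtbl").iterdir()):
        hits.extend(screen.parse_domtbl(path, genome_id=path.stem))
    for h in hits:
        if h.family_id not in profiles:
            raise KeyError(f"hit references unknown family {h.family_id!r}")
    hits = [h for h in hits if h.family_id in kept_profiles]
    hits = screen.apply_thresholds(
        hits, kept_profiles,
        fallback_evalue=config.fallback_evalue,
        min_query_cover=config.min_query_cover)
    hits = screen.best_hit_per_family(hits)

    marker_map = screen.select_marker_genomes(hits, config.marker_family)
    retained = good_quality & set(marker_map)

    tree = phylo.read_newick(inp / "species.nwk")
    if config.outgroup:
        phylo.root_with_outgroup(tree, config.outgroup)
        if config.clade_refs:
            in_clade = phylo.clade_filter(tree, *config.clade_refs)
            retained &= in_clade
    retained &= set(phylo.leaf_labels(tree))

    genomes = sorted(retained)
    families = sorted(f for f in kept_profiles if f != config.marker_family)
    matrix = screen.build_presence_matrix(hits, genomes, families)
    gene_labels = screen.classify_gene_prevalence(
        matrix, core_min_fraction=config.gene_core_fraction)
    return {
        "matrix": matrix,
        "gene_labels": gene_labels,
        "species_tree": tree,
        "marker_map": marker_map,
    }


def events_stage(tree, calls, sugar_labels, retained_genomes):
    """Fitch gain/loss counts per non-absent sugar on the pruned tree."""
    pruned = tree.extract_tree_with_taxa_labels(list(retained_genomes))
    characters: dict[str, dict[str, int]] = {}
    for c in calls:
        characters.setdefault(c.sugar_id, {})[c.genome_id] = int(c.detected)
    events = {}
    for sugar, char in sorted(characters.items()):
        if sugar_labels.loc[sugar, "label"] == "absent":
            continue
        events[sugar] = phylo.fitch_changes(pruned, char)
    labels = sugar_labels["label"].to_dict()
    present = {s: labels[s] for s in events}
    summary = phylo.summarize_events(events, present) if events else {}
    return events, summary, pruned


def monophyly_stage(inp: Path, config: RunConfig, gene_labels):
    targets_df = pd.read_csv(inp / "targets.tsv", sep="\t", header=None,
                             names=["family_id", "leaf"])
    targets_by_family = {
        fam: set(sub["leaf"]) for fam, sub in targets_df.groupby("family_id")
    }
    results = []
    family_labels = {}
    for tree_path in sorted((inp / "genetrees").iterdir()):
        fam = tree_path.stem
        if fam not in targets_by_family:
            continue
        gtree = phylo.read_newick(tree_path)
        res = mono.score_family(
            gtree, targets_by_family[fam], family_id=fam,
            support_threshold=config.support_threshold,
            rooting=config.rooting)
        results.append(res)
        if fam in gene_labels.index:
            family_labels[fam] = gene_labels.loc[fam, "label"]
    return results, family_labels


def tests_stage(inp: Path, config: RunConfig, events, sugar_labels,
                mono_results, family_labels) -> dict:
    labels = sugar_labels["label"].to_dict()
    group_order = ("accessory", "core")
    tests: dict = {}

    usable = {s: v for s, v in events.items() if labels.get(s) in group_order}
    res = perm.compare_groups(
        usable, labels, n_permutations=config.n_permutations,
        seed=config.seed, group_order=group_order)
    tests["gain_loss_events"] = _result_dict(res)

    if mono_results:
        scores = {r.family_id: r.score for r in mono_results
                  if r.included and family_labels.get(r.family_id) in group_order}
        fam_labels = {f: family_labels[f] for f in scores}
        res = perm.compare_groups(
            scores, fam_labels, n_permutations=config.n_permutations,
            seed=config.seed + 1, group_order=group_order)
        tests["monophyly"] = _result_dict(res)
        tests["_monophyly_summary"] = res.group_summaries

    kp_path = inp / "kingdom_prevalence.tsv"
    if kp_path.exists():
        kp = pd.read_csv(kp_path, sep="\t")
        records = [
            perm.KingdomPrevalenceRecord(str(r["sugar_id"]),
                                         float(r["kingdom_prevalence"]))
            for _, r in kp.iterrows()
        ]
        res = perm.kingdom_prevalence_test(
            records, {s: l for s, l in labels.items() if l in group_order},
            n_permutations=config.n_permutations, seed=config.seed + 2,
            group_order=group_order)
        tests["kingdom_prevalence"] = _result_dict(res)
    return tests


def render_heatmap_table(calls, tree) -> pd.DataFrame:
    """Genomes x sugars detection matrix, rows in tree leaf order."""
    detected: dict[str, dict[str, int]] = {}
    for c in calls:
        detected.setdefault(c.genome_id, {})[c.sugar_id] = int(c.detected)
    order = phylo.leaf_labels(tree)
    missing = [g for g in detected if g not in set(order)]
    if missing:
        raise KeyError(f"genomes absent from tree: {sorted(missing)}")
    rows = [g for g in order if g in detected]
    sugars = sorted({c.sugar_id for c in calls})
    return pd.DataFrame(
        [[detected[g].get(s, 0) for s in sugars] for g in rows],
        index=rows, columns=sugars)


def _result_dict(res: perm.PermutationResult) -> dict:
    return {
        "statistic_observed": res.statistic_observed,
        "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "exact": res.exact,
        "group_summaries": res.group_summaries,
    }


def _write_tests_tsv(tests: dict, path: Path) -> None:
    rows = []
    for name, res in tests.items():
        if name.startswith("_"):
            continue
        row = {"test": name,
               "statistic": res["statistic_observed"],
               "p_value": res["p_value"],
               "n_permutations": res["n_permutations"],
               "exact": res["exact"]}
        for gname, s in res["group_summaries"].items():
            row[f"{gname}_median"] = s["median"]
            row[f"{gname}_iqr"] = f"{s['q1']}-{s['q3']}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
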