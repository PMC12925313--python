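"""Count minimum gain/loss events of each sugar on the species tree.

Each sugar's detection pattern is a binary character on the rooted
marker-gene tree; Fitch small parsimony gives the minimum number of
state changes (gains or losses, counted jointly) explaining it. Core
and accessory groups are summarised by median and interquartile range,
and the tree-ordered detection matrix behind the presence heatmap is
written alongside.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from glycopan import phylo
from glycopan.pipeline import render_heatmap_table
from glycopan.network import PathwayCall


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--calls", type=Path,
                    default=Path("results/pathways/pathway_calls.tsv"))
    ap.add_argument("--labels", type=Path,
                    default=Path("results/pathways/sugar_prevalence.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/events"))
    args = ap.parse_args()

    manifest = json.loads((args.data / "manifest.json").read_text())
    tree = phylo.read_newick(args.data / "species.nwk")
    phylo.root_with_outgroup(tree, manifest["outgroup"])

    calls_df = pd.read_csv(args.calls, sep="\t")
    labels = pd.read_csv(args.labels, sep="\t", index_col=0)["label"]
    genomes = sorted(calls_df["genome_id"].unique())
    pruned = tree.extract_tree_with_taxa_labels(genomes)

    counts = {}
    for sugar, sub in calls_df.groupby("sugar_id"):
        if labels.get(sugar) == "absent":
            continue
        char = dict(zip(sub["genome_id"], sub["detected"].astype(int)))
        counts[sugar] = phylo.fitch_changes(pruned, char)
    summary = phylo.summarize_events(counts, labels.to_dict())

    args.out.mkdir(parents=True, exist_ok=True)
    pd.Series(counts, name="min_changes").rename_axis("sugar_id").to_csv(
        args.out / "event_counts.tsv", sep="\t")
    calls = [PathwayCall(**row) for row in calls_df.to_dict("records")]
    render_heatmap_table(calls, pruned).to_csv(
        args.out / "heatmap_table.tsv", sep="\t")

    for group, s in summary.items():
        print(f"{group}: median {s['median']} gain/loss events "
              f"(IQR {s['q1']} - {s['q3']}, n={s['n']})")


if __name__ == "__main__":
    main()
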