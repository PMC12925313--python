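"""Call nucleotide-sugar pathway presence per genome.

For each genome and sugar: best source-to-sugar route completeness and
the two-criterion detection rule (>= 75% route completeness AND the
terminal enzyme present), then sugar-level core/accessory labels
(core iff detected in more than 90% of genomes).
"""

import argparse
from pathlib import Path

import pandas as pd

from glycopan import network as net


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--matrix", type=Path,
                    default=Path("results/screen/presence_matrix.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/pathways"))
    args = ap.parse_args()

    matrix = pd.read_csv(args.matrix, sep="\t", index_col=0)
    network = net.load_network(args.data / "network.yaml")
    calls = net.call_all_pathways(network, matrix)
    labels = net.classify_sugar_prevalence(calls)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(
        args.out / "pathway_calls.tsv", sep="\t", index=False)
    labels.to_csv(args.out / "sugar_prevalence.tsv", sep="\t")

    counts = labels["label"].value_counts().to_dict()
    print(f"{len(calls)} calls over {len(network.products)} sugars; "
          f"sugar labels: {counts}")


if __name__ == "__main__":
    main()
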