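"""Quality-screen genomes and build the gene-family presence matrix.

Applies the CheckM bounds (completeness >= 90%, contamination <= 5%),
parses the per-genome domtblout evidence, filters hits by the KOfam
threshold rule (curated bitscore cutoffs; else e-value <= 1e-20 with
>= 75% profile coverage), requires a marker-gene hit, restricts to the
marker-tree clade spanned by the reference genomes, and writes the
binary presence matrix with core/accessory gene labels.
"""

import argparse
from pathlib import Path

from glycopan.pipeline import RunConfig, screen_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/screen"))
    args = ap.parse_args()

    cfg = RunConfig.from_dataset(args.data, args.out)
    stage = screen_stage(args.data, cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    matrix = stage["matrix"]
    matrix.to_csv(args.out / "presence_matrix.tsv", sep="\t")
    stage["gene_labels"].to_csv(args.out / "gene_prevalence.tsv", sep="\t")
    (args.out / "retained_genomes.txt").write_text("\n".join(matrix.index) + "\n")

    labels = stage["gene_labels"]["label"].value_counts().to_dict()
    print(f"retained {matrix.shape[0]} genomes x {matrix.shape[1]} families; "
          f"gene labels: {labels}")


if __name__ == "__main__":
    main()
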