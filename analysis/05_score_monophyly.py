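"""Score monophyly of the target genomes' sequences in each gene family.

For every gene-family tree: the fraction of target sequences covered by
the largest clade containing only targets (1 = perfect monophyly), the
branch support of the targets' last common ancestor, and the inclusion
flag (families with LCA support below 80% carry unreliable signal and
are excluded from group summaries).
"""

import argparse
from pathlib import Path

import pandas as pd

from glycopan import monophyly as mono
from glycopan import phylo


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--gene-labels", type=Path,
                    default=Path("results/screen/gene_prevalence.tsv"))
    ap.add_argument("--support-threshold", type=float, default=0.8)
    ap.add_argument("--out", type=Path, default=Path("results/monophyly"))
    args = ap.parse_args()

    targets_df = pd.read_csv(args.data / "targets.tsv", sep="\t",
                             header=None, names=["family_id", "leaf"])
    by_family = {f: set(s["leaf"]) for f, s in targets_df.groupby("family_id")}
    gene_labels = pd.read_csv(args.gene_labels, sep="\t", index_col=0)["label"]

    rows = []
    for tree_path in sorted((args.data / "genetrees").iterdir()):
        fam = tree_path.stem
        if fam not in by_family:
            continue
        res = mono.score_family(
            phylo.read_newick(tree_path), by_family[fam], family_id=fam,
            support_threshold=args.support_threshold)
        rows.append({"family_id": fam, "score": res.score,
                     "lca_support": res.lca_support,
                     "included": res.included,
                     "label": gene_labels.get(fam, "unlabeled")})
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "monophyly.tsv", sep="\t", index=False)

    inc = df[df["included"]]
    for group, sub in inc.groupby("label"):
        med = sub["score"].median()
        q1, q3 = sub["score"].quantile([0.25, 0.75])
        print(f"{group}: median monophyly {med:.2f} "
              f"(IQR {q1:.2f} - {q3:.2f}, n={len(sub)}); "
              f"{len(df) - len(inc)} families excluded overall")


if __name__ == "__main__":
    main()
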