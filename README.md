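# glycopan

Pangenome analysis of nucleotide-sugar biosynthetic potential in a
bacterial genus, built around metagenome-assembled genomes (MAGs).

Glycans in the biofilm matrix are assembled from activated sugar
precursors (nucleotide-sugars such as UDP-glucose or dTDP-rhamnose), and
unlike amino acids this alphabet is not universal: which precursors a
genome can make constrains which glycans it can build. `glycopan` asks,
for a set of genomes from one genus, which nucleotide-sugar pathways
each genome carries, which sugars are *core* (nearly universal in the
genus) versus *accessory* (present in subsets), and whether the two
groups differ in their evolutionary dynamics — gain/loss turnover on the
species tree, monophyly of the responsible gene families, and prevalence
of the same sugars across the bacterial kingdom.

## The analysis

1. **Genome screening** — genomes are kept when CheckM completeness
   ≥ 90% and contamination ≤ 5%, and when they carry the marker gene
   (a *ppk1*-style family) used to build the species tree; genomes
   falling outside the clade spanned by two reference genomes on the
   rooted marker tree are discarded.
2. **Gene evidence** — HMMER `domtblout` hits are filtered per KOfam
   convention: families with a curated bitscore threshold are judged on
   bitscore; others need e-value ≤ 1e-20 and ≥ 75% profile coverage.
   Families backed by fewer than 200 known sequences are excluded.
   Surviving best hits populate a binary genomes × families presence
   matrix; a family present in ≥ 90% of genomes is a core gene.
3. **Pathway calls** — a reference reaction network (central-carbon
   sources → nucleotide-sugar products, each reaction gated by gene
   families) decides per genome whether a sugar is makeable: some
   source-to-sugar route must be ≥ 75% complete *and* the terminal
   enzyme present. Sugars detected in > 90% of genomes are core.
4. **Gain/loss events** — each sugar's presence pattern is a binary
   character on the species tree; Fitch small parsimony (generalised to
   polytomies with Hartigan majority sets) gives the minimum number of
   gain-or-loss events explaining it.
5. **Monophyly** — within each gene-family tree, the monophyly score is
   the fraction of target-genome sequences covered by the largest clade
   containing only targets (1 = perfectly monophyletic). Families whose
   target LCA has branch support < 80% are excluded.
6. **Group comparison** — core vs accessory groups are compared on event
   counts, monophyly scores, and kingdom-wide prevalence with a
   two-sided permutation test on the difference of group medians
   (100 000 permutations, exact enumeration when feasible).

A synthetic-data generator (`glycopan.simulate`) produces complete
study-shaped inputs — species tree, domtblout files, CheckM table, gene
trees with implanted clades, kingdom-prevalence table, matching network
— with recorded ground truth, so the whole pipeline is testable without
any database download.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
synthetic dataset (everything lands under `results/`):

```bash
python analysis/01_simulate_dataset.py        # seed 0 by default
python analysis/02_screen_genomes.py
python analysis/03_call_pathways.py
python analysis/04_count_events.py
python analysis/05_score_monophyly.py
python analysis/06_permutation_tests.py
```

which prints (seed 0):

```
wrote results/data: 61 genomes (+3 quality decoys), 9 core + 12 accessory sugars, 63 gene trees, seed 0
retained 61 genomes x 63 families; gene labels: {'accessory': 41, 'core': 22}
1281 calls over 21 sugars; sugar labels: {'accessory': 14, 'core': 7}
accessory: median 9.0 gain/loss events (IQR 5.5 - 11.0, n=14)
core: median 0.0 gain/loss events (IQR 0.0 - 0.0, n=7)
accessory: median monophyly 0.72 (IQR 0.55 - 1.00, n=15); 26 families excluded overall
core: median monophyly 1.00 (IQR 1.00 - 1.00, n=22); 26 families excluded overall
gain_loss_events: accessory - core median difference = +9, p = 0.00787
monophyly: accessory - core median difference = -0.2812, p = 0.00019
kingdom_prevalence: accessory - core median difference = -0.6348, p = 0.00124
```

Reading this: the three planted low-quality genomes were screened out;
of 21 simulated sugars the pipeline calls 7 core and 14 accessory (two
core sugars drifted below the 90% prevalence bound in this realisation);
accessory sugars need a median of 9 independent gain/loss events on the
species tree against 0 for core sugars; core gene families are perfectly
monophyletic (median 1.00) while accessory families are scattered
(median 0.72); and all three core-vs-accessory contrasts are significant
at α = 0.01. The same run is available as one command,
`glycopan run --input results/data --out results/run`, and each stage as
a `glycopan` subcommand.

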