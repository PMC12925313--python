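# Methods

## Overview

`glycopan` implements a comparative-genomics workflow for the
biosynthetic potential of nucleotide-sugars in a genus-level genome set:
evidence screening into a binary presence matrix, pathway-presence
inference on a reference reaction network, core/accessory
classification, minimum gain/loss counting on the species tree,
monophyly scoring in gene-family trees, and median-difference
permutation tests between the core and accessory groups. This note
records the models, conventions, defaults, and the choices made where
the design was genuinely open.

## Genome and hit screening

* **Quality bounds.** A genome passes when completeness ≥ 90% *and*
  contamination ≤ 5% (both configurable). A record violating either
  bound is removed; records with completeness outside [0, 100] or
  negative contamination are rejected as invalid rather than silently
  filtered.
* **Hit thresholds.** The KOfam convention: a family carrying a curated
  bitscore threshold keeps a hit iff its full-sequence bitscore reaches
  the threshold, with no coverage requirement; a family without one
  falls back to e-value ≤ 1e-20 combined with profile coverage ≥ 75%.
  "Query cover" is the fraction of the HMM profile covered, because in
  `hmmsearch` the profile is the query: multiple domains of one ORF
  against one profile contribute the union of their profile spans, and
  score/e-value come from the best full-sequence line.
* **Families with thin support.** Profiles backed by fewer than 200
  known sequences (strict `<`) are removed before any hit filtering, to
  avoid calls from poorly supported models.
* **Best hit.** At most one hit per (genome, family): highest bitscore,
  ties broken by lower e-value then lexicographic ORF id so results do
  not depend on input order. Presence in the matrix means ≥ 1 surviving
  hit; requiring multiple ORFs is deliberately not modelled.
* **Core genes.** A family is core when its prevalence is ≥ 90%
  (inclusive); a sugar is core when its detection prevalence is
  strictly > 90%. The asymmetry is intentional and follows the two
  rules' wording; both cutoffs are configurable.

## Pathway presence

The reference map is a directed graph over metabolites whose edges are
reactions gated by gene families — OR across isoenzyme alternatives, AND
within a complex (the standard KEGG-module reading). Sources are the
central-carbon entry points (fructose-6-phosphate, ribulose-5-phosphate,
sedoheptulose-7-phosphate); each sugar names one terminal reaction.

**Completeness** of a sugar in a genome is the maximum over all simple
(cycle-free) source-to-sugar routes of the fraction of route reactions
whose gene requirement is satisfied. On a linear pathway this reduces to
the intuitive "3 of 4 steps = 75%" reading, and it remains well defined
on branched networks. Route enumeration is exhaustive with a depth cap
(default 15 reactions); the bundled network is small enough (45
reactions) that this is instantaneous. An alternative
connected-component reading — completeness 1 iff the sugar is reachable
through present reactions only — is available as
`mode="reachability"`; the route reading is the default because it
degrades gracefully with single missing steps. Completeness counts
reactions, not genes.

**Detection** requires both criteria: completeness ≥ 75% and the
terminal reaction present. Adding a gene to a genome can never decrease
any completeness value (monotonicity; property-tested).

The bundled `data/nucleotide_sugar_network.yaml` transcribes the
standard bacterial nucleotide-sugar map (24 products, 45 reactions).
The KO-to-reaction assignments are curated data, not code; any use
against real genomes should start by reviewing that file. The test
suite never depends on this transcription's biological accuracy — all
pipeline-level tests run on generated networks with known truth.

## Species-tree operations

Trees are read in the FastTree Newick dialect (supports as internal
node labels) via dendropy. Branch supports are indexed by bipartition
(both leaf-set sides of each internal edge) *before* any re-rooting, so
support lookup is immune to the classic support/edge mis-association
that re-rooting introduces.

**Gain/loss counting** uses small parsimony: the minimum number of
binary state changes over all ancestral labelings. The bottom-up pass
assigns each internal node the set of states carried by the largest
number of its children and adds (children − majority) changes per node;
on bifurcating trees this is Fitch's count, and on multifurcations
(which FastTree emits) it attains the true minimum without arbitrary
polytomy resolution. Gains and losses are counted jointly — no root
prior, no gain/loss asymmetry — and the count is invariant to root
placement on binary trees (property-tested against exhaustive
enumeration).

Group summaries report median and interquartile range with
linear-interpolation quantiles, the convention under which quarter
values such as 11.75 arise from integer counts.

## Monophyly

The monophyly score of a target leaf set is the size of the largest
clade consisting exclusively of targets, divided by the target count.
"Clade" is taken in the rooting-invariant sense — each side of each
bipartition of the unrooted topology — so FastTree's arbitrary rooting
cannot change a score. Clades containing any non-target leaf never
count, even if target-dominated. The score always lies in
[1/|targets|, 1] and equals 1 iff the targets form a bipartition side.

The inclusion filter excludes families whose target LCA has support
below 80% (strict). For non-monophyletic targets the LCA depends on
rooting; the tree is midpoint-rooted by default (`as-read` available)
and the LCA's support is looked up by bipartition on the original
topology. When the LCA is the root its support is undefined and the
family is excluded, as are degenerate families whose targets span every
leaf. Support scales are auto-detected (values > 1 anywhere ⇒ 0–100
scale).

## Permutation tests

The statistic is median(accessory) − median(core); the two-sided
p-value is the fraction of label regroupings (group sizes preserved)
whose absolute statistic reaches the observed one. When the number of
distinct regroupings C(n, n_A) fits the permutation budget (default
100 000) all are enumerated and the p-value is exact; otherwise
regroupings are sampled and the add-one estimator (b+1)/(n+1) is used,
which never returns 0 and is mildly conservative. No multiple-testing
correction is applied across the three tests; they are reported
individually.

Note that the |statistic|-based two-sided p-value coincides with the
"twice the smaller one-sided p" convention only when the permutation
null is symmetric (equal group sizes); with unequal groups the two
definitions differ and this package reports the |statistic| version.
Type-I error at α = 0.05 is calibrated to [0.035, 0.065] over 2000
simulated null datasets (tested).

With small integer-valued groups the permutation null of a median
difference is lumpy: heavy ties can place several percent of the null
mass exactly at the observed statistic even when the groups look
cleanly separated. This is a property of the statistic, not an
implementation artefact (verified against scipy's
`permutation_test`), and it is why significance on simulated data
varies more between replicates than the medians themselves do.

## Synthetic data generator

The generator emulates the structure of a genus-level MAG survey with
61 genomes, 9 core and 12 accessory sugars (all configurable):

* **Species tree**: random bifurcating Yule-shape topology, exponential
  branch lengths, supports drawn from a high range (0.90–1.0).
* **Characters**: per-branch flip probabilities (a CFN-style process,
  deliberately not rate × branch length). Core sugars start present at
  the root and are lost with probability 0.005 per branch; accessory
  sugars start absent and gain/lose at 0.08/0.08. Every flip is
  recorded, so parsimony counts can be bounded by the simulation truth.
* **Pathways and evidence**: each sugar owns a linear 3-step pathway of
  dedicated gene families; a genome carrying the sugar carries all its
  genes, a genome lacking it carries each gene independently with
  probability 0.1 (stray homologs). Evidence is written as genuine
  HMMER domtblout text with scores/e-values on the correct side of the
  thresholds, plus sub-threshold noise hits, a planted family with
  fewer than 200 known sequences, and CheckM records including decoy
  genomes that must fail the quality screen.
* **Gene trees**: the genomes carrying a family are implanted as k
  clades (k = 1 for core families, 2–4 for accessory) grafted onto
  pendant edges of distinct background leaves inside one mid-sized
  subtree of a 40-leaf background scaffold. Restricting graft points to
  one neighbourhood mirrors how a genus's sequences occupy a region of
  a kingdom-wide family tree and keeps the targets' LCA a supported
  internal node. Because graft points are distinct pendant edges, the
  construction's monophyly score is exactly (largest clade)/(total
  targets), which tests exploit as an oracle.
* **Kingdom prevalence**: Beta(8, 2) for core sugars, Beta(2, 8) for
  accessory, reproducing the high/low separation the analysis expects.
* **Truth**: `truth.json` records, per sugar, the generative regime
  (`sugar_class`) *and* the class implied by the realised noise-free
  character under the classification rule (`realized_class`). The two
  differ when drift crosses the 90% prevalence boundary (for example a
  single loss on a deep branch removes half the genus); that gap is a
  property of the evolutionary process, not recoverable by any
  classifier, so pipeline correctness is judged against the realised
  class.

All randomness flows from one master seed through named substreams
(CRC32-keyed), so each stage is independently reproducible and repeated
runs are byte-identical.

What the generator does **not** emulate: sequence evolution (no
alignments are simulated), incomplete-genome gene dropout correlated
with CheckM completeness, horizontal-transfer donor lineages, shared
intermediate steps between pathways, and KEGG profile content. Passing
tests therefore demonstrate the correctness of the screening, network,
parsimony, monophyly and testing machinery on data with the study's
*shape*, not the biological accuracy of any particular network
transcription.

## Problem sizes and numerical choices

Simulation-based tests use the full study dimensions (61 genomes,
21 sugars, 63 gene families) across 20 replicate seeds, with 20 000
permutations per test in replicate runs and 100 000 in single showcase
runs. Oracle tests use 200 random trees (≤ 7 leaves for exhaustive
parsimony, ≤ 30 for bipartition enumeration) and exhaustive
2^10 gene-presence grids on a 12-reaction toy network. Floating-point
ties in permutation statistics are compared with a 1e-12 relative
guard; quantiles use linear interpolation throughout; best-hit and
route enumeration are fully deterministic given inputs.

## Known limitations

* The bundled reference network is a curation starting point, not a
  validated annotation source.
* Presence requires a single surviving hit; copy number and operon
  context are out of scope.
* Fitch counting weights gains and losses equally and ignores branch
  lengths; a rate-aware gain/loss model would discriminate deep from
  shallow events but is deliberately out of scope.
* The median-difference permutation test has limited resolution with
  few, heavily tied values per group (see above); medians/IQRs should
  be read alongside the p-values.
* The pipeline consumes the standard outputs of CheckM, prodigal,
  HMMER, MAFFT and FastTree; it does not run them.
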