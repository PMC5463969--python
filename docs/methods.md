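# Methods

## Study design the package models

The pipeline targets paired tumor/normal multi-omics cohorts of the
kind distributed as TCGA-style level-3 tables: gene expression
(RPKM-like), miRNA expression (RPM-like), array methylation beta
values, and segmented somatic copy number for the tumor samples, plus
two external resources supplied as files — a miRNA→target prediction
table carrying the number of supporting algorithms per pair, and a
scored protein–protein interaction edge list. All matrices arrive
already normalised; the package performs no within- or between-sample
normalisation of its own.

Pairing is by patient label: a patient with exactly one tumor and one
normal sample contributes a within-patient difference; unpaired samples
are excluded from differential testing but still used for correlation
analyses, which run over the tumor samples of the full cohort (dosage
and repression are tumor-side relationships, and restricting to the
paired subset would discard most of the correlation power).

## Differential testing

Expression values are tested on log2(x + 1); the pseudocount guards
RPKM/RPM zeros. Methylation is collapsed from probes to genes by
arithmetic mean and tested on log2(beta) (pseudocount 0, since beta
values are strictly positive). This makes the single fold-change
criterion a genuine ratio rule on every layer: a "fold change ≥ 2" for
methylation means the beta value itself at least doubled or halved. An
M-value analysis can be had by passing a pre-transformed matrix with
`log_transform=False`; the package does not take a position on which
scale is preferable.

The test statistic is a moderated paired t: per-feature variances of the
paired differences are shrunk toward a pooled prior estimated by method
of moments from the spread of log sample variances (scaled
inverse-chi-square prior; the prior degrees of freedom d0 solve a
trigamma equation, inverted by Newton iteration). The statistic is
referred to a t distribution with n − 1 + d0 degrees of freedom. Two
limits are exposed for verification and sensitivity analysis:
`prior_df=0` reduces exactly to the ordinary paired t, and
`prior_df=inf` pools all features to one variance. Features constant
across all samples get t = 0 and status `ns` rather than aborting a
run (they are genuinely uninformative); a zero variance combined with
an explicitly zero prior is an error, since 0/0 has no defensible
value. Significance: |log2FC| ≥ 1 (boundary included) and BH-adjusted
P < 0.01 (boundary excluded), the same rule on every layer.

## Copy number

Segment-to-gene assignment takes, per gene and sample, the seg_mean of
the single segment with the largest overlap (ties to the
earlier-starting segment). Single-segment provenance keeps every
gene-level value auditable; a length-weighted mean would blur
breakpoints through genes. SEG coordinates are treated as 1-based
inclusive and gene (BED-like) coordinates as 0-based half-open; both
are converted to half-open internally.

Calls use fixed log2-ratio cutoffs −1.3 / −0.3 / 0.3 / 0.9 (common
SNP6 practice; configurable), with the extreme boundaries inclusive.
Only amplification and homozygous deletion count as significant
changes. Recurrence is a per-gene binomial upper-tail test of the
per-sample alteration count against the cohort-wide background rate of
that state, BH-corrected over gene × state tests, reported at q < 0.01
when the gene's frequency exceeds background. This is a deliberate
simplification of positional recurrence models (no genomic background
model, no arm-level peel-off, no position-dependent q values): the
downstream analysis consumes only gene lists and five-state calls, and
for that purpose a frequency test with FDR control is sufficient and
fully transparent. A zero background with nonzero gene rate uses a
floor of 1/(2·n_samples·n_genes) so the tail P remains defined.

## Integration thresholds

Defaults follow the standard practice for each gate: target pairs need
support from ≥ 3 prediction algorithms; functional miRNA–target pairs
need Pearson r < −0.1 with P < 0.05 over tumor samples; copy-number
candidates need r > 0.5 with P < 0.05 between log2 expression and the
gene's copy ratio. The miRNA candidate set is defined *before* the
correlation gate, with the correlation-restricted functional subset
reported separately, so both the full candidate universe and its
expression-validated core are available. Correlations use
log2-transformed abundances; Pearson on raw right-skewed RPKM-like
values would be dominated by the largest samples. Pairs with a
zero-variance vector yield an undefined-correlation record that is
logged and excluded downstream rather than erroring the run.

## Networks and hub calling

The DEG network is the induced subgraph on differentially expressed
genes with interaction score ≥ 0.4; the score is a confidence filter
only — path computations treat edges as unweighted. Centrality
conventions (matching the common network-analysis tooling): betweenness
sums σ_st(v)/σ_st over unordered pairs excluding the endpoint,
unnormalised; closeness is (n_c − 1)/Σd within the node's connected
component, 0 for isolates. "Top 10" uses dense ranks with ties sharing
a rank and ties at rank 10 included — under ties any drop rule is
order-dependent, while including the tied tail is deterministic and
errs toward sensitivity. Hub eligibility is restricted to candidate
(seed) genes by default, with an unrestricted ranking available for
inspection; whether ranks should be computed over all subnetwork nodes
or only candidates is genuinely open, and ranking over all nodes with
candidate-restricted calls is the stricter combination. The
cross-network rule (degree top-10 in ≥ 2 subnetworks) adds key genes
not already called hubs.

## Synthetic cohorts

Defaults: 60 patients, 30 paired, 2,000 genes, 300 miRNAs, 3,000
methylation sites, 15% DE features (half up, half down), 25 planted
genes per regulatory mechanism, log2 effect 2.0, latent noise SD 0.3,
one seed driving a single `numpy` Generator (no global state). The
paired count and effect/noise scale are chosen to mirror the paired
subsets such cohorts actually contain (tens of pairs, not hundreds)
while keeping the generator fast enough for repeated simulation.

Expression latents are Gaussian on the log2 scale and exponentiated, so
values are non-negative and "fold change" is exact by construction.
Methylation is a logistic squash of a Gaussian latent (bounded in
(0,1)); planted genes move between beta ≈ 0.15 and ≈ 0.6, a ≥ 4-fold
beta change, opposite in direction to their expression shift. Planted
miRNA pairs share a mean-centered latent factor with opposite signs
across tumor samples (repression); planted copy-number genes sit in
their own focal segments whose per-sample dose (≈ +1.2 amp / −1.8
homdel, SD 0.4) feeds mean-centered into the expression latent, so
calls are recurrent and dosage correlation is positive by construction.
When all three planted counts are nonzero, one down-regulated gene is
planted in all three layers (hypermethylated, deleted, targeted by an
up-miRNA), making the triple intersection non-empty.

The PPI graph is an Erdős–Rényi background over the DE genes (plus 100
non-DE genes to exercise the induced-subgraph filter) with key genes
wired to 30 DE neighbors at score ≥ 0.4. A small high-degree tail of 16
non-candidate DE genes with degrees spread over ~16 distinct values is
added because real protein networks are heavy-tailed while a pure ER
graph is not: with dense ranking, an ER degree distribution has so few
distinct values that nearly every degree ranks in the top 10, which
would make the top-k degree cutoff vacuous. The tail restores a
meaningful upper degree spectrum. Algorithm-support counts are uniform
on {1..5} for background target pairs and forced to {3..5} for planted
pairs, so the ≥ 3 filter is exercised in both directions.

What the generator does **not** emulate: count noise and
library-size effects, probe chemistry and probe-level methylation
correlation structure, subclonal or allele-specific copy number,
genome-position-dependent CNA background, and correlated co-expression
modules beyond the planted couplings. Passing tests therefore
demonstrate that the pipeline's logic and statistics are correct under
the stated generative model — not that the thresholds are optimal for
any particular real platform.

## Numerical and degenerate-input choices

BH adjustment validates inputs to [0,1] and preserves input order.
Empty site-to-gene mappings, empty queries and seedless subnetworks
return empty results with warnings instead of raising; malformed GMT
lines and duplicate term ids are hard errors naming the line. Boundary
conventions throughout: fold change and interaction score thresholds
inclusive, P/q thresholds exclusive, CNA extreme-state thresholds
inclusive on the extreme side, functional-pair r strictly below −0.1.
Manifest determinism relies on sorted iteration everywhere sets are
serialised and on hashing the written files themselves.

## Problem sizes used in validation

The test suite and the acceptance script run the default cohort
(2,000 × 90 expression matrix), a matched null cohort, 20 null
replicate seeds for the type-I check, and 50 random graphs of ≤ 30
nodes for the exact centrality cross-check; the full suite completes in
well under a minute on one CPU. These sizes give the planted-recovery
and calibration checks comfortable statistical resolution (e.g. the
null P-fraction check pools 2,000 features) while keeping repeated
whole-pipeline runs cheap.

## Known limitations

The recurrence test ignores genomic position, so adjacent genes in one
focal segment are tested as independent (anti-conservative for long
segments on real data). The methylation fold-change rule on beta values
is scale-sensitive near 0 and 1. Hub calls depend on the degree
spectrum of the supplied PPI network; on very tie-heavy networks the
dense-rank top-10 can be large, and `hub_k` should be read together
with the number of distinct metric values. Enrichment uses a plain
hypergeometric tail over a user-chosen background (default: all genes
on the expression matrix) without GO-graph propagation or
EASE-style score deflation.
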