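# Methods

This note records the models, parameter choices and numerical conventions
behind `amlss`, and what the synthetic validation does and does not
establish about real data.

## Mutated-cell-fraction estimation

Each sequenced read covering a targeted somatic variant is an allele
observation keyed by (cell barcode, UMI, variant). Per-UMI majority voting
suppresses sequencing errors: a UMI with more mutant than reference reads is
called mutated, the reverse reference, and exact ties ambiguous. Ambiguous
UMIs are excluded from all downstream counts — the voting rule itself is the
only error correction applied, matching the assay's design in which each UMI
tags one cDNA molecule whose reads should be unanimous.

For a group of cells the mutated-cell proportion is estimated as
`P = (n_m/(n_m+n_r)) / 0.5`, pooling UMIs over all *heterozygous* variants
in the group. The division by 0.5 is the heterozygous correction: in a fully
mutated population each cell transcribes mutant and reference alleles
roughly equally, so the expected mutant-UMI share is one half. The estimator
assumes no allele-specific expression and is only valid for het sites;
variants are supplied per sample through an explicit het list. `P` is
clipped at 1 because sampling noise can push the raw ratio above it.

Properties worth knowing:

- **Unbiasedness and the clip.** Writing `p̂` for the mutant-UMI share,
  `P = min(1, 2p̂)` is unbiased for the true fraction `f` except near
  `f = 1`, where the clip introduces a negative bias of order
  `sqrt(2/(π n))` for `n` pooled UMIs (≈ 0.06 at n = 50). This is inherent
  to clipping a binomial proportion at its boundary; the acceptance checks
  therefore compare the Monte-Carlo mean against the exact binomial
  expectation of the clipped estimator, computable in closed form.
- **Masking.** Any group supported by 3 or fewer genotyped UMIs is reported
  masked rather than estimated — the same rule the hexagon and
  per-cell-type summaries use for their "too few reads" state. Masking is
  exact by construction: it depends only on `n_m + n_r`.

## Cell-state rules

QC excludes cells with fewer than 200 informative genes or more than 15%
mitochondrial reads; both inequalities are strict, so boundary cells are
kept. "Informative" is implemented as genes with nonzero counts, an
assumption the input conventions document (the rule's source does not define
it further).

The AML-immature relabeling operates on clusters, not cells: a cluster with
strictly more than 80% of its cells from AML samples, in which the combined
share of cells predicted HSC or LMPP strictly exceeds one half, is relabeled
`AML_immature` wholesale. "Majority" is read as combined HSC+LMPP share
rather than plurality, since the two types are named jointly. The rule is
applied after QC and is idempotent. Its failure mode — swallowing a genuine
HSC cluster when normal samples are underrepresented — is real; the
generator counters it by emulating CD34-enriched normal references
(progenitor-rich NBM samples), which is also how such references are built
in practice.

Hexagonal projection uses a pointy-top axial lattice with configurable
circumradius and exact cube-rounding point assignment, so binning is a true
partition of the plane (the grid geometry of the original figures is not
published; the lattice is a parameter). Display semantics: hexagons with
≤ 3 genotype reads are `masked_low_reads`; hexagons not exceeding 0.1% of
the grand cell total are `hidden_low_count`; low-read masking takes
precedence when both apply.

## Expression averaging

Signature derivation operates on per-(sample, cell type) average expression:
cells are normalized to counts-per-10k, averaged on the linear scale per
group, then log2-transformed with a floor at 0.01 (values below the floor
are raised to it before the log). Groups with fewer than 10 cells are
excluded from the average matrix: a mean over a handful of cells is
dominated by detection noise and injects floor-level outliers that inflate
the within-group variance of every downstream t-test. The original
averages come from hundreds of cells per group, where this is a non-issue;
10 cells is the smallest group for which the averages were observed to be
stable in the synthetic cohorts.

## Signature derivation and classification

Stage 1 selects, within each class separately, genes up-regulated in
immature cell types (AML immature, GMP, LMPP) versus mature types
(monocytes, erythroid, dendritic, NK, T, B) by two-sided two-sample t-test
on the group averages, BH-adjusted over all genes; defaults keep q < 2.25e-5
capped at 548 genes for class I and q < 3e-5 capped at 389 for class II.
The t-test uses pooled variance by default (Welch by flag); observations
are the per-sample per-cell-type averages. Stage 2 unions the two
selections. Stage 3 tests each union gene between the classes' per-sample
AML-immature averages, BH-adjusted over the union family only (the
derivation filters "from these gene sets", so the union is the family), and
keeps q < 0.05, split into class-I-up and class-II-up by the sign of the
mean difference. Ranking ties anywhere break lexicographically by gene id.

An optional exclusion then drops genes whose mean linear expression in any
non-immature cell type exceeds half their AML-immature mean — a guard
against cell-type composition leaking into the bulk classifier. The 0.5
ratio is configurable; no published criterion exists. On synthetic cohorts
whose planted genes carry a mild progenitor component the threshold sits
within sampling noise of the true ratio and trims a few genuine genes, so
the recovery validation assesses the statistical stages with the exclusion
off, while the pipeline default keeps it on.

Bulk classification z-scores each signature gene across samples (making
calls invariant to gene-wise affine rescaling) and scores each sample
`s1 − s2`, the difference of its mean z over the class-I-up and class-II-up
lists. A class is called when the margin `|s1 − s2|` reaches 0.4 z-units
*and* the winning list's own mean z is non-negative. The second condition
is a nearest-centroid rejection floor: a blast-poor sample depresses both
signature halves asymmetrically, and a pure margin rule would confidently
assign it to whichever class it is less unlike; with the floor such samples
come out `unclassified`, reproducing the observation that unclassifiable
cases are blast-poor. The margin default (0.4) was sized on the synthetic
cohorts so that samples under ~15% immature content predominantly fail to
reach a call while samples above ~30% are called with high accuracy.
A clustering route (hierarchical clustering on the signature genes with
cluster-level class assignment by mean centroid score) is provided for
parity with heatmap-based assignment.

Hierarchical clustering is agglomerative with 1 − Pearson correlation
distance and average linkage over gene-wise z-scored rows — the settings of
the original tool are unpublished, so these standard heatmap conventions
are fixed and documented. The variance filter keeps genes whose SD across
samples reaches a stated fraction of the largest SD.

## Somatic-variant filtering

The freebayes-style somatic score is the exact four-term contrast
`SSC = T.GL(T) − T.GL(N) + N.GL(N) − N.GL(T)`; it is scale-agnostic in the
likelihoods and antisymmetric under swapping the tumor and normal roles.
Filter thresholds live in a data-driven table; the shipped defaults are the
production values with all `>=` cuts inclusive and the pindel VAF cut
strict. Germline subtraction removes any candidate whose normalized
(left-aligned, minimal, 1-based) key appears in the cultured-skin panel of
*any* patient. Candidate tables are interchanged as TSV; running the
callers, annotation, and copy-number/fusion analysis are out of scope.

## The synthetic-data generator

The generator's job is statistical, not biological, realism: it reproduces
exactly the structure the estimators and classifiers rely on.

- **Counts**: gamma-Poisson (negative binomial, shape θ = 10) around
  per-cell-type centroids; library sizes lognormal around 2000 reads;
  per-sample random effects (σ = 0.15 log2) on every gene.
- **Cell types**: each type has a marker block (5% of genes, +2.5 log2);
  an immature-program block (5% of genes, +3 log2 in HSC, LMPP, GMP and
  AML-immature) models the stemness axis that dominates any
  immature-versus-mature contrast; the AML-immature centroid derives from
  the HSC/LMPP geometric mean plus its own markers, so a normal-marrow
  reference predicts those cells as HSC or LMPP — which is what the
  relabeling rule exploits.
- **Subtypes**: immature fractions are Beta(17,3) for class I (median ≈
  86%) and Beta(2.0,4.2) for class II (median ≈ 30%, range wide), matching
  the blast-rich/blast-poor contrast the classifier must survive. The
  planted 60-gene signature is a stem-program profile (+2 log2 in
  AML-immature cells of both classes, +1 log2 in normal progenitors) with a
  class-specific ±1.5 log2 effect applied *only* in AML-immature cells, so
  the subtype is invisible in mature cells and in composition.
- **Genotyping**: mutated cells emit mutant alleles per UMI as
  Bernoulli(0.5); wild-type cells emit reference; each read flips with
  probability 0.005; whole-cell dropout at 0.53 mirrors the ~47% yield of
  the targeted assay (a per-UMI dropout mode is available, since the true
  dropout mechanism is not known); every AML-immature cell is a clone
  member, differentiated myeloid types partially, lymphoid types not.
- **Mitochondria and QC bait**: the MT- block targets a 7% expected read
  share independent of panel size, and ~3% of cells are emitted low-quality
  (starved library or mito-heavy) so QC has work to do.
- **Bulk**: per-sample pseudobulk (sum of counts, CPM-normalized), so
  composition differences propagate into bulk exactly as they confound real
  cohorts.

All randomness flows from one seed through named child streams; outputs are
byte-identical across runs.

What passing tests show — and don't. The synthetic cohorts have clean
cluster structure, no doublets or ambient RNA, exchangeable cells within a
type, and planted effects that match the derivation's assumptions (e.g.
equal-variance t-tests are exactly correct here). Success therefore
validates the *implementation* of each rule and estimator and the internal
consistency of the pipeline, not the biological adequacy of the rules on
real marrow data. Conversely, failure modes the generator does reproduce —
clipping bias near fully mutated populations, the blast-poor unclassifiable
regime, composition-dominated bulk variance, HSC-cluster capture by the
relabeling rule — are structural, and carry over.

## Problem sizes

Default demonstration scale is 2 classes × 15 samples × 1000 cells × 1500
genes, which exercises all stages in well under a minute each. The
validation suite uses 200 groups × 60 UMIs per point for estimator
calibration, 1000 random tables/vectors for the oracle checks, 100
simulations for null calibration of the signature derivation, and the
demonstration scale for end-to-end recovery.

## Known limitations

- Embeddings, graph clustering and reference-based type prediction are
  consumed as inputs; the centroid label-transfer utility is a deliberately
  simple stand-in for anchor-based transfer.
- Only heterozygous variants are supported by the estimator (no divisor
  other than 0.5), and no allele-specific-expression correction is applied.
- The stage-1 observational unit (averages, not cells) follows the
  derivation's description; deriving from single cells instead would change
  the power calculus materially.
- The 30-gene shortlist requires an existing three-way call set; it does
  not itself define the unclassified group.
- TSV is the interchange format for variant candidates; VCF ingestion from
  specific callers is not implemented.
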