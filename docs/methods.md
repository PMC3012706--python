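# Methods

This note documents the models, conventions and numerical choices behind
`locustexpr`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Counting units and similarity clustering (`seqcluster`, `readcount`)

A *de novo* transcript catalog contains isoforms and recent paralogs as
separate entries; a read from such a gene maps to several of them and is
lost to classical unique-read counting. Transcripts are therefore grouped
into counting units by single-linkage clustering over pairwise similarity
matches: an edge joins two transcripts when one match record has overlap
ratio strictly above the threshold **and** identity strictly above 0.96.
Two presets exist: 0.60 overlap for gene-set deduplication and 0.80 for
expression units (the stricter overlap keeps paralogs with partial
overlap apart, so cluster-level counting does not conflate genes).

* **Overlap-ratio denominator.** The overlap is divided by the *shorter*
  of the two sequences, so a short isoform fully contained in a longer
  one scores near 1. This matches the calibration of the thresholds
  against isoform-pair overlap quantiles; the longer-length denominator
  is available (`denominator="longer"`) for sensitivity analysis.
* **Duplicate records.** A→B and B→A records are judged independently;
  the pair links iff *any* record passes both thresholds. Merging field
  maxima across records could manufacture an edge no observed alignment
  supports.
* **Representative.** The longest member, ties broken by smallest id;
  the cluster (and counting unit) is named after it.

Counting rule: a read whose hits all lie inside one unit contributes one
count to that unit; a read whose hits span two or more units is
discarded and tallied separately (assigned + discarded = total, per
library). Counts live at the unit level — the share of an intra-cluster
multiread among members is unidentifiable without a reference, and
unit-level counting keeps the library total N free of double counting.
Member transcripts inherit their unit's count at RPKM time, each
normalized by its own length. "Detected"/"expressed" means assigned
count ≥ 1 throughout (markers, PCA filter, lane-detection summaries);
no RPKM floor is imposed.

Deeply sequenced paired-end libraries are represented by one randomly
selected lane (seed-controlled) wherever they enter cross-library
analyses, keeping them exchangeable with one-lane single-end libraries;
their full depth is used only in the dedicated deep-pair comparison.

## Normalization (`normexpr`)

TMM (trimmed mean of M-values) is computed exactly as published: genes
with a zero count in either library are dropped; M = log₂ relative-
abundance ratio and A = mean log₂ relative abundance are each trimmed
symmetrically (30% on M, 5% on A, by ranks); the factor is 2 to the
precision-weighted mean of the surviving M, with delta-method weights
(N−c)/(Nc) summed over the two libraries. The implementation is verified
against an independently written rendering of the formula and against
`edgeR::calcNormFactors` (agreement ~10⁻⁷ in the tests).

Factors are reported with the reference library at f = 1 exactly
(`renorm="ref"`, default); the common geometric-mean-1 convention is
available as `renorm="geomean"`. The choice multiplies every factor by
one constant, which cancels from every cross-library ratio the pipeline
computes, and is recorded in the normalization table.

The effective library size is N_eff = N·√f — deliberately the square
root, not the plain product common in factor-times-size conventions;
this is the pipeline's defining convention and every downstream RPKM
uses it. RPKM(t, lib) = count / ((L_t/10³)·(N_eff/10⁶)); zero count
gives RPKM exactly 0.

## Differential expression (`diffexpr`)

The Audic–Claverie posterior for the second library's count y given the
first library's count x, with size ratio r = N₂/N₁, is

p(y|x) = r^y Γ(x+y+1) / (Γ(x+1)Γ(y+1)(1+r)^(x+y+1)),

a negative binomial in y with size x+1 and success probability 1/(1+r)
for integer x. Two adaptations for reference-free RNA-seq: x and y are
*reads per kilobase* of the transcript (expected counts scale with
length), and in a series of pairwise comparisons N₁, N₂, x and y are all
rescaled to the smallest library in the series, equalizing statistical
weight across depths (after rescaling r = 1). The stricter deep-pair
cutoff (FDR < 10⁻⁵ vs 10⁻²) exists precisely because deeper libraries
give the statistic far more power; the test suite reproduces the
more-reads-more-calls ordering.

Numerical choices:

* Real-valued x, y via the Γ form; tails via the continuous extension of
  the negative-binomial survival function, the regularized incomplete
  beta I_q(y, x+1) with q = r/(1+r). Closed form, term-by-term summation
  and 10⁶-draw simulation agree within 10⁻⁹ / 3 Monte-Carlo SE.
* Two-sided p = min(1, 2·min(lower, upper)) with both tails inclusive of
  the observed value. This construction conditions on x and is **not**
  exchange-symmetric (the posterior's size parameter follows the
  conditioning count; the discrepancy can reach several-fold at small
  counts). The reported p is the maximum over the two conditioning
  orientations: exactly symmetric under swapping the libraries,
  conservative, and identical to the one-orientation value in the
  reference cases (p = 1 at equal counts; p = ¼ for 0 vs 3 at r = 1).
* p-values are floored at 10⁻³⁰⁰ (the beta tail underflows for extreme
  deep-pair count differences), keeping them in (0, 1].
* FDR: Benjamini–Hochberg step-up (via statsmodels). Fold change is the
  ratio of TMM-adjusted RPKM; when exactly one side is zero a pseudo-RPKM
  ε = 10⁻³ is added to both sides so presence/absence units remain
  callable. Units with zero counts in both libraries are not tested.
* Under its own sampling model (Poisson), the caller's null rate at
  q < 0.01, fc > 2 stays below 1% and a planted 4-fold effect at deep
  sizes is recovered with precision and recall ≥ 0.99. Under
  negative-binomial extra-variation the test — like the original — has
  no dispersion term and over-calls at high depth; this is a property of
  the method being reimplemented, not a defect of the implementation,
  and modern dispersion-based testing is explicitly out of scope.

## Marker screens (`markers`)

Phase-specific screen (all six stages): flagged toward a phase iff
detected in ≥ 5 of its 6 stages and undetected in ≥ 4 stages of the other
phase. The two directions are mutually exclusive by counting.

Stable-difference screen (five post-egg stages; eggs excluded exactly as
specified): coefficient of variability sd/mean (sample sd, ddof 1) below
0.3 within the phase groups, larger/smaller mean ratio above 1.5, and
two-sided Welch t-test p < 0.05 (Welch chosen because the groups have
n = 5 and no variance-equality guarantee). The published wording "CV < 0.3
within gregarious phase group **or** solitary phase group" is ambiguous;
`cv_mode="both"` (default) requires both groups stable — a transcript
varying wildly in one phase is a poor stable marker — while
`cv_mode="either"` implements the literal reading. Units with a zero
group mean are skipped with a logged reason. Overlapping calls from the
two screens are reported with an `overlap` flag, never dropped.

## Enrichment (`enrich`)

GOstat-style 2×2 per term: the gene list versus the background *minus*
the list (so the list cannot contaminate its own reference). Pearson
chi-square with 1 df and no continuity correction, unless any expected
count under independence is below 5, in which case the two-sided Fisher
exact test (point-mass rule: sum of all tables with probability ≤ the
observed) is used. Raw p-values are reported at the stated α (no
cross-term correction, matching how such scans are conventionally
reported); BH correction is available behind `correct=True`. A direction
flag marks enrichment vs depletion since the two-sided p alone does not.

## Library PCA (`multivar`)

Transcripts detected in fewer than 6 libraries are removed; each
surviving transcript's RPKM profile is standardized to zero mean, unit
variance across libraries (zero-variance rows dropped — standardization
undefined); the SVD of the resulting libraries × transcripts matrix gives
library scores, transcript loadings and variance fractions, equivalent to
the eigen-decomposition of the library covariance of standardized data
but computed on the small side. Signs are fixed (largest-|loading|
positive per component) for determinism. On the synthetic 12-library
design the stage effect dominates: stage groups separate on the leading
components and phase only on a later one, reproducing the qualitative
structure of the study design the generator emulates.

## Assembly QC (`asmqc`)

Length bins are half-open [100, 500), [500, 1000), [1000, 2000),
[2000, ∞) (bins are exhaustive: anything below 500 falls in the first
bin). N50 is the length at which the descending cumulative sum first
reaches half the total; it is always one of the input lengths and is
order-invariant. Coverage evaluation uses 1-based inclusive intervals
and per-base depth; a reference qualifies when its covered fraction at
depth ≥ d strictly exceeds the cutoff (defaults d = 2, 0.9). With d = 1
the covered set equals the union of alignment spans, so both the
read-depth and span-based evaluation modes are the same parameter. The
mismatch rate is total mismatches over total bases covered at depth ≥ 1.
Chimera flagging requires ≥ 2 *distinct* subject proteins each passing
identity > 0.3, e-value < 10⁻¹⁰, score > 200; no positional separation of
the hits is required.

## Synthetic data (`simdata`)

The generator defines the study conditions; its defaults were fixed once:

* **Design**: 12 libraries (G/S × six stages); the 4th-instar pair (G4,
  S4) at 20× depth spread over 20 lanes, so one lane ≈ one shallow
  library, mirroring the one-lane down-sampling rule.
* **Counts**: negative binomial with variance μ + φμ² (φ = 0.05 default;
  φ = 0 is Poisson). Mean = baseline × stage factor × phase fold ×
  library scaling × depth. Baseline ≈ 10 expected reads/kb at depth 1
  (log-normal, σ = 1, floored at 3 reads so "expressed" units are
  reliably detected in a single lane); per-library scaling log-normal
  σ = 0.1.
* **Stage effect**: a log-normal factor (σ = 0.6) per unit × stage,
  *shared between phases* — developmental modulation is common to both
  phases, which is what makes stages dominate phases in PCA.
* **Phase effect**: 10% of units get a fold growing with stage
  (1.5, 2, 2.5, 3, 3.5, 4 from egg to adult), direction random; this
  yields the increasing phase divergence across development.
* **Markers**: 32 phase-specific units (mean exactly 0 in the off phase,
  ≥ 10 expected reads in the on phase) and 8 stage-flat stable units at
  2.5-fold with high abundance — roughly the 4:1 specific:stable
  composition the screen families show in practice. Stable markers are
  stage-flat by construction; that is their defining property.
* **Composition bias**: 50 very-high-abundance units (8-fold) in the
  gregarious phase, the canonical TMM stressor; they are recorded in the
  truth as genuine differential expression.
* **Clusters**: planted cluster members are chained by match records
  with overlap ratio 0.85–0.99 of the shorter member and identity
  0.965–0.995, so the expression preset reconstructs the planted map
  exactly; sub-threshold decoy matches (identity ≤ 0.95) are added and
  must not create edges.
* **Alignments**: one record per simulated count; a read from a
  multi-member cluster gains a second in-cluster hit with the
  intra-cluster multimap rate, and a spurious out-of-unit hit with the
  cross-cluster noise rate. At rates (0, 0) the counting layer
  reproduces the generating counts exactly; every cross-noise read is
  discarded by construction of the counting rule.
* **Annotations**: terms assigned independently of DE status except one
  planted term whose membership probability is multiplied by the
  enrichment factor for DE units.

Everything is deterministic given a seed (numpy `SeedSequence`-derived
streams per operation).

What the generator does **not** emulate: base-level read sequences,
quality scores or mapping errors; positional coverage biases;
correlated gene-gene expression structure; GC/length biases beyond the
explicit length proportionality; isoform-specific expression within a
cluster. Passing tests therefore demonstrate correctness of the
computational pipeline under its stated model, not robustness to every
artifact of real libraries.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run the stochastic conditions
at desk scale, chosen as the smallest sizes at which the measured
quantities are stable: 5,000-unit pairs × 10 seeds for null rate and
power, 2,000-unit 12-library designs × 10 seeds for marker recovery,
100 replicates for enrichment power, 200-node graphs for the clustering
oracle, and a ~1,000-unit end-to-end run (the full-study scale — tens of
millions of reads — is neither needed nor appropriate for validating the
algorithms). The acceptance script derives all sub-seeds from `--seed`
and completes in about a minute; repeated pipeline runs at a fixed seed
produce byte-identical output bundles (run logs carry timestamps and are
excluded from that guarantee).

## Known limitations

* The Audic–Claverie statistic has no dispersion parameter; at great
  depth it declares small relative differences significant. The
  fold-change cutoff mitigates but does not remove this.
* Unit-level counting cannot apportion multireads among cluster members;
  member RPKM inherits the unit count and over-states members that are
  individually silent.
* The stable-marker CV screen at φ = 0.05 sits close to its 0.3
  threshold (a five-point sample CV of an NB profile with true CV ≈ 0.23
  crosses 0.3 about a quarter of the time per group), which bounds the
  screen's recall; this is a property of the published thresholds.
* The pipeline's stage orchestration assumes the 12-library design's
  library ids for the per-stage comparisons; the library API has no such
  assumption.
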