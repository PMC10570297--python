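# Methods

## Scope and data model

`cnvrpop` operates downstream of a read-depth CNV caller. Its unit of input
is the caller's per-sample call record: type (deletion/duplication),
1-based inclusive coordinates, size, normalized read depth (RD; per-region
depth divided by the sample's genome-wide mean, so diploid ≈ 1.0), a
significance column interpreted as a t-test p-value plus three further
significance columns carried opaquely, and q0, the fraction of
zero-mapping-quality reads in the region. Copy number stays on the
normalized-RD scale throughout the package; the deleted/conserved/duplicated
thresholds 0.4 and 1.6 (Redon et al.'s convention) only make sense on that
scale, and the simulator never uses an absolute two-copy scale.

Coordinates are 1-based inclusive in every in-memory type and every TSV;
BED outputs are 0-based half-open and say so in their headers. Lengths are
`end − start + 1` everywhere.

## Quality filter

A call is retained iff p < 0.01 AND size > 1 kb AND q0 < 0.5 — all three
inequalities strict, as conventional for this filter. q0 = −1 is the
caller's sentinel for "no reads to assess"; it is treated as missing and
retained by default (discarding would silently drop calls in low-coverage
regions), switchable via `FilterSpec.keep_missing_q0`. The first
significance column is the filter p-value; using a later column is a
one-line change in `read_calls` if a caller orders them differently.

## CNVR merging

CNVRs are the connected components of the ≥ 1 bp overlap relation among
filtered calls on one chromosome (transitive closure), spanning the union
envelope. Book-ended calls share no base and are not merged. The merge is a
single sorted sweep, deterministic, idempotent and order-independent; every
filtered call lands in exactly one CNVR. A minimum-overlap fraction
(relative to the shorter of call and growing envelope) is available but
defaults to 0, since plain overlap is the standard construction;
order-independence is only guaranteed at the default.

A CNVR is typed `both` iff its supporting calls include at least one
deletion and one duplication, so duplication + deletion + both counts
partition the CNVR set. Per-group CNVR tables re-run the merge within each
group's samples: group-wise counts cannot be derived from a single global
merge because a region may be contiguous across the cohort yet fragmented
within one group. Both modes are exposed; global is the default.

## Genotyping

Call mode (default): a sample's CN over a CNVR is the overlap-length-
weighted mean of its calls' normalized RD, with uncovered bases
contributing 1.0 (diploid) and no evidence at all giving exactly 1.0. If a
sample's own calls overlap (callers normally emit disjoint calls), shared
bases are counted once, attributed to the call that sorts first by
(start, end). Depth mode: mean binned depth over the CNVR divided by the
sample's genome-wide mean bin depth; a CNVR outside the track extent is an
error rather than a silent 1.0. The matrix is complete by construction — a
value for every CNVR × sample.

## Vst

With group sizes nᵢ, V_T the variance of CN across all N individuals and
Varᵢ the within-group variances,

    V_S = Σ nᵢ·Varᵢ / Σ nᵢ ,   Vst = (V_T − V_S) / V_T ,

defined as 0 when V_T = 0. Population (denominator N) variances with nᵢ
weights are the default — the standard construction for this statistic.
Under that convention the law of total variance gives V_T = V_S +
between-group variance, so Vst ∈ [0, 1]. A sample-variance convention
(denominator N − 1, weights nᵢ − 1) is switchable for sensitivity checks;
it can go negative, and negative values are reported unclamped because
clamping would distort the top-quantile threshold.

Candidate selection: with n CNVRs and fraction f (default 0.01), the
threshold is the k-th largest Vst with k = ⌈f·n⌉, and every record with
Vst ≥ threshold is a candidate — so ties at the threshold are included and
"top 1%" is well defined even for small n. Group contrasts (e.g. pooled
high-altitude vs low-altitude breeds) are user configuration, not
hard-coded; the default scan treats every group as its own stratum.

The qPCR-validation arithmetic is included as `ddct_quantity`: relative
copy number 2^(−ΔΔCt) with ΔΔCt = (Ct_target − Ct_ref)_test −
(Ct_target − Ct_ref)_calibrator.

## Annotation

Gene models come from GFF3 via `gffutils`; exons attach to genes through
arbitrary Parent chains (typically gene → mRNA → exon), orphan exons and
missing strands are errors, overlapping exons are merged, and a gene
without exon children is treated as a single exon spanning its body (the
conservative choice: overlap with it is exonic). Classification precedence
is exonic > intronic > upstream > downstream > intergenic per CNVR —
fractions are per-region, not per-base. Upstream/downstream are
strand-aware flanks of `flank_bp` (default 1900 bp, i.e. 1.9 kb; 1 kb is
the more common annotator default, so the value is a parameter on every
interface). A CNVR that is upstream of one gene and downstream of another
resolves to upstream by the precedence rule. Shrinking the flank can only
move flank-classified regions to intergenic (monotonicity; tested).

## Synthetic cohorts

The generator emulates the statistical structure the downstream stages
assume, not sequence-level reality:

* **Truth.** Each locus carries a categorical distribution over normalized
  CN states per group; each sample draws independently from its group's
  distribution. Individuals are unrelated — within-breed relatedness is not
  modelled.
* **Calls.** Every non-diploid (sample, locus) yields one call at the locus
  coordinates with RD = CN + Gaussian jitter (sd `rd_noise_sd`, truncated
  at 0) and passing quality statistics; `junk_call_rate` × (signal count)
  extra calls are planted per sample, each failing exactly one filter
  criterion (cycling p-value / size / q0) so filter tests can attribute
  removals. A sidecar labels every record.
* **Depth.** Poisson per 100-bp bin with mean `mean_coverage` × CN — no
  overdispersion, GC or mappability structure. This is deliberately the
  simplest model that exercises depth-mode genotyping; passing tests say
  nothing about GC-driven artefacts in real tracks.
* **Genes.** Loci cycle through the five region classes; the generator
  places a gene (strands alternating) realizing each class — exon over the
  locus, intron around it, or a gene 1 kb away on the strand-appropriate
  side — and no gene near intergenic loci. Loci must be spaced further
  apart than twice the largest flank in play (the default layout uses
  60 kb) so placements cannot contaminate neighbours.
* **Determinism.** One global seed; per-sample, per-stage substreams are
  derived from it (`default_rng([seed, stage, sample_index])`), so outputs
  are byte-identical across runs and insensitive to emission order.

Defaults mirror a small multi-breed resequencing design: seven groups of
four samples (six breeds, one split into polled and horned flocks),
`mean_coverage = 20` reads per 100-bp bin (the centre of the 16.75–23.08×
range typical of such cohorts), `rd_noise_sd = 0.05`, and
`junk_call_rate = 0.1` — roughly one obviously bad call per ten real ones,
a realistic contamination level for a read-depth caller before filtering.

The analytic counterpart `expected_vst` computes the population-level Vst
implied by the configured distributions (pooled-mixture variance vs
size-weighted within-group variance); empirical Vst from generated truth
converges to it, and the test suite checks mean absolute error < 0.05 at
100 samples per group over 20 replicate loci.

## Problem sizes and numerics

The test suite and acceptance script run the scan-power experiment at
1000 loci × 28 samples (10 planted at expected Vst ≈ 1 against a shared
polymorphic background), the recovery experiment at 200 samples × 20 loci,
and the oracle comparison on 1000 random small inputs at 1e-12 tolerance —
sizes chosen so the entire suite completes in seconds while leaving the
planted/background Vst separation far larger than sampling noise.
Percentages in report tables are rounded half-up to two decimals, matching
the conventional table style; the exact quotient is used everywhere
upstream of formatting. Probability vectors are validated to sum to 1
within 1e-9 and renormalized before sampling to absorb that slack.

## Known limitations

* Call mode genotypes only what the caller reported; a CNV the caller
  missed looks diploid. Depth mode exists precisely to cross-check this.
* No significance testing of Vst (permutation p-values) and no smoothing
  across adjacent CNVRs; the scan is a pure empirical-quantile screen.
* The merge has no reciprocal-overlap notion by default; a single long
  noisy call can bridge two biologically distinct events.
* GO/KEGG enrichment of CNVR genes is out of scope (database-dependent,
  external services); the package stops at per-CNVR gene lists and
  shared/group-specific set counts.
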