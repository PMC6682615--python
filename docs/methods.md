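# Methods

## Scope and assumptions

`gliodist` models a multi-region biopsy study design: per patient, 2–6
physically localized tissue samples with stereotactic image coordinates in
mm, each profiled by whole-exome variant calling, CNV segmentation and a
methylation beta-value array. The package starts *after* the upstream
bioinformatics (alignment, somatic calling, annotation, segmentation,
array preprocessing): its inputs are annotated variant tables (or
pre-split single-sample VCFs), CNVkit-style `.cns` segment files, and a
probes × samples beta matrix. All comparisons are intra-patient; the
pooled association treats pairs from different patients as exchangeable
points on a common line, which is an explicit modeling simplification
(see Limitations).

Coordinates are assumed to be in a common image frame per patient with
measurement error small relative to inter-site distances (a few mm at
most); no registration or brain-shift correction is attempted.

## Spatial pairs

Pairs are enumerated exhaustively within each patient. Three pair kinds
exist:

* `coordinate` — Euclidean distance of the two coordinate triples;
* `shallow_deep_needle` — the two ends of one divided needle core, fixed
  at `shallow_deep_mm` (default 5 mm, from the 0.9 mm × 10 mm side-port
  needle geometry). The constant is configurable because it is a property
  of one instrument, not of the mathematics;
* `same_site_forceps` — a shallow/deep pair taken with forceps at one
  location. No geometric constant exists for this case; the default
  distance is 0 mm (the only coordinate-consistent value) and such pairs
  can be excluded from association entirely (`exclude_same_site_forceps`).

Samples lacking a complete coordinate triple are kept in the cohort but
excluded from coordinate pairs; partial triples are flagged, not repaired.

## Mutation distance

The five retention criteria (exonic region; frameshift deletion/insertion,
nonsynonymous SNV, stopgain or stoploss; reference reads ≥ 10; alternate
reads ≥ 8; alternate AF ≥ 0.1) are applied conjunctively with a
per-criterion rejection tally. Mutation identity is (chrom, pos, ref,
alt); gene symbols are annotation only. When a provided `alt_freq`
disagrees with the read counts beyond 1e-6 the provided value wins with a
warning, since counts may cover a different read subset than the caller's
AF estimate.

The continuous Jaccard (Tanimoto) distance is 0 for identical AF vectors
and 1 for disjoint supports; the degenerate all-zero/all-zero case is
defined as 0 (identical profiles) with a warning. On binary vectors the
formula reduces to the set Jaccard distance, which the tests verify
exhaustively up to length 6. The distinct-mutation count (union minus
shared) is computed per pair as well and is the default mutation-modality
input to the spatial regression, putting the fitted slope on a
counts-per-mm scale; the Jaccard value is retained in the same table for
correlation on the normalized scale.

Hypermutation flagging is advisory: a sample is flagged when its filtered
count exceeds max(absolute_threshold = 300, fold_threshold = 10 × cohort
median). The literature-derived exome-wide background (≈1 mutation/Mb ×
30 Mb = 30) is reported alongside for context. Exclusion is an explicit
opt-in (`exclude_hypermutated`), mirroring how such samples are removed
only after case-level review.

The sharing tree partitions mutations by their presence pattern across
samples. The all-samples pattern forms the trunk from the root "N"
(normal, zero mutations); non-singleton patterns attach greedily in
decreasing size order to the deepest strictly-containing placed node;
singleton counts become the leaf branch lengths. Patterns that overlap
without nesting cannot be drawn on a tree — they are attached to the
deepest compatible ancestor and reported, not silently resolved. This
greedy rule is our convention: with more than three samples the tree is
not uniquely determined by the patterns alone.

## CNV distance

Per patient, the union of all samples' segment start/end positions defines
the coarsest common refinement; intervals covered by at least one sample
become events, and each event inherits the log2 of the unique covering
segment per sample (no interpolation). Events a sample's segmentation does
not cover are excluded *pairwise* (pairwise-complete analysis) rather than
imputed; `impute_neutral` treats them as log2 = 0 instead, which is the
appropriate reading for whole-genome tilings where absence means "no
call".

The Canberra distance uses |P| + |Q| in the denominator. The classical
Canberra form divides by P + Q, which is ill-defined for signed log2
ratios (the denominator can be zero or negative for informative events);
the magnitude form coincides with it on non-negative data — the regime the
tests cross-check against the reference implementation — and guarantees
each term lies in [0, 1] with self-distance exactly zero. Terms with
|P| + |Q| = 0 contribute 0. Events with identical log2 in both samples
contribute nothing, so "flat" columns carry no information, as expected.

Coordinates are 0-based half-open (BED/CNVkit convention). Sex chromosomes
are included by default (`drop_sex_chroms` to exclude). The breakpoint
union is per patient, since distances never cross patients; a cohort-wide
union can be obtained by passing all patients' segments to
`union_breakpoints` directly.

## Methylation distance

QC order is fixed and idempotent: samples with strictly more than 10% of
probe values missing are dropped first, then probes with strictly more
than 3 missing values among the retained samples. Both thresholds are
strict inequalities by convention.

Probe selection is deterministic: MAD ranking (cohort level, for
clustering/embedding use) and variance ranking (within each patient, for
distance) both exclude probes with any missing value in the relevant
sample set and break ties lexicographically by probe id. Variance uses the
n−1 denominator (`ddof=1`); with 2–6 samples per patient the choice is
material and is configurable. Because the top-k selection is per patient,
L1 distances are comparable across patients only through the common k
(default 500); each distance lies in [0, k].

## Association

Pearson r with the two-sided t-transform p-value and the least-squares
line are computed on the pooled intra-patient pairs per modality
(scipy's `pearsonr`/`linregress` under the module surface, cross-checked
in the tests against explicit covariance-sum and normal-equation
oracles). Fewer than 3 pairs yields a null result flagged
`insufficient_n`. No multiple-testing correction is applied across the
three modalities.

Derived equivalences: per_10mm = 10·slope and mm_per_unit = 1/slope
(undefined, reported as NaN, for slope 0). Presentation rounding is one
decimal place, with two decimals for magnitudes below 0.2 so that small
constants keep two significant digits (1/6.8 reports as 0.15, not 0.1);
raw values are always retained in the machine-readable output.

Within-patient pairs share samples and are not independent. The pooled
analysis is the package's default because it matches how such cohorts are
conventionally summarized; a patient-level permutation p-value (genomic
distances shuffled within patients) is available as an optional robustness
output and is clearly marked as an extension.

Optional stratification columns (e.g. IDH status, 1p/19q) are carried
through `assemble_records` and produce per-level subgroup correlations in
the report; no significance claims are attached to them.

## Synthetic cohort generator

The generator emulates the study geometry and the qualitative structure of
the three data layers; it is not a tumor-growth simulation.

* **Geometry.** Sites uniform in a sphere of `tumor_radius_mm` (default
  30 mm, matching observed 5–20+ mm pair separations); a configurable
  fraction of needle sites (default 0.5) splits into shallow/deep
  sub-samples exactly 5 mm apart.
* **Mutations.** `n_truncal` (default 10, matching the canonical
  three-sample example) truncal mutations drawn once per patient — one
  AF and read-count draw shared by all samples, so a cohort without
  subclones has exactly zero mutation distance — plus "seeded subclone
  spheres": random 3D centers with radii 0.15–0.6 of the tumor radius,
  carried by the samples inside them at lower AF (private 0.20 vs truncal
  0.40 mean), which reproduces the observed trend of shared mutations
  having higher AF than private ones. Rates (0.3 subclones per mm of
  radius, 1 + Poisson(3) mutations each) were set so per-sample burdens
  land near the reported ~20 mutations per biopsy and far pairs
  accumulate tens of distinct mutations. Read counts are constructed to
  satisfy all five filter criteria; labeled decoys violating exactly one
  criterion each (cycling through the five) can be mixed in at
  `decoy_fraction` to validate the filter against construction labels.
* **CNV.** A patient-level base segmentation (≈40 segments over four
  model chromosomes, log2 0 with probability 0.4 else N(0, 0.4)); sample
  deviations are drawn jointly per segment from a Gaussian field whose
  per-sample sd grows with distance from the tumor center
  (`perturbation_sd_per_mm`, default 0.01/mm) and whose cross-sample
  correlation decays with separation (squared-exponential, length scale
  10 mm). Occasional sample-specific breakpoints (probability 0.2 per
  segment) exercise the union step.
* **Methylation.** A bimodal base beta profile per probe (Beta(1,9) /
  Beta(9,1) mixture); per-sample deviations from a squared-exponential
  Gaussian field over the site coordinates (sd 0.5, length scale 10 mm)
  are added on the logit scale and mapped back through the logistic
  function, so values respect [0, 1] without clipping artifacts. Missing
  values are injected at rate 0.005.

Each patient uses RNG streams derived from (master seed, patient index,
layer), so cohorts are bit-reproducible and extensible without perturbing
existing patients.

What the generator does **not** emulate: selection, tumor growth dynamics
and clonal phylogenies; array probe chemistry and batch effects; purity
and ploidy variation; read-level noise. Passing tests on synthetic
cohorts therefore demonstrate the pipeline's correctness and the direction
of its spatial trends, not performance on real tumors. Two known shape
caveats: the sphere process saturates — the mean distinct-mutation count
flattens for separations beyond the subclone length scale — and the
pooled mutation correlation on small mechanistic cohorts is weak (r ≈
0.1–0.4), because subclone membership is highly stochastic at realistic
rates.

A separate direct generator, `simulate_distance_pairs`, draws (distance,
genomic distance) pairs straight from a target line y = a + b·x plus
Gaussian noise truncated at 0, and `simulate_linear_cohort` pools such
draws over a multi-patient layout. Its default targets are the published
regression lines (slopes 1.7 / 6.9 / 0.18 with intercepts −11.6 / −93.8 /
5.27). Because truncation at 0 biases least squares wherever the line mean
approaches 0, each modality's x-range is restricted to the regime where
a + b·x stays well above 0 (mutation 10–30 mm, CNV 16–30 mm, methylation
5–30 mm), and the noise sds (3 / 10 / 0.5) are small enough for the pooled
fit to identify the slope precisely; realistic cohort-level scatter is the
mechanistic generator's job, not this one's.

## Problem sizes and determinism

The test suite runs mechanistic cohorts of 4–10 patients with 300–2000
probes and the linear recovery on a 25-patient layout (~500 pairs pooled
over replicates in the acceptance script); the full suite completes in
well under a minute. All stochastic tests use fixed seeds; hypothesis
profiles are derandomized. Pipeline outputs are byte-stable for a given
config: tabular floats are written at fixed precision, and the report
carries a config hash, the package version and the seed.

## Known limitations

* Pooled inference ignores within-patient dependence; the permutation
  option mitigates but does not remove this.
* The sharing-tree convention is one of several defensible rules for > 3
  samples; incompatible patterns are reported rather than resolved.
* Methylation distances depend on the per-patient probe selection and are
  not directly comparable across patients.
* The Canberra magnitude-denominator convention differs from the
  classical P + Q form on signed data; users comparing against other
  implementations should check which form those use.
* VCF ingestion accepts only pre-split, single-ALT records and
  ANNOVAR-style INFO keys.
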