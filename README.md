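# gliodist

Spatial–genomic distance analysis for multi-site tumor biopsy cohorts.

Diffuse gliomas are genetically heterogeneous within a single tumor: two
biopsies from the same lesion can differ in their somatic mutations, copy
number profile and methylation state. `gliodist` quantifies how that
molecular divergence grows with the *physical* separation of the biopsy
sites. It is aimed at researchers working with stereotactic multi-region
biopsy data (image coordinates plus whole-exome variant calls, CNVkit-style
segmentations and methylation-array beta values) who want the
spatial–genomic relationship as a set of reproducible numbers rather than a
figure.

## The model

For biopsy sites *i*, *j* with image coordinates (x, y, z) in mm, the
spatial distance is Euclidean:

    d_ij = sqrt((x_i - x_j)^2 + (y_i - y_j)^2 + (z_i - z_j)^2)

A needle core divided into a "shallow" and a "deep" sub-sample is assigned a
fixed 5 mm separation derived from the needle geometry. Pairs are always
intra-patient — samples are never compared across tumors.

Three genomic distances are computed per intra-patient pair:

* **Mutation (Jaccard/Tanimoto).** Somatic calls are filtered by five
  criteria (exonic; frameshift indel / nonsynonymous SNV / stopgain /
  stoploss; reference reads ≥ 10; alternate reads ≥ 8; alternate allele
  frequency ≥ 0.1), assembled into a per-patient mutation × sample AF
  matrix, and compared by

      d_Jaccard = Σ(P_i − Q_i)² / (ΣP_i² + ΣQ_i² − ΣP_iQ_i)

  where P, Q are the two samples' AF vectors (0 where a mutation is
  absent). The distinct-mutation count |A△B| is reported alongside, and
  samples with outlier burden (vs. the ~30-mutation exome-wide background
  expectation) are flagged as hypermutation candidates. A sharing tree
  (trunk = mutations in all samples, tips = private mutations) is emitted
  as Newick.

* **CNV (Canberra).** All samples' segment breakpoints are pooled into the
  coarsest common refinement ("CNV events"); each event inherits the
  covering segment's log2 copy ratio, and pairs are compared over their
  shared events by

      d_Canberra = Σ |P_i − Q_i| / (|P_i| + |Q_i|)

  (0/0 terms contribute 0, so self-distance is exactly zero; magnitudes in
  the denominator keep the metric well-defined for signed log2 ratios).

* **Methylation (L1).** After QC (drop samples with > 10% missing values,
  then probes with > 3 missing values), the 500 most variable probes
  *within each patient* are selected and pairs compared by the total
  variation d_L1 = Σ|P_i − Q_i|. Cohort-level MAD ranking is provided for
  clustering/embedding workflows.

Per modality, pooled (d_ij, genomic distance) pairs are summarized by the
Pearson correlation (two-sided t-transform p) and the least-squares line
`genomic = a + b·d_ij`, from which two equivalence constants are derived:
the genomic distance accrued per 10 mm (10b) and the mm equivalent of one
genomic unit (1/b).

Because multi-region genomic cohorts are rarely public, the package ships a
seed-reproducible synthetic cohort generator (spherical tumor geometry,
truncal + subclone-sphere mutations, spatially correlated CNV and
methylation fields) that feeds every pipeline stage end to end.

## Worked example

Simulate an 8-patient cohort and run the full pipeline:

```
gliodist simulate --outdir demo --seed 7 --n-patients 8 --n-probes 2000
gliodist run --coordinates demo/coordinates.tsv --variants demo/variants.tsv \
    --cnv-dir demo/cns --beta demo/beta.csv --sample-meta demo/samples.tsv \
    --outdir demo_out
```

This writes `pairs.tsv`, one distance table per modality, `records.tsv` and
`report.json`. For this seed the cohort has 36 samples forming 67
intra-patient pairs, and the report contains (abridged):

```
"cnv": {
  "n_pairs": 67,
  "pearson_r": 0.639,
  "p_value": 5.8e-09,
  "slope": 0.387,
  "intercept": 26.79,
  "per_10mm": 3.87,
  "mm_per_unit": 2.59
}
```

Read: across 67 pairs the CNV Canberra distance correlates with physical
separation at r = 0.64; each additional 10 mm between biopsy sites adds
about 3.9 units of CNV distance, and one unit of CNV distance corresponds
to about 2.6 mm. The methylation modality shows r = 0.86 (slope 1.11 per
mm) and the mutation modality a weaker r = 0.12 on this small cohort — the
mutation count distance is the noisiest of the three signals at this
cohort size. Pairs within a patient are not independent; an optional
within-patient permutation p-value (set `permutation: true` in the run
config, or call `associate(..., permutation=True)` from the library) is
available as a robustness check.

Individual stages (`pairs`, `mutdist`, `cnvdist`, `methdist`, `correlate`)
consume and produce the same files, so any subset can be run on real data.

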