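# Methods

## Problem setting

Multiplex chromogenic IHC on tissue-microarray (TMA) cores gives, after
image analysis, one record per detected cell: planar coordinates (µm),
a phenotype call (tumor/PanCK⁺, CD8⁺ cytotoxic T-cell, FOXP3⁺ Treg, CD68⁺
macrophage, other), a PD-L1 positivity flag and a CPS-eligibility class.
The package quantifies where immune cells sit relative to tumor-cell
clusters, summarises each case, assigns molecular subgroups and compares
subgroups. It starts from labelled cells: image processing, cell
segmentation and phenotype classification are upstream and out of scope,
as is computing HRDetect or MSIsensor scores (both are consumed as inputs).

## Tumor-cluster geometry

Clusters are connected components of ⋃ᵢ B(cᵢ, r), discs of radius
`merge_radius` centred on tumor cells. Defaults: `merge_radius` = 15 µm
(about one cell diameter of slack, merging cells < 30 µm apart, which
reproduces gland-like nests), `min_cells` = 5 (components below this are
treated as scattered single cells, not clusters). Discs are approximated by
64-gons (< 0.2% area error, deterministic). Areas are reported in mm²
(µm² × 10⁻⁶) with union semantics — overlaps are never double-counted.

Exclusion polygons (necrosis, vessels, acinar and islet regions) are
subtracted from the *area denominator* but not from the cluster outline
used for distance banding: a necrotic hole inside a tumor nest should not
relabel adjacent cells as stromal. A flag-free alternative was considered
and rejected as a silent behaviour change; the outline convention is the
package default and the subtraction is configurable through which polygons
are passed.

Signed distance to the cluster perimeter is negative inside a cluster,
zero on the boundary (boundary cells count as intra-tumoral) and positive
outside. Cores with no cluster raise a typed error; the pipeline drops such
cores with a warning because the density denominator is undefined.

### Numerical behaviour

Translation invariance of areas and distances is exact to floating point.
Rotation invariance holds only to the polygonalisation scale (~10⁻⁴
relative) because buffered discs have orientation-fixed vertices; the test
suite asserts exactly that. Distances are validated against an independent
exact point-to-segment oracle (agreement < 0.5 µm, in practice ~10⁻⁹).

## Compartments

Bands follow the 10/50 µm convention: intra-tumoral *d* ≤ 10 µm,
peri-tumoral 10 < *d* ≤ 50 µm, stromal *d* > 50 µm. Both cut-offs are
closed on the inner side — a measure-zero choice fixed for determinism.
One perimeter geometry is used for both bands (cluster perimeter, cell
centroids as query points); measuring the inner band from individual
tumor-cell edges instead would shift intra counts slightly but is not
implemented, as a single consistent geometry is easier to reason about and
to validate. Every eligible (non-tumor, non-excluded) cell lands in exactly
one compartment; the partition identity is property-tested.

## Per-case metrics

- **Density**: compartment count normalised to the total tumor-cluster area
  of the core (cells/mm²), then averaged over replicate cores (arithmetic
  mean over evaluable cores). All three compartments use the tumor-cluster
  area as denominator — the convention of the source analysis; a per-zone
  area denominator (`zone_areas_mm2`) is available and is what the
  intensity-recovery tests use, since per-zone intensity is the
  generator's ground truth.
- **Log floor**: before log₁₀ transformation, zero case values are replaced
  by 0.9 × the smallest non-zero value among the cases evaluated, keeping
  them strictly below every observed case. Group comparisons run on raw
  densities; logs are for reporting and plotting.
- **CD8:FOXP3 ratio**: whole-core CD8/FOXP3, averaged over cores with at
  least one FOXP3⁺ cell. Zero-FOXP3 cores are excluded rather than given a
  pseudocount or infinity, keeping case means finite without inventing a
  floor.
- **CPS**: 100 × (PD-L1⁺ tumor cells + lymphocytes + macrophages) / viable
  tumor cells per core, capped at 100 (the clinical convention), averaged
  over evaluable cores; positive ⇔ case CPS ≥ 1. Cores without viable
  tumor cells are CPS-unevaluable.

## Molecular subgrouping

Decision order (first match wins):

1. **MMR-d** — any assessed MMR protein lost on IHC, or MSIsensor ≥ 20.
   A germline MMR-gene mutation alone does not suffice. MMR-d is checked
   before HR-d because it is the established ICI-responsive reference
   subtype; no case in the bundled reference table triggers both paths, so
   the precedence is a documented convention rather than an observable.
2. **HR-d, germline path** — germline BRCA1/BRCA2/PALB2 with HRDetect
   ≥ 0.9 (inclusive), or with no HRDetect score available. A carrier below
   0.9 is HR-intact unless flagged low-tumor-cellularity and scoring
   > 0.7 (low cellularity can suppress the structural-variant component of
   the score). The flag is an explicit per-case input, not an automatic
   cellularity computation — the exception was applied ad hoc to a single
   case and automating it would pretend to more generality than exists.
3. **HR-d, somatic path** — no germline hit, HRDetect > 0.9 (exclusive,
   as printed) and evidence of somatic HR-gene inactivation.
4. **HR/MMR-intact** — everything else, including unevaluable cases.

The bundled `reference_molecular_annotations.tsv` transcribes the 26
published deficient cases; applying the classifier reproduces the 25/1
split, including the two somatic-only cases and the low-cellularity case.
HRDetect values printed as "> 0.999" are stored as 0.999; every rule
comparison is unaffected.

## Statistics

- Wilcoxon rank-sum, two-sided: exact enumeration when n₁+n₂ ≤ 20 with no
  ties, tie-corrected normal approximation otherwise (scipy
  `mannwhitneyu` under the hood; the exact branch is property-tested
  against full permutation enumeration).
- Fisher's exact test, two-sided (sum of hypergeometric probabilities not
  exceeding the observed table's), via scipy and exhaustively checked
  against an enumeration oracle for all tables with n ≤ 40. Degenerate
  margins return p = 1 with a warning.
- Kaplan–Meier (lifelines) with median = first time the curve drops to
  ≤ 0.5 (infinite when it never does) and the two-group log-rank test.
  A survival exclusion list handles cases removed from OS analysis (e.g.
  a case treated concurrently for a second primary).
- P-values are reported unadjusted, mirroring the source presentation;
  `adjust=True` adds Benjamini–Hochberg q-values for the density panel for
  reuse outside the original single-contrast design.
- Group summaries are mean ± sample SD (n−1).

## Synthetic cohorts

The generator emulates the data-generating process the analysis assumes:

- **Cores**: a disc of diameter 1500 µm (the TMA core), default 3 clusters
  of ~120 µm radius, 80 tumor cells each, Gaussian-scattered; cluster
  polygons are built with the same disc-union geometry the analysis uses,
  so generator truth and analysis geometry agree by construction.
- **Immune cells**: homogeneous Poisson point processes per (phenotype,
  compartment), placed by rejection sampling inside the true compartment
  polygons. Default intensities use the published intra-tumoral group
  means (CD8 131.1 vs 40.5 cells/mm², FOXP3 25.5 vs 13.6) and equal
  peri-tumoral/stromal and CD68 intensities across groups (CD8 150/200,
  FOXP3 20/25, CD68 50/80/100 for intra/peri/stromal) — plausible values
  for stroma-rich PDAC, chosen once; no published per-compartment values
  exist for these.
- **Case heterogeneity**: a per-case, per-phenotype log-normal multiplier
  with unit mean and CV 1.2, matching the published group SD/mean ratios
  (≈1.18 and ≈1.26). Multipliers are shared across a case's replicate
  cores and across compartments of a phenotype.
- **PD-L1**: per-class Bernoulli flags (intact: 3×10⁻⁴ tumor / 5×10⁻⁴
  immune; HR-d: 2×10⁻³ / 4×10⁻³), set so that on full-size cores the
  intact group essentially never reaches CPS ≥ 1 while a minority of HR-d
  cases does.
- **Annotations** are constructed rule-consistently per intended subgroup,
  so the classifier recovers every label (tested).
- **Survival**: exponential with group medians 29.1 and 19.9 months and
  administrative censoring at 60 months (the censoring mechanism of the
  source cohort is unreported; administrative censoring is the simplest
  defensible choice).
- **Reproducibility**: one root seed; each (case, core) draws from a
  substream keyed by a CRC of the case id plus the core index, so output
  is independent of generation order and byte-identical across reruns.
  If a wide cluster-radius draw leaves every component below `min_cells`,
  the tumor layout is redrawn (bounded, deterministic).

What the generator does **not** model: staining artifacts, segmentation
error, phenotype misclassification, spatial clustering of immune cells
beyond compartment effects (no attraction/repulsion point processes),
inter-core heterogeneity within a case beyond Poisson noise, and any
built-in group effect on the CD8:FOXP3 ratio (both phenotypes scale
independently, so the simulated ratio contrast is approximately null even
though the real cohort showed a difference). Passing tests therefore
validate the pipeline's correctness and calibration, not the biological
realism of any particular tissue.

## Problem sizes in the test suite

Replicated simulation studies (zone-partition oracle over 1000 cores,
interval coverage over 500 cores, 200 null cohorts for type-I error, 30
effect cohorts at group sizes 25 vs 166 for power) run on a reduced
0.6-mm core with one cluster of 30 tumor cells. Intensities — the study
conditions — are unchanged; the core size only trades Poisson precision
per core for replication count. The calibration results at this scale:
the intra-tumoral CD8 comparison at the published effect rejects in
≥ 95% of replicates while the equal-intensity compartments stay at the
nominal 5% level.

## Known limitations

- Densities use the tumor-area denominator for all compartments; stromal
  "density" is therefore a count ratio, not a true areal density (use the
  zone-area mode when the latter is wanted).
- The classifier encodes printed thresholds verbatim (≥ 0.9 vs > 0.9 vs
  > 0.7); these are conventions of the source rules, not tuned values.
- KM medians from 25-case groups carry ~20–30% sampling error; the suite
  tests unbiasedness across replicates rather than per-replicate accuracy
  at that size.
- Cell query points are centroids; distances to cell *edges* would shift
  band membership by roughly a cell radius for borderline cells.
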