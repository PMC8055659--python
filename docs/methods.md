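# Methods

## Data model

The unit of analysis is the ROI frame: all segmented cells of one
(sample, ROI, timepoint) capture on a rectangular field, by default
931 × 698 µm = 0.649838 mm². Coordinates follow image convention — origin
at the top-left of the field, y increasing downward, continuous microns.
Marker calls are booleans produced upstream by the image-analysis software;
intensity thresholds are out of scope here. Every cell is nucleated
(DAPI+), so the percentage denominator is the frame's total cell count.

### Marker-table merging

Vendor exports often ship one per-cell table per marker from the same
segmentation. Tables are joined on coordinates rounded to 0.1 µm with an
exact match after rounding; no tolerance beyond the rounding grid is
applied, because a looser tolerance would require arbitrary tie-breaking.
Two cells of one table colliding on a rounded coordinate raise an error
rather than guessing. Cells absent from any input are dropped, but every
drop is counted per input in the merge report — nothing is silently lost.
On a 0.1 µm grid a 931 × 698 µm field has ≈ 6.5 × 10⁷ sites, so collisions
are rare below a few hundred cells and the merge either succeeds exactly or
fails loudly.

## Phenotyping

A phenotype rule is a set of markers required positive plus an optional set
required negative; unmentioned markers are don't-care. Membership is
deliberately non-exclusive — a CD3+CD8+PD-1+ cell is also CD3+CD8+ and
CD3+ — because the panel definitions enumerate overlapping populations, and
exclusive "best label" assignment would break the subset monotonicity
count(CD3+CD8+PD-1+) ≤ count(CD3+CD8+) ≤ count(CD3+) that nested rules
must satisfy. Negative requirements appear only where a definition prints
one (e.g. CD3+FOXP3+CD8− regulatory T cells). The five shipped panels are
plain YAML and freely editable.

Density = count / ROI area (cells/mm²); percent = 100 · count / DAPI+
count. Percent is invariant to the ROI area (the area cancels), so
percentages — not densities — feed the reproducibility statistics.

## Reproducibility statistics

With exactly two observations per ROI (week 1, week 2) the coefficient of
variation uses the sample standard deviation (ddof = 1), giving the closed
form CV(a, b) = |a − b| / (√2 · mean(a, b)). A pair of zeros is defined as
CV = 0: the phenotype was absent twice, which is perfect agreement.
The battery computes, per phenotype and panel:

* one CV per ROI of each sample (50 CVs under the default 10 × 5 design),
  summarised by the median;
* a within-sample Spearman ρ over each sample's ROIs (average ranks for
  ties — percent ties at 0 are common); undefined (returned as NaN with a
  warning) below 3 ROIs or for constant vectors;
* one across-sample ρ per phenotype over sample-level mean percents
  (10 points), week 1 vs week 2. Pooling all 50 ROI points instead is
  available via `across_mode="pooled_rois"`; sample-level means are the
  default because the across-sample question is about sample ranking, and
  pooled ROI points mix within- and between-sample variance.

P-values are Bonferroni-adjusted within one panel's phenotype family
(p_adj = min(1, m·p), family size logged). Phenotypes with zero counts in
at least half of the ROIs are excluded from the battery and listed: rank
statistics over near-constant zero vectors are noise, and scarce
populations need a different design. Benchmarks — median CV ≤ 0.5, median
within-sample ρ ≥ 0.5, across-sample ρ ≥ 0.7 — are attached as flags, not
hard failures.

## Proximity analysis

Nearest-neighbour distances are Euclidean, computed within one ROI only
(captures are disjoint fields; stitching across them would fabricate
geometry). The search uses a k-d tree and is verified in the test suite to
match an exhaustive all-pairs computation bitwise. When a cell qualifies
for both the reference and the target phenotype (nested rules), its
self-distance is excluded — the nearest *other* target cell counts.

Matrix entries pool per-cell distances across all ROIs and samples, then
take one median ("cohort median"). The global close/far radius is the
median of the per-pair medians; pooling all cells into one median instead
is available (`mode="pooled_cells"`). Medians are reported without edge
correction: nearest-neighbour distances of cells near the field border are
right-censored, which biases the distribution's tail upward but moves the
median negligibly at the cell densities involved (typical nearest-neighbour
distances of 10–60 µm against a 931 × 698 µm field).

## Mixed/unmixed pattern classification

For each sample, distances from every CK+ cell to its nearest CD3+ cell are
pooled over the sample's ROIs; the empirical CDF of these distances (the
cross-type G function) is compared against the theoretical curve under
complete spatial randomness, G(r) = 1 − exp(−λπr²), with λ estimated as the
pooled CD3+ count over the pooled area — the same intensity as the observed
pattern, so the comparison isolates spatial arrangement from abundance.

The deviation score is the signed area between the curves by the trapezoid
rule over the radius grid, default 0–200 µm in 1 µm steps (200 µm is the
working interaction scale of the proximity maps):

    score = ∫₀²⁰⁰ [G_theo(r) − G_emp(r)] dr   (µm)

Positive score: T cells are farther from malignant cells than CSR predicts
(exclusion); negative: closer (attraction). Labels: |score| ≤ 10 µm →
*mixed*, score > +10 µm → *unmixed*, and score < −10 µm → *aggregated*, an
extension label for stronger-than-random attraction that the two-way
mixed/unmixed scheme does not distinguish. The ±10 band is inclusive on
both sides. The score construction as an integrated curve deviation in µm
is this package's own operationalisation of the mixed/unmixed decision
band; alternative summaries (e.g. sup-norm) order the same simulations
identically but are not in units of the band.

No edge correction is applied to the empirical G by default; under CSR at
the densities used, the boundary bias of the raw CDF stays well inside the
±10 µm band (the null-distribution tests bound the mean score within
±1 µm). A border-correction option (discarding reference cells within
r_max of the boundary) would trade this small bias for a large variance
increase on a 931 × 698 µm field and is deliberately not default.

## Synthetic tissue generator

The generator produces the cohort design the analysis stages assume:
10 samples × 5 ROIs × 2 timepoints on 931 × 698 µm fields, four exclusive
base classes per cell.

* **Malignant cells** — Matérn cluster process: nest centres Poisson
  (default 8 per ROI, uniform in the field), offspring Poisson (mean 250
  per nest) uniform in discs of radius 120 µm, resampled to stay inside the
  field so realised counts keep the nominal mean (≈ 2,000 CK+ cells per
  ROI, ≈ 3,100 cells/mm²). Uniform-in-disc offspring is the simplest
  process producing cohesive tumour nests.
* **Immune cells** — T cells (default mean 400/ROI) and macrophages
  (default 75/ROI): each cell lands uniformly inside a random nest disc
  with probability *m* (the infiltration/mixing fraction, default 0.5) and
  uniformly in the nest complement otherwise, by rejection sampling. m = 0
  reproduces an immune-excluded architecture, m = 1 full infiltration.
* **Other stromal cells** — CSR, default mean 300/ROI, all markers
  negative; included so the DAPI+ denominator contains marker-negative
  cells as real segmentations do.
* **Markers** — drawn per cell from class-conditional probabilities
  (malignant: CK 1.0, PD-L1 0.04; T cell: CD3 1.0, CD8 0.72, PD-1 0.05
  independent; macrophage: CD68 1.0, PD-L1 0.69). These defaults rank the
  phenotype densities like a typical NSCLC cohort (CK+ ≫ CD3+ > CD3+CD8+ >
  CK+PD-L1+ ≈ CD68+ > CD68+PD-L1+ > CD3+PD-1+ > CD3+CD8+PD-1+); absolute
  medians are not a target.
* **Between-sample heterogeneity** — one log-normal abundance factor per
  class per sample (log-sd 0.5), drawn independently per class so that
  phenotype *percentages*, not only counts, differ between samples; a
  single shared factor would cancel in the percent normalisation and
  remove all across-sample signal.
* **Week-2 replicate** — each week-1 cell is retained with probability
  q = 0.9, its position jittered by an isotropic Gaussian of sd 2 µm
  (clipped to the field), marker calls preserved; Poisson(0.1 · n) new
  cells are added by class-preserving bootstrap: each copies a uniformly
  chosen week-1 cell's marker map and is displaced by an isotropic Gaussian
  of sd 10 µm, so clustered classes stay clustered and CSR classes stay
  near-CSR without threading generator internals through the frame type.
  Real consecutive 4-µm sections have no published noise model; thinning +
  jitter + additions is an explicit modelling assumption.

Seeding: one master `SeedSequence` per cohort, spawned per sample (factor
stream + one stream per ROI, split into week-1 and week-2 substreams), so
any ROI regenerates in isolation and cohorts are bit-reproducible.

### What the generator does and does not emulate

It reproduces clustered malignant nests, tunable immune infiltration,
realistic abundance ranking, between-sample heterogeneity, and replicate
noise — the features the pipeline's statistics respond to. It does not
emulate segmentation errors, marker intensity distributions or threshold
drift, spatially correlated marker expression (e.g. PD-L1 gradients at
nest borders), tissue folds, or necrotic regions. Green tests therefore
demonstrate correctness of the computations and sane behaviour under the
modelled noise, not robustness to every artefact of real slides.

## Problem sizes and numerical choices

The shipped tests and the summary script use the full default cohort
(≈ 280,000 cells) for the reproducibility battery — it runs in seconds —
and 1–3-sample cohorts for spatial analyses, which are per-sample
computations anyway. Null-model checks use 100 CSR replicates at 2,000
points. Fixed seeds are used throughout; moment checks assert within 3
standard errors. Degenerate inputs (empty frames, zero areas, absent
phenotypes, single timepoints) raise typed errors or return flagged nulls
rather than propagating NaNs silently.

## Known limitations

* Close/far and mixed/unmixed thresholds are descriptive conventions, not
  inferential tests; no permutation envelopes or K/L functions are
  provided.
* Distances ignore tissue context (a nearest neighbour across a vessel or
  fold counts like any other).
* The reproducibility battery requires exactly two timepoints and matched
  (sample, ROI) keys; longitudinal designs with more timepoints need a
  different model.
* Cohort pooling weights samples by their cell counts; per-sample-first
  aggregation is exposed as an option where it matters.
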