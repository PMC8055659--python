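# mifspat

Spatial and reproducibility analysis of multiplex-immunofluorescence (mIF)
per-cell data from tumour tissue.

Multiplexed immunofluorescence panels stain 6–8 markers on one tissue
section; after spectral unmixing and cell segmentation, each scanned region
of interest (ROI, a 931 × 698 µm field) yields a table with one row per
cell: its x/y position in microns and a boolean positivity call per marker.
`mifspat` takes such tables — or generates synthetic ones with the same
statistical structure — and answers the questions a translational pathology
group asks of them:

* **Phenotyping** — which cells satisfy each marker co-expression rule
  (e.g. CD3+CD8+ cytotoxic T cells, CD3+FOXP3+CD8− regulatory T cells)?
  Membership is non-exclusive; definitions for five immuno-oncology panels
  (43+ phenotypes) ship as editable YAML.
* **Quantification** — phenotype counts, densities per mm² of ROI area, and
  percentages of total nucleated (DAPI+) cells.
* **Reproducibility** — when every ROI is re-stained and re-quantified on a
  consecutive section one week later, how well do the two timepoints agree?
  Per-ROI coefficient of variation CV(a,b) = |a−b| / (√2·mean), within- and
  across-sample Spearman rank correlations, Bonferroni-adjusted p-values per
  panel family.
* **Proximity** — per-cell nearest-neighbour distances from malignant (CK+)
  cells to each phenotype; cohort-pooled median distance matrix; a global
  median radius splitting phenotypes into *close* vs *far*.
* **Spatial architecture** — the cross-type nearest-neighbour distance
  G function from CK+ cells to CD3+ T cells compared with the Poisson
  reference G(r) = 1 − exp(−λπr²) at the observed T-cell intensity λ. The
  signed area between the curves over 0–200 µm is a deviation score in µm:
  |score| ≤ 10 → *mixed* (infiltrated) tumour, score > +10 → *unmixed*
  (T cells excluded from cohesive malignant nests).

A synthetic tissue generator (Matérn-cluster malignant nests, immune cells
with a tunable infiltration fraction *m*, class-conditional marker calls,
two-timepoint replicates) makes every stage testable end to end and provides
ground truth for parameter-recovery checks.

## Worked example

```python
import mifspat as m

panel = m.default_panels()["1"]          # CK, CD3, CD8, PD-1, PD-L1, CD68
frames, _ = m.simulate_cohort(m.SimConfig(seed=1))
dens = m.density_table(frames, panel)
stats, _ = m.summarize_repro(dens)
print(m.repro_frame(stats)[["phenotype", "median_cv", "rho_across"]])
```

which prints (seed 1, default 10 samples × 5 ROIs × 2 timepoints):

```
    phenotype  n_cv  median_cv  median_rho_within  rho_across
         CD3+    50     0.0127               1.00      1.0000
     CD3+CD8+    50     0.0140               1.00      1.0000
CD3+CD8+PD-1+    50     0.0462               0.90      1.0000
    CD3+PD-1+    50     0.0378               0.90      0.9879
        CD68+    50     0.0177               0.95      1.0000
  CD68+PD-L1+    50     0.0283               1.00      0.9879
          CK+    50     0.0031               1.00      1.0000
    CK+PD-L1+    50     0.0274               0.95      0.9879
```

Each row is one phenotype; `n_cv` = 50 CVs (10 samples × 5 ROIs), all
median CVs sit far below the 0.5 reproducibility benchmark, and the rank
correlations between weeks are near 1 — the regime a well-behaved assay
should occupy. The spatial side:

```python
results = m.classify_cohort(frames, panel, timepoint="week1")
for sid, r in results.items():
    print(sid, f"{r.score:+.2f} um", r.label)
```

scores near 0 µm label a sample *mixed*; a cohort simulated with m = 0
(immune cells fully excluded from nests) scores +50 to +80 µm → *unmixed*.

The `examples/` directory holds one short script per capability
(simulation, phenotyping, reproducibility, proximity, pattern
classification, marker-table merging); each prints its numbers with a note
on what they mean. A thin CLI mirrors the stages:

```bash
mifspat simulate --seed 1 --out out/
mifspat run-all --seed 1 --out out/
```

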