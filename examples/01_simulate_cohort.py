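"""Generate a small synthetic two-timepoint cohort and inspect its makeup.

The generator emulates segmented multiplex-IF per-cell tables: malignant
cells in clustered nests, immune cells with a tunable degree of nest
infiltration, and a consecutive-section week-2 replicate.
"""

import mifspat as m

cfg = m.SimConfig(n_samples=2, n_rois_per_sample=3, seed=1)
frames, truth = m.simulate_cohort(cfg)

print(f"{len(frames)} ROI frames "
      f"({cfg.n_samples} samples x {cfg.n_rois_per_sample} ROIs x 2 timepoints)")
f = frames[0]
print(f"first frame {f.key()}: {f.n_cells} cells on a "
      f"{f.width:.0f} x {f.height:.0f} um field ({f.area_mm2:.3f} mm2)")
print("ground-truth class counts:", f.meta["n_by_class"])
print("per-sample abundance factors (log-normal, sd "
      f"{cfg.sample_sd}):")
for sid, s in truth["samples"].items():
    print(" ", sid, {k: round(v, 2) for k, v in s["factors"].items()})
# Each cell also carries boolean marker calls (CK, CD3, CD8, PD-1, PD-L1,
# CD68 by default), so the frames feed directly into the phenotyping stage.
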