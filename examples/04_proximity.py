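"""Nearest-neighbor proximity of immune phenotypes to malignant cells.

For every CK+ malignant cell the distance to the nearest cell of each
target phenotype is computed within its ROI; cohort-pooled medians fill a
proximity matrix.  The median of all pair medians is the global radius
splitting phenotypes into close vs far from the malignant compartment.
"""

import mifspat as m

frames, _ = m.simulate_cohort(m.SimConfig(n_samples=3, seed=4))
w1 = [f for f in frames if f.timepoint == "week1"]
panel = m.default_panels()["1"]

targets = [r.name for r in panel.rules if r.name != "CK+"]
summaries = [m.summarize_pair(w1, panel, "CK+", t) for t in targets]
radius = m.median_radius(summaries)
print(f"global median radius: {radius:.2f} um\n")
for s in summaries:
    if len(s.nn_distances):
        print(f"CK+ -> {s.target:14s} median {s.median_distance:7.2f} um "
              f"({s.proximity_label(radius)})")
# Phenotypes whose median distance is at or below the radius are 'close' to
# the malignant cells; the matrix form is available via proximity_matrix().
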