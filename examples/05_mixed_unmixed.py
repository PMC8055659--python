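"""Mixed vs unmixed tumour architecture from the cross-type G function.

The empirical CDF of CK+ -> nearest CD3+ distances is compared with the
Poisson curve 1 - exp(-lambda pi r^2) at the observed T-cell intensity.
The signed area between the curves over 0-200 um is the deviation score:
within +-10 um of the reference = mixed (infiltrated), above +10 um =
unmixed (T cells excluded from the malignant nests).
"""

import mifspat as m

panel = m.default_panels()["1"]
for mix, regime in [(0.9, "infiltrated"), (0.0, "excluded")]:
    cfg = m.SimConfig(n_samples=2, n_rois_per_sample=5, seed=7, mixing=mix)
    frames, _ = m.simulate_cohort(cfg)
    results = m.classify_cohort(frames, panel, timepoint="week1")
    print(f"mixing m={mix} ({regime} immune cells):")
    for sid, r in results.items():
        print(f"  {sid}: score {r.score:+7.2f} um  lambda "
              f"{r.lambda_target:.2e}/um2  -> {r.label}")
# Scores track the generator's infiltration fraction m: full exclusion
# produces strongly positive scores (unmixed), heavy infiltration keeps the
# empirical curve at or above the Poisson reference (mixed).
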