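"""Are the sample sizes sufficient? Saturation curves for iFD_CV, HD and H_e.

Resamples 1..N units (individuals or replicate plots) within each population,
recomputes the statistic 100 times per step, and reports where the curve
flattens: if the mean stops moving well before the full sample size, the
sampling effort was sufficient.
"""

import traitdiv as td
from traitdiv.saturation import (hd_saturation, he_saturation, ifdcv_saturation,
                                 saturation_onset)

sim = td.simulate(td.SimulationConfig(n_populations=4), seed=3)

for name, curve in [
    ("iFD_CV (individuals)", ifdcv_saturation(sim.traits, iterations=100, seed=1)),
    ("HD (replicate plots)", hd_saturation(sim.env, iterations=100, seed=2)),
    ("H_e (genotyped individuals)", he_saturation(sim.genotypes, iterations=100, seed=3)),
]:
    print(f"\n{name}")
    for pop, grp in curve.groupby("group"):
        onset = saturation_onset(grp, tolerance=0.02)
        full = grp.dropna(subset=["mean"]).iloc[-1]
        label = onset if onset is not None else "not saturated"
        print(f"  {pop}: full-sample value {full['mean']:.3f}, "
              f"mean stabilises (<2% steps) from n = {label}")
print("\nThe full-sample point always equals the plain statistic (SD = 0): the"
      " curve is recomputed from each subsample, never cached.")
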