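"""Risk labels and supervised discretization of region factors.

Labels each region high/low risk from its percent change (>= 1%/degC for
cold, >= 10%/degC for heat), then cuts a continuous factor into states with
entropy-minimization splits (MDL stopping). Also shows a manual interval
scheme that honors printed bracket types exactly.
"""

import numpy as np

from tempmort import discretize, synth
from tempmort.discretize import DiscretizationScheme, FactorScheme, Interval
from tempmort.gam import EffectEstimate

# --- risk labeling -------------------------------------------------------
for side, pc in [("cold", 0.5), ("cold", 1.7), ("heat", 9.9), ("heat", 12.0)]:
    est = EffectEstimate("R00", side, "tmean", 0.0, np.log(1 + pc / 100),
                         0.01, pc, False)
    print(f"{side} {pc:5.1f}%/degC -> {discretize.label_risk(est)}")

# --- supervised splits ---------------------------------------------------
cfg = synth.WorldConfig(seed=5, n_regions=26)
factors = synth.generate_factor_table(cfg)
x = factors.continuous["pct_65plus"].to_numpy()
labels = factors.labels["cold_risk"].to_numpy()
cuts = discretize.supervised_splits(x, labels)
print(f"\npct_65plus values span [{x.min():.2f}, {x.max():.2f}]; "
      f"supervised cut(s): {[round(c, 2) for c in cuts]}")
# the truth network draws low-state values below 5.65 and high above, so a
# data-driven cut near 5.65 means the state boundary was rediscovered

# --- manual scheme with verbatim brackets --------------------------------
scheme = DiscretizationScheme({
    "edu_years": FactorScheme("edu_years", intervals=[
        Interval.parse("[5.18, 5.25]", "low"),
        Interval.parse("(5.25, 12.31]", "high"),
    ])})
fs = scheme.factors["edu_years"]
print(f"\nmanual scheme: 5.25 -> {fs.assign(5.25)} (closed upper bracket), "
      f"5.26 -> {fs.assign(5.26)}")
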