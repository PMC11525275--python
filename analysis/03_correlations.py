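"""Linear associations among age, fluid cognition, and WMH load.

Pearson correlations (log-transformed WMH volumes) with within-family BH-FDR
control, the partial correlation of global WMH with fluid cognition
controlling for age, and the a-priori power calculation.
Writes results/correlations.csv.
"""

import numpy as np

from wmhnet import assoc, io

scored = io.read_phenotypes("results/factors.csv")
data = scored.copy()
for col in ("wmh_global_k07", "wmh_pv_k07", "wmh_deep_k07", "wmh_global_k05"):
    data[f"log_{col}"] = assoc.log_wmh(data[col])

pairs = []
for wmh in ("log_wmh_global_k07", "log_wmh_pv_k07", "log_wmh_deep_k07"):
    pairs.append({"x": "age_years", "y": wmh, "family": "age_wmh"})
    pairs.append({"x": "fluid", "y": wmh, "family": "cog_wmh"})
pairs.append({"x": "age_years", "y": "fluid", "family": "age_cog"})
table = assoc.correlation_table(data, pairs)

for k in ("k07", "k05"):
    r, p = assoc.partial_correlation(
        data[f"log_wmh_global_{k}"], data["fluid"], data[["age_years"]].to_numpy()
    )
    print(f"partial r(global WMH {k}, fluid | age) = {r:+.3f} (p = {p:.3f})")

power = assoc.power_pearson(0.35, len(data), 0.05, two_sided=True)
print(f"power to detect r = 0.35 at n = {len(data)}, two-tailed alpha = .05: {power:.2f}")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
table.to_csv("results/correlations.csv", index=False)
print("wrote results/correlations.csv")
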