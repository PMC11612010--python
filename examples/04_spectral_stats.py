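"""Band powers, group power tables and the paired statistical battery.

Generates both conditions for a few synthetic 'subjects', tabulates
delta/theta/alpha/beta power and the theta-beta ratio, and tests the
planted preictal spectral shift (delta down, theta up) with the
normality-routed paired comparison.
"""

import numpy as np
import pandas as pd

import preictal as p

# per-condition epoch sets for 8 synthetic subjects
epoch_sets = {}
for si in range(8):
    spec = p.SyntheticSpec(seed=100 + si, class_effects=p.strong_effects())
    epochs, _ = p.generate_dataset(spec, 20)
    epoch_sets[f"subj{si}"] = epochs

band_table, channel_table = p.power_tables(epoch_sets)
print("group-mean band power (uV^2), channel-averaged:")
df = band_table.to_frame()
print(df.groupby("group")[band_table.columns].mean().round(2).to_string())

print("\npaired interictal vs preictal comparison per band:")
inter = pd.DataFrame(band_table.values[0], columns=band_table.columns)
pre = pd.DataFrame(band_table.values[1], columns=band_table.columns)
table = p.stats.compare_feature_table(inter, pre, alpha=0.05, d_threshold=0.3)
print(table.round(4).to_string(index=False))
print("\nthe planted effects (delta x0.5, theta x1.6 preictally) surface as "
      "large opposite-signed Cohen's d values")
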