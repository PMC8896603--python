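"""Side-by-side evaluation of several normalization strategies.

Builds the familiar comparison-table layout: one row per
transformation/normalization pair with the cross-channel mean AD statistic,
Otsu discordance, slide variance proportion, and manual-label accuracy.
Smaller AD / discordance / variance proportion = less slide effect;
higher accuracy = biology better preserved.
"""

import pandas as pd

from slidenorm import (
    SimConfig,
    apply_transform,
    combat_normalize,
    evaluate_method,
    register_normalize,
    simulate_table,
)
from slidenorm.cli import method_row_name

table, _ = simulate_table(SimConfig(n_slides=6, cells_per_slide=500, tau=0.5, seed=17))
channels = ["vimentin", "cd3"]

rows = []
for transform in ("none", "log10", "mean_divide", "mean_divide_log10"):
    transformed = apply_transform(table, transform)
    for method in ("none", "combat", "registration"):
        if transform == "none" and method != "none":
            continue  # normalizers run on a chosen scale
        if method == "combat":
            normalized, _ = combat_normalize(transformed, channels=channels)
        elif method == "registration":
            normalized, _ = register_normalize(transformed, channels=channels)
        else:
            normalized = transformed
        report = evaluate_method(table, normalized, channels=channels,
                                 method=method_row_name(transform, method))
        rows.append(report.to_row())

print(pd.DataFrame(rows).round(3).to_string(index=False))
print("\nMean division and the registration runs cut the slide-level metrics;")
print("ComBat zeroes the variance proportion by construction.")
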