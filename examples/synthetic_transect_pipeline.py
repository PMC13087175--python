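"""End-to-end transect analysis on a synthetic South Pacific section.

Generates a small forward-modelled transect (planted hydrothermal ridge,
volcano and shelf Fe sources plus a mesopelagic siderophore patch), runs the
four-pathway partition prediction per sample, classifies the residuals and
prints the summary table the analysis is built around.
"""

import numpy as np

from fespec.pathways import residence_time_ratio
from fespec.synthetic import SyntheticConfig, generate_transect
from fespec.transect import run_transect, summary_stats

samples, truth = generate_transect(SyntheticConfig(seed=11, n_stations=20,
                                                   n_depths=10))
res = run_transect(samples)

print(f"{len(res)} samples deeper than 250 m")
for name in ("dfe", "lpfe"):
    s = summary_stats(res[name], res[f"{name}_pred"])
    print(f"{name.upper():>5}: median obs {s['median_obs']:.3f} / pred "
          f"{s['median_pred']:.3f} nmol/L, slope {s['slope']:.2f}, "
          f"r^2 {s['r_squared']:.2f}")
print("residual classes:", res["residual_class"].value_counts().to_dict())
print("ferromanganese flags:", int(res["ferromanganese"].sum()),
      "of", int((truth['label'] == 'anomaly_femn').sum()), "planted")

inl = res[res["residual_class"] == "equilibrium_inlier"]
ratio = residence_time_ratio(np.median(inl["dfe"]), np.median(inl["lpfe"]))
print(f"scavenging residence-time ratio (ratio of inlier medians): {ratio:.1f}")
print("\nEnhanced residuals sit at the planted sources; the inlier subset is")
print("the part of the section where observed Fe partitioning is explained")
print("by equilibrium chemistry alone.")
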