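"""Are there more than two cell states?  Clustering the stable equilibria.

Harvests every stable state from the standard bifurcation runs, clusters
the all-species profiles and maps the four clusters onto fully active
(A), partial active (pA), partial inactive (pI) and fully inactive (I).
DLL alone cannot make this split: the partials are distinguished by
their residual receptor (VR2) and repressor (HE) signals.
"""

import numpy as np
import pandas as pd

import tipstalk as ts
from tipstalk.classify import default_branches

branches = default_branches()
profiles = ts.collect_profiles(branches, picks=[0.25, 0.5, 0.75])
result = ts.cluster_profiles(profiles, k=4)

rows = []
for cid, name in sorted(result.class_map.items(), key=lambda kv: kv[1]):
    m = result.cluster_mean(cid)
    n = int((result.labels == cid).sum())
    rows.append({"class": name, "n": n,
                 **{s: round(float(v), 3) for s, v in zip(ts.SPECIES, m)}})
print(pd.DataFrame(rows).set_index("class")[["n", "DLL", "VR2", "HE", "nicd"]])

inv = {v: k for k, v in result.class_map.items()}
vr2 = ts.SPECIES.index("VR2")
he = ts.SPECIES.index("HE")
print(
    f"\npI keeps {result.cluster_mean(inv['pI'])[vr2] / result.cluster_mean(inv['I'])[vr2]:.1f}x "
    f"the active receptor of I; pA carries "
    f"{result.cluster_mean(inv['pA'])[he] / result.cluster_mean(inv['A'])[he]:.1f}x the HE of A."
)
print("\nDendrogram (Newick, truncated):", result.to_newick()[:120], "...")
print(
    "A DLL readout alone would lump pI with I and pA with A; receptor and "
    "notch-pathway readouts are needed to see the partial states."
)
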