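#!/usr/bin/env python
"""Bliss-independence combination call and tumor-control fractionation.

Checks the observed triple-combination survival (GNP-RGD;CIS + 2 Gy)
against the Bliss product of the single-modality arms, then translates the
per-fraction survival difference into expected surviving clonogens and
Poisson tumor control probability for a 1e12-cell tumor over repeated
identical treatments. Writes results/tcp.csv.
"""

from pathlib import Path

import pandas as pd

from gnplem.assays import SFEstimate
from gnplem.combination import (
    bliss_classify,
    bliss_expected_sf,
    min_fractions_for_tcp,
    poisson_tcp,
    survivors_after_fractions,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# printed single-modality survival fractions: cisplatin alone, GNP-RGD + 2 Gy
expected = bliss_expected_sf(0.61, 0.26)
observed = SFEstimate(mean=0.16, sem=0.007, n=3)
res = bliss_classify(expected, observed, k_sigma=2)
print(
    f"Bliss expectation 0.61 x 0.26 = {expected:.4f}; observed "
    f"{observed.mean:.2f} +/- {observed.sem:.3f} -> {res.call}"
)

N0 = 1e12
rows = []
for n in range(1, 25):
    for label, sf in [("GNP-RGD;CIS + IR", 0.16), ("CIS + IR", 0.23)]:
        surv = survivors_after_fractions(N0, sf, n)
        rows.append({"fractions": n, "arm": label, "sf": sf,
                     "survivors": surv, "tcp": poisson_tcp(surv)})
df = pd.DataFrame(rows)
df.to_csv(OUT / "tcp.csv", index=False)

for sf in (0.16, 0.23):
    r = min_fractions_for_tcp(N0, sf, 0.5)
    print(
        f"SF {sf}: TCP >= 0.5 first reached at {r.n_treatments} fractions "
        f"({r.survivors:.3f} expected survivors, TCP {r.tcp:.2f})"
    )
print("The GNP-sensitized arm controls the tumor in 4 fewer fractions.")
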