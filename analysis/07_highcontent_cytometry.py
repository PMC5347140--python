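#!/usr/bin/env python
"""High-content summaries over a dose series of the dual-activity drug:
mitotic index (pHH3-positive fraction, thresholds from the vehicle well's
99th percentiles), condensed-DNA fraction, mode-anchored cell-cycle
fractions, and proliferation from nuclei counts.  The destabilising arm
shows as rising pHH3/condensed fractions and G2/M + sub-G1 accumulation
with dose.
"""

from pathlib import Path

import pandas as pd

from moadecon import cytometry as cy
from moadecon.pipeline import STUDY_DRUGS
from moadecon.simulate import gen_nuclei

SEED = 20260920
OUT = Path("results")
OUT.mkdir(exist_ok=True)

spec = STUDY_DRUGS["bkm120_like"]
doses = [0.0, 0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6]
wells = {d: gen_nuclei(spec, d, seed=SEED + i, n_nuclei=2500,
                       well_id=f"W{i:02d}")
         for i, d in enumerate(doses)}

thr_mean, thr_max = cy.phh3_threshold_from_vehicle(wells[0.0])
n_vehicle = len(wells[0.0])
rows = []
for d, w in wells.items():
    s = cy.summarize_well(w, w["well_id"].iloc[0], thr_mean, thr_max,
                          condensed_threshold=0.0, n_vehicle=n_vehicle)
    rows.append({"dose_um": d * 1e6, "n_nuclei": s.n_nuclei,
                 "pct_phh3": s.pct_phh3_positive,
                 "pct_condensed": s.pct_condensed,
                 **{k: s.cycle_fractions[k] for k in ("subG1", "G1", "S", "G2M")},
                 "proliferation_pct": s.proliferation_pct_of_vehicle})
table = pd.DataFrame(rows)
table.round(2).to_csv(OUT / "cytometry.csv", index=False)
print(f"pHH3 thresholds from vehicle 99th percentiles: "
      f"mean>{thr_mean:.0f}, max>{thr_max:.0f}")
print(table.round(2).to_string(index=False))
print("\nG2M + subG1 accumulate and proliferation falls with dose, the "
      "signature of the destabilising arm")
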