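#!/usr/bin/env python
"""Classify drug mechanisms from the fitted panel: the Hill-slope matrix
after the panel exclusion rule, least-square penalty scores for all drug
pairs, and relative-sensitivity profiles sorted by the pure PI3K
inhibitor.  The expected signature: PI3K inhibitors pair near baseline,
while the destabiliser and the dual drug carry large penalties against any
PI3K inhibitor — classifying the dual compound with the destabilisers.
"""

from pathlib import Path

import pandas as pd

from moadecon.panel import hill_slope_table, penalty_score_matrix, sensitivity_profile

SRC = Path("scratch/fits.csv")
if not SRC.exists():
    raise SystemExit("run analysis/02_fit_dose_response.py first")
fits = pd.read_csv(SRC)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

slopes = hill_slope_table(fits[fits["readout"] == "viability"])
slopes.round(3).to_csv(OUT / "hill_slopes.csv")
excluded = slopes.attrs["excluded_lines"]
print(f"retained {len(slopes)} of {len(slopes) + len(excluded)} lines "
      f"(excluded for ambiguous slope: {excluded or 'none'})")

pen = penalty_score_matrix(slopes)
pen.round(1).to_csv(OUT / "penalty_scores.csv")
print("\npenalty scores (summed squared slope differences):")
print(pen.round(1).to_string())

viab = fits[(fits["readout"] == "viability")
            & ~fits["cell_line"].isin(excluded)]
ic50s = viab.pivot(index="cell_line", columns="drug", values="ic50_m")
rel = sensitivity_profile(ic50s, "pqr309_like")
rel.round(3).to_csv(OUT / "sensitivity_profile.csv")
print(f"\nwrote Hill-slope matrix, penalty scores and sensitivity profile to {OUT}/")
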