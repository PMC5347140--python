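#!/usr/bin/env python
"""Fit every (drug, cell line, readout) dilution series of the simulated
panel with the variable-slope logistic: full 4-parameter curves for
viability and pHH3, the normalised 3-parameter curve for tubulin-corrected
pPKB.  Writes the per-curve fit table to scratch/ (read by scripts 03-04)
and prints the ambiguity audit.
"""

from pathlib import Path

import pandas as pd

from moadecon.dose_response import DoseResponseSet, fit_sigmoid
from moadecon.io import read_tidy_csv
from moadecon.pipeline import READOUT_MODELS

SRC = Path("scratch/fixtures/dose_response.csv")
if not SRC.exists():
    raise SystemExit("run analysis/01_simulate_study.py first")

df = read_tidy_csv(SRC, "dose_response")
rows = []
for (drug, line, rdt), g in df.groupby(["drug", "cell_line", "readout"]):
    ds = DoseResponseSet(drug=drug, cell_line=line, readout=rdt,
                         conc_m=g["conc_M"].to_numpy(),
                         response=g["response"].to_numpy())
    f = fit_sigmoid(ds, model=READOUT_MODELS[rdt])
    rows.append({"drug": drug, "cell_line": line, "readout": rdt,
                 "log_ic50": f.log_ic50, "ic50_m": f.ic50,
                 "hill_slope": f.hill_slope, "top": f.top, "bottom": f.bottom,
                 "se_log_ic50": f.se_log_ic50, "se_hill": f.se_hill,
                 "ambiguous": f.ambiguous, "model": f.model})
fits = pd.DataFrame(rows)

out = Path("scratch/fits.csv")
fits.to_csv(out, index=False)

amb = fits[fits["ambiguous"]]
print(f"fitted {len(fits)} curves -> {out}")
print(f"{len(amb)} ambiguous fits "
      f"({amb.groupby('readout').size().to_dict() if len(amb) else 'none'})")
viab = fits[fits["readout"] == "viability"]
print("\nmean viability Hill slope per drug:")
print(viab.groupby("drug")["hill_slope"].mean().round(2).to_string())
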