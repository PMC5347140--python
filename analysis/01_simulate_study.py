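#!/usr/bin/env python
"""Simulate the study's raw inputs: a 44-line dose-response panel for five
drugs (three PI3K inhibitors, one dual-activity compound, one pure
microtubule destabiliser), each with viability, pPKB and pHH3 readouts over
the 9-point half-log dilution series in duplicate.

The bulky tidy table goes to scratch/ (it is regenerable from the seed);
downstream scripts read it from there.
"""

from pathlib import Path

from moadecon.io import dose_response_frame
from moadecon.pipeline import STUDY_DRUGS
from moadecon.simulate import ScenarioSeed, gen_study

SEED = 20260920
N_LINES = 44

OUT = Path("scratch/fixtures")
OUT.mkdir(parents=True, exist_ok=True)

panels = gen_study(STUDY_DRUGS, ScenarioSeed(seed=SEED, n_lines=N_LINES))
df = dose_response_frame(panels)
df.to_csv(OUT / "dose_response.csv", index=False)

print(f"simulated {df['drug'].nunique()} drugs x {df['cell_line'].nunique()} "
      f"cell lines x {df['readout'].nunique()} readouts "
      f"({len(df)} measurements) -> {OUT / 'dose_response.csv'}")
for drug, spec in STUDY_DRUGS.items():
    print(f"  {drug:14s} mechanism={spec.kind}")
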