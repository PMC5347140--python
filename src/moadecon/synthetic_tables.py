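"""Synthetic stand-in reference tables.

The study's per-cell-line IC50 table and the regioisomer Kd table are not
redistributable here; these deterministic stand-ins are *synthetic*
constructions that reproduce only the published summary constraints (panel
median and quartile bound of the anti-proliferative IC50 distribution; the
7-30-fold regioisomer affinity range across the four class-I PI3K isoforms).
They let the panel-summary and fold-change code paths run end to end; they
are not the original measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bkm120_viability_ic50_table", "regioisomer_kd_table"]


def bkm120_viability_ic50_table() -> pd.DataFrame:
    """Synthetic 44-line anti-proliferative IC50 table (uM).

    Constructed so that the panel median is 1.2 uM and exactly 75% of lines
    have IC50 >= 0.9 uM, with the overall range matching the published
    frequency distribution (~0.1-12 uM).  Columns: cell_line, ic50_um.
    """
    low = np.geomspace(0.30, 0.85, 11)       # the quartile below 0.9 uM
    mid = np.geomspace(0.90, 1.15, 11)
    median_pair = np.array([1.2, 1.2])       # 22nd/23rd order statistics
    high = np.geomspace(1.30, 11.5, 20)
    ic50 = np.concatenate([low, mid, median_pair, high])
    assert ic50.size == 44
    return pd.DataFrame({
        "cell_line": [f"line_{i + 1:02d}" for i in range(44)],
        "ic50_um": np.round(ic50, 4),
    })


def regioisomer_kd_table() -> pd.DataFrame:
    """Synthetic Kd table (nM) for two asymmetric inhibitors and their
    regioisomers across the four class-I PI3K catalytic isoforms.

    Parent compounds bind 7-30-fold tighter than their regioisomers on every
    isoform.  Columns: compound, regioisomer_of, isoform, kd_nm.
    """
    parents = {
        "PIKiN1": {"p110alpha": 12.0, "p110beta": 45.0, "p110gamma": 30.0,
                   "p110delta": 18.0},
        "PIKiN2": {"p110alpha": 3.5, "p110beta": 20.0, "p110gamma": 9.0,
                   "p110delta": 6.0},
    }
    folds = {
        "PIKiN1": {"p110alpha": 9.0, "p110beta": 12.0, "p110gamma": 7.5,
                   "p110delta": 15.0},
        "PIKiN2": {"p110alpha": 22.0, "p110beta": 30.0, "p110gamma": 18.0,
                   "p110delta": 25.0},
    }
    rows = []
    for comp, by_iso in parents.items():
        for iso, kd in by_iso.items():
            rows.append({"compound": comp, "regioisomer_of": "", "isoform": iso,
                         "kd_nm": kd})
            rows.append({"compound": f"{comp}-R1", "regioisomer_of": comp,
                         "isoform": iso, "kd_nm": kd * folds[comp][iso]})
    return pd.DataFrame(rows)
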