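"""Panel-level mechanism profiling across a cell-line x drug matrix.

Hill slopes of viability curves separate drug classes: simple cytostatic
pathway inhibition gives slopes near -1, whereas microtubule-destabilising
(cytotoxic) action gives slopes steeper than -2.  This module assembles the
slope matrix with the panel exclusion rule (a cell line showing high slope
uncertainty for *any* drug is excluded for all drugs), computes least-square
penalty scores between drug pairs, relative-sensitivity profiles, and
phospho-Histone H3 fold-change summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSet, SigmoidFit

logger = logging.getLogger(__name__)

__all__ = [
    "PanelTable",
    "PenaltyScore",
    "hill_slope_table",
    "penalty_score",
    "penalty_score_matrix",
    "sensitivity_profile",
    "phh3_fold_change",
]


@dataclass
class PanelTable:
    """Fits for every (cell_line, drug, readout) combination in a panel."""

    entries: dict[tuple[str, str, str], tuple[DoseResponseSet, SigmoidFit]] = field(
        default_factory=dict
    )

    def add(self, data: DoseResponseSet, fit: SigmoidFit) -> None:
        self.entries[(data.cell_line, data.drug, data.readout)] = (data, fit)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for (line, drug, readout), (_, fit) in self.entries.items():
            rows.append({
                "cell_line": line, "drug": drug, "readout": readout,
                "log_ic50": fit.log_ic50, "ic50_m": fit.ic50,
                "hill_slope": fit.hill_slope, "top": fit.top,
                "bottom": fit.bottom, "se_log_ic50": fit.se_log_ic50,
                "se_hill": fit.se_hill, "ambiguous": fit.ambiguous,
                "converged": fit.converged, "model": fit.model,
            })
        return pd.DataFrame(rows)

    def excluded_lines(self, readout: str = "viability") -> set[str]:
        """Lines with an ambiguous fit for at least one drug on ``readout``."""
        out = set()
        for (line, drug, rdt), (_, fit) in self.entries.items():
            if rdt == readout and fit.ambiguous:
                out.add(line)
        return out


@dataclass
class PenaltyScore:
    """Summed squared Hill-slope differences between two drugs over a panel."""

    drug_a: str
    drug_b: str
    per_line: pd.Series  # index: cell_line -> squared slope difference
    total: float


def hill_slope_table(
    panel: PanelTable | pd.DataFrame, readout: str = "viability"
) -> pd.DataFrame:
    """Cell-line x drug matrix of Hill slopes after the exclusion rule.

    A cell line is excluded whenever at least one of its drug fits on the
    readout is ambiguous; the audit of excluded lines is logged.  Accepts a
    :class:`PanelTable` or a tidy fits frame with columns cell_line, drug,
    readout, hill_slope, ambiguous.
    """
    fits = panel.fits_frame() if isinstance(panel, PanelTable) else panel
    fits = fits[fits["readout"] == readout]
    if fits.empty:
        raise ValueError(f"no fits for readout {readout!r}")
    bad_lines = set(fits.loc[fits["ambiguous"].astype(bool), "cell_line"])
    for line in sorted(bad_lines):
        drugs = fits.loc[
            (fits["cell_line"] == line) & fits["ambiguous"].astype(bool), "drug"
        ].tolist()
        logger.info("excluding line %s (ambiguous slope for %s)", line, drugs)
    kept = fits[~fits["cell_line"].isin(bad_lines)]
    if kept.empty:
        raise ValueError("no cell lines retained after the exclusion rule")
    mat = kept.pivot(index="cell_line", columns="drug", values="hill_slope")
    mat.attrs["excluded_lines"] = sorted(bad_lines)
    return mat


def penalty_score(
    slopes_a: pd.Series, slopes_b: pd.Series,
    drug_a: str = "a", drug_b: str = "b",
) -> PenaltyScore:
    """Least-square penalty score: per line (h_a - h_b)**2, summed.

    Like-mechanism pairs stay near baseline; a microtubule-destabiliser
    paired with a simple PI3K inhibitor exceeds 100 on a 36-line panel.
    The two slope vectors must be aligned on the same retained cell lines.
    """
    if not slopes_a.index.equals(slopes_b.index):
        raise ValueError("slope vectors must be aligned on identical cell lines")
    per_line = (slopes_a - slopes_b) ** 2
    return PenaltyScore(drug_a, drug_b, per_line, float(per_line.sum()))


def penalty_score_matrix(slope_matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric drug x drug matrix of total penalty scores."""
    drugs = list(slope_matrix.columns)
    out = pd.DataFrame(0.0, index=drugs, columns=drugs)
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            t = penalty_score(slope_matrix[a], slope_matrix[b], a, b).total
            out.loc[a, b] = out.loc[b, a] = t
    return out


def sensitivity_profile(ic50s: pd.DataFrame, sort_drug: str) -> pd.DataFrame:
    """IC50s relative to each drug's panel mean, sorted by one drug.

    Each entry is ``IC50(line, drug) / mean over lines of IC50(., drug)``
    (arithmetic mean; missing IC50s are excluded from the mean and left as
    NaN).  Rows are ordered from the most to the least sensitive line for
    ``sort_drug``.
    """
    if sort_drug not in ic50s.columns:
        raise KeyError(f"sort drug {sort_drug!r} not in panel")
    rel = ic50s / ic50s.mean(axis=0, skipna=True)
    return rel.sort_values(by=sort_drug, ascending=True)


def phh3_fold_change(
    treated_fraction: float | np.ndarray, vehicle_fraction: float | np.ndarray
) -> float | np.ndarray:
    """Drug-induced fold change of phospho-Histone H3-positive cells.

    ``fold = treated / vehicle``; > 1 means a mitotic-arrest increase, < 1 a
    decrease (the signature of pure PI3K inhibition).  A zero vehicle
    fraction leaves the fold undefined (NaN) with a log entry.
    """
    treated = np.asarray(treated_fraction, dtype=float)
    vehicle = np.asarray(vehicle_fraction, dtype=float)
    undefined = vehicle == 0
    if np.any(undefined):
        logger.warning("%d fold change(s) undefined: vehicle fraction is 0",
                       int(np.sum(undefined)))
    fold = np.where(undefined, np.nan, treated / np.where(undefined, np.nan, vehicle))
    return float(fold) if fold.ndim == 0 else fold
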