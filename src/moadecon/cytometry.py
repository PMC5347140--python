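"""Per-nucleus high-content classification and per-well summaries.

From a segmented nuclei table (DNA integrated intensity, phospho-Histone H3
mean/max intensities, border flag, condensation features) this module
computes the mitotic index (pHH3-positive fraction), the condensed-DNA
fraction, cell-cycle fractions from the DNA-content histogram, and
proliferation as nuclei counts normalised to vehicle.

Cell-cycle gating is mode-anchored: the G1 peak of the DNA-content
distribution is located and the sub-G1 / G1 / S / G2-M gates are fixed
multiples of the G1 mode (configurable).  This makes the fractions invariant
to any global linear rescaling of intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CycleGates",
    "WellSummary",
    "classify_phh3",
    "condensed_fraction",
    "cell_cycle_fractions",
    "proliferation_from_counts",
    "phh3_threshold_from_vehicle",
    "summarize_well",
]

NUCLEI_COLUMNS = ["well_id", "dna_int", "phh3_mean", "phh3_max", "border"]


@dataclass(frozen=True)
class CycleGates:
    """DNA-content gates as multiples of the G1 mode.

    sub-G1 < ``subg1``; G1 in [``subg1``, ``g1_hi``); S in
    [``g1_hi``, ``s_hi``); G2/M in [``s_hi``, ``g2m_hi``]; above ``g2m_hi``
    is reported separately as >4N and excluded from the four fractions.
    """

    subg1: float = 0.6
    g1_hi: float = 1.3
    s_hi: float = 1.7
    g2m_hi: float = 2.6


@dataclass
class WellSummary:
    well_id: str
    n_nuclei: int
    pct_phh3_positive: float
    pct_condensed: float | None
    cycle_fractions: dict[str, float]
    proliferation_pct_of_vehicle: float | None = None


def _check_nuclei(nuclei: pd.DataFrame, columns=NUCLEI_COLUMNS) -> pd.DataFrame:
    missing = [c for c in columns if c not in nuclei.columns]
    if missing:
        raise ValueError(f"nuclei table is missing columns {missing}")
    return nuclei


def classify_phh3(
    nuclei: pd.DataFrame, mean_threshold: float, max_threshold: float
) -> float:
    """Percent phospho-Histone H3-positive nuclei (mitotic index).

    Two-step rule: a nucleus is positive iff its mean pHH3 intensity *and*
    its maximum pHH3 intensity both exceed their thresholds.  Nuclei at
    image borders never enter the denominator.  Returns NaN (flagged in the
    log) when no non-border nuclei are present.
    """
    n = _check_nuclei(nuclei)
    inner = n[~n["border"].astype(bool)]
    if inner.empty:
        logger.warning("pHH3 fraction undefined: no non-border nuclei")
        return float("nan")
    positive = (inner["phh3_mean"] > mean_threshold) & (inner["phh3_max"] > max_threshold)
    return float(100.0 * positive.sum() / len(inner))


def phh3_threshold_from_vehicle(
    vehicle_nuclei: pd.DataFrame, percentile: float = 99.0
) -> tuple[float, float]:
    """Default per-plate pHH3 thresholds: the given percentile of the
    vehicle wells' mean and max intensities (99th by default)."""
    v = _check_nuclei(vehicle_nuclei)
    inner = v[~v["border"].astype(bool)]
    return (
        float(np.percentile(inner["phh3_mean"], percentile)),
        float(np.percentile(inner["phh3_max"], percentile)),
    )


def condensed_fraction(
    nuclei: pd.DataFrame,
    classifier_threshold: float,
    weights: dict[str, float] | None = None,
) -> float:
    """Percent nuclei classified 'condensed' by a linear score.

    ``score = sum_f weights[f] * nuclei[f]``; a nucleus is condensed when
    the score exceeds the threshold.  The default feature set (intensity
    density positively weighted, area negatively) is a configurable
    stand-in for a trained two-class linear classifier.
    """
    weights = weights or {"intensity_density": 1.0, "area": -20.0}
    missing = [f for f in weights if f not in nuclei.columns]
    if missing:
        raise ValueError(f"nuclei table is missing condensation features {missing}")
    score = sum(w * nuclei[f] for f, w in weights.items())
    return float(100.0 * (score > classifier_threshold).sum() / len(nuclei))


def _g1_mode(dna: np.ndarray) -> float:
    """Locate the G1 peak of the DNA-content distribution.

    Kernel density on log2 intensity.  The diagnostic signature of the G1
    peak is its G2/M companion at ~2x intensity: among local maxima with
    density at least 5% of the global peak, the ~2x-spaced pair with the
    highest combined density is taken as the G1/G2-M doublet and its lower
    member as G1.  Without any such doublet (e.g. a pure single-phase
    population) the global mode is used.
    """
    logd = np.log2(dna[dna > 0])
    if logd.size < 10:
        raise ValueError("too few nuclei to locate a G1 mode")
    kde = stats.gaussian_kde(logd, bw_method=0.15)
    grid = np.linspace(logd.min(), logd.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    strong = peaks[dens[peaks] >= 0.05 * dens.max()]
    if strong.size == 0:
        raise ValueError("no detectable G1 mode in the DNA-content histogram")
    pos, height = grid[strong], dens[strong]
    best_pair, best_height = None, -np.inf
    for i, p in enumerate(pos):
        gap = pos - p  # log2 scale: a 2x partner sits ~1 unit above
        for j in np.flatnonzero((gap >= np.log2(1.7)) & (gap <= np.log2(2.3))):
            if height[i] + height[j] > best_height:
                best_height = height[i] + height[j]
                best_pair = p
    if best_pair is not None:
        return float(2.0 ** best_pair)
    return float(2.0 ** grid[peaks[np.argmax(dens[peaks])]])


def cell_cycle_fractions(
    dna_intensities: np.ndarray | pd.Series,
    gates: CycleGates = CycleGates(),
) -> dict[str, float]:
    """Cell-cycle fractions {subG1, G1, S, G2M} (percent, summing to 100).

    The G1 mode anchors fixed-ratio gates; nuclei above the G2/M gate are
    reported under the extra key ``over4n_pct`` (percent of all nuclei) and
    excluded from the four normalised fractions.
    """
    dna = np.asarray(dna_intensities, dtype=float)
    dna = dna[np.isfinite(dna) & (dna > 0)]
    if dna.size < 10:
        raise ValueError("too few nuclei for cell-cycle analysis")
    mode = _g1_mode(dna)
    r = dna / mode
    counts = {
        "subG1": np.sum(r < gates.subg1),
        "G1": np.sum((r >= gates.subg1) & (r < gates.g1_hi)),
        "S": np.sum((r >= gates.g1_hi) & (r < gates.s_hi)),
        "G2M": np.sum((r >= gates.s_hi) & (r <= gates.g2m_hi)),
    }
    assigned = sum(counts.values())
    if assigned == 0:
        raise ValueError("no nuclei fall inside the cell-cycle gates")
    out = {k: 100.0 * v / assigned for k, v in counts.items()}
    out["over4n_pct"] = float(100.0 * np.sum(r > gates.g2m_hi) / dna.size)
    return out


def proliferation_from_counts(n_treated: int, n_vehicle: int) -> float:
    """Proliferation as percent of vehicle: 100 * n_treated / n_vehicle."""
    if n_vehicle <= 0:
        raise ValueError("vehicle nuclei count must be positive")
    return 100.0 * n_treated / n_vehicle


def summarize_well(
    nuclei: pd.DataFrame,
    well_id: str,
    phh3_mean_threshold: float,
    phh3_max_threshold: float,
    condensed_threshold: float | None = None,
    condensed_weights: dict[str, float] | None = None,
    n_vehicle: int | None = None,
    gates: CycleGates = CycleGates(),
) -> WellSummary:
    """Full per-well summary for one well of a nuclei table."""
    w = _check_nuclei(nuclei)
    w = w[w["well_id"] == well_id]
    if w.empty:
        raise ValueError(f"no nuclei for well {well_id!r}")
    pct_cond = None
    if condensed_threshold is not None:
        pct_cond = condensed_fraction(w, condensed_threshold, condensed_weights)
    return WellSummary(
        well_id=well_id,
        n_nuclei=len(w),
        pct_phh3_positive=classify_phh3(w, phh3_mean_threshold, phh3_max_threshold),
        pct_condensed=pct_cond,
        cycle_fractions=cell_cycle_fractions(w["dna_int"].to_numpy(), gates),
        proliferation_pct_of_vehicle=(
            proliferation_from_counts(len(w), n_vehicle) if n_vehicle else None
        ),
    )
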