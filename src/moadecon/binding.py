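"""TR-FRET competitive-binding analysis and AlphaScreen activity IC50s.

A europium-labelled antibody (donor, 620 nm) and an Alexa647 kinase tracer
(acceptor, 665 nm) report tracer occupancy of the PI3K ATP site; a compound
displacing the tracer lowers the 665/620 emission ratio.  The displacement
IC50 from a normalised variable-slope fit is converted to a dissociation
constant with the Cheng-Prusoff competition correction

    Kd = IC50 / (1 + [tracer] / Kd_tracer).

Tracer constants (Kd and final assay concentration per isoform) are assay
inputs; final tracer concentrations are the 3x-stock values diluted 3-fold
in the equal-volume three-component mix.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .dose_response import DoseResponseSet, SigmoidFit, fit_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "TRACER_KD_NM",
    "TRACER_STOCK_3X_NM",
    "tracer_final_conc_nm",
    "BindingAssay",
    "KdResult",
    "emission_ratio",
    "displacement_ic50",
    "kd_from_ic50",
    "regioisomer_fold",
    "alphascreen_ic50",
]

#: Kinase Tracer314 dissociation constants per class-I PI3K isoform (nM).
TRACER_KD_NM = {"p110alpha": 2.2, "p110beta": 3.5, "p110gamma": 13.9, "p110delta": 4.1}

#: 3x tracer stock concentrations per isoform (nM); final = stock / 3.
TRACER_STOCK_3X_NM = {"p110alpha": 60.0, "p110beta": 75.0, "p110gamma": 75.0,
                      "p110delta": 30.0}


def tracer_final_conc_nm(isoform: str) -> float:
    return TRACER_STOCK_3X_NM[isoform] / 3.0


@dataclass
class BindingAssay:
    """One isoform's displacement plate: raw 665/620 signals over a dilution."""

    isoform: str
    compound_concs_m: np.ndarray
    signals_665: np.ndarray
    signals_620: np.ndarray
    background_665: float
    background_620: float
    kd_tracer_nm: float | None = None
    tracer_conc_nm: float | None = None

    def __post_init__(self) -> None:
        if self.kd_tracer_nm is None:
            self.kd_tracer_nm = TRACER_KD_NM[self.isoform]
        if self.tracer_conc_nm is None:
            self.tracer_conc_nm = tracer_final_conc_nm(self.isoform)
        if self.kd_tracer_nm <= 0 or self.tracer_conc_nm <= 0:
            raise ValueError("tracer Kd and concentration must be positive")


@dataclass
class KdResult:
    isoform: str
    ic50_m: float
    kd_m: float
    hill: float


def emission_ratio(
    s665: np.ndarray | float,
    s620: np.ndarray | float,
    mean_background_665: float,
    mean_background_620: float,
) -> np.ndarray | float:
    """Background-subtracted 665/620 emission ratio.

    Wells whose corrected donor signal (620 nm) is non-positive are dropped
    (NaN) with a warning: the ratio is undefined there.
    """
    a = np.asarray(s665, dtype=float) - mean_background_665
    d = np.asarray(s620, dtype=float) - mean_background_620
    bad = d <= 0
    if np.any(bad):
        logger.warning("%d well(s) dropped: corrected 620 nm signal <= 0",
                       int(np.sum(bad)))
    ratio = np.where(bad, np.nan, a / np.where(bad, np.nan, d))
    return float(ratio) if ratio.ndim == 0 else ratio


def displacement_ic50(
    concs_m: np.ndarray, ratios_pct_of_dmso: np.ndarray,
    isoform: str = "", compound: str = "",
) -> SigmoidFit:
    """Normalised variable-slope fit of % remaining emission vs concentration."""
    ok = np.isfinite(ratios_pct_of_dmso)
    data = DoseResponseSet(
        drug=compound, cell_line=isoform, readout="binding_ratio",
        conc_m=np.asarray(concs_m)[ok],
        response=np.asarray(ratios_pct_of_dmso)[ok],
    )
    return fit_sigmoid(data, model="normalized3p")


def kd_from_ic50(ic50_m: float, tracer_conc_m: float, kd_tracer_m: float) -> float:
    """Cheng-Prusoff competition correction: Kd = IC50/(1 + [L]/Kd_L).

    The correction only shrinks: Kd <= IC50, with equality in the
    zero-tracer limit.
    """
    if min(ic50_m, tracer_conc_m, kd_tracer_m) <= 0:
        raise ValueError("all inputs must be strictly positive")
    return ic50_m / (1.0 + tracer_conc_m / kd_tracer_m)


def regioisomer_fold(kd_parent_m: float, kd_regioisomer_m: float) -> float:
    """Affinity fold of a compound over its regioisomer (Kd_regio / Kd_parent)."""
    if kd_parent_m <= 0 or kd_regioisomer_m <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_regioisomer_m / kd_parent_m


def alphascreen_ic50(
    concs_m: np.ndarray, rlu: np.ndarray, compound: str = ""
) -> SigmoidFit:
    """PI3Kalpha activity IC50 from AlphaScreen PIP3 signals.

    Signals (relative luminescence units) are normalised to the vehicle
    (maximal) signal and fitted with the normalised variable-slope curve.
    """
    rlu = np.asarray(rlu, dtype=float)
    top = float(np.max(rlu))
    if top <= 0:
        raise ValueError("maximal AlphaScreen signal must be positive")
    data = DoseResponseSet(
        drug=compound, cell_line="", readout="alpha_rlu",
        conc_m=concs_m, response=100.0 * rlu / top,
    )
    return fit_sigmoid(data, model="normalized3p")
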