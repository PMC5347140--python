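"""Target engagement at the anti-proliferative IC50 and the therapeutic window.

The central deconvolution question: when a drug halves proliferation, how much
of each of its targets is it actually engaging?  For a pure PI3K inhibitor
~90% pathway inhibition is needed to halve growth, whereas a
microtubule-destabiliser (MDA) halves growth while inducing only a small
fraction of its maximal mitotic-arrest (phospho-Histone H3) response.  For a
dual-activity drug whose two engagement curves sit on top of its proliferation
IC50 there is no concentration window of selective PI3K inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import SigmoidFit, evaluate_sigmoid

__all__ = [
    "EngagementSummary",
    "PlasmaExposure",
    "effect_fraction",
    "engagement_at_growth_ic50",
    "mitosis_pi3k_ratio",
    "concentration_for_engagement",
    "plasma_mean_concentration",
    "therapeutic_window",
    "NONRESPONDER_CAP_M",
]

#: convention for drugs without any mitotic response: the pHH3 EC50 entering
#: the EC50/IC50 ratio is set constant to 20 uM.
NONRESPONDER_CAP_M = 20e-6


@dataclass
class EngagementSummary:
    drug: str
    cell_line: str
    prolif_ic50: float  # molar
    pi3k_engagement_at_ic50: float | None  # percent inhibition of pPKB
    mda_engagement_at_ic50: float | None  # percent of maximal pHH3
    ec50_ratio: float | None  # EC50(pHH3) / IC50(pPKB)
    window_exists: bool | None = None


@dataclass
class PlasmaExposure:
    """Published plasma exposure: mean concentration is AUC(0-24h)/24 h."""

    dose_mg: float
    auc_0_24_um_h: float

    @property
    def mean_conc_um(self) -> float:
        return plasma_mean_concentration(self.auc_0_24_um_h)


def effect_fraction(fit: SigmoidFit, x: float) -> float:
    """Percent of the curve's maximal effect attained at concentration ``x``.

    For an inhibition curve (negative hill, response falls from top to
    bottom) the effect is the inhibition attained, ``100*(top - y)/span``;
    for an activation curve (positive hill) it is ``100*(y - bottom)/span``.
    Either way the value runs from 0 (no effect) to 100 (maximal effect).
    """
    if fit.span <= 0:
        raise ValueError("degenerate fit: top must exceed bottom")
    y = evaluate_sigmoid(fit, x)
    if fit.hill_slope < 0:
        frac = (fit.top - y) / fit.span
    else:
        frac = (y - fit.bottom) / fit.span
    return float(100.0 * frac)


def engagement_at_growth_ic50(
    prolif_fit: SigmoidFit, target_fit: SigmoidFit
) -> tuple[float, bool]:
    """Target engagement (% of maximal effect) at the proliferation IC50.

    Returns ``(engagement_percent, extrapolated)``; the flag is set when the
    proliferation IC50 lies outside the target curve's tested concentration
    range, i.e. the engagement level is an extrapolation of the target fit.
    """
    if prolif_fit.ambiguous or target_fit.ambiguous:
        raise ValueError("both fits must be non-ambiguous")
    if not np.isfinite(prolif_fit.log_ic50):
        raise ValueError("proliferation IC50 is undefined")
    x = prolif_fit.ic50
    extrapolated = not (
        target_fit.log_conc_min <= prolif_fit.log_ic50 <= target_fit.log_conc_max
    )
    return effect_fraction(target_fit, x), extrapolated


def mitosis_pi3k_ratio(
    mean_ec50_phh3: float | None,
    mean_ic50_ppkb: float,
    nonresponder_cap: float = NONRESPONDER_CAP_M,
) -> float:
    """Ratio of mitotic-arrest EC50 (pHH3) to PI3K-inhibition IC50 (pPKB).

    A drug with no detectable mitotic response has its pHH3 EC50 replaced by
    the 20 uM non-responder cap (pass ``None``/NaN for the EC50).  Large
    ratios mean PI3K inhibition occurs far below any mitotic effect; ratios
    near 1 mean the two activities are inseparable by dose.
    """
    if not np.isfinite(mean_ic50_ppkb) or mean_ic50_ppkb <= 0:
        raise ValueError("pPKB IC50 must be positive")
    ec50 = mean_ec50_phh3
    if ec50 is None or not np.isfinite(ec50):
        ec50 = nonresponder_cap
    return float(ec50 / mean_ic50_ppkb)


def concentration_for_engagement(target_fit: SigmoidFit, level: float) -> float:
    """Molar concentration at which the target curve reaches ``level``% of
    its maximal effect (inverse of :func:`effect_fraction`).

    Closed form: ``x = EC50 * (level / (100 - level)) ** (1 / |hill|)``.
    """
    if target_fit.ambiguous:
        raise ValueError("cannot invert an ambiguous fit")
    if not (0.0 < level < 100.0):
        raise ValueError("engagement level must lie strictly inside (0, 100)")
    h = abs(target_fit.hill_slope)
    if h == 0 or not np.isfinite(h):
        raise ValueError("fit has no usable slope")
    return float(target_fit.ic50 * (level / (100.0 - level)) ** (1.0 / h))


def plasma_mean_concentration(auc_0_24_um_h: float) -> float:
    """Mean steady-state plasma concentration (uM) from AUC(0-24h) in uM*h."""
    if auc_0_24_um_h <= 0:
        raise ValueError("AUC must be positive")
    return auc_0_24_um_h / 24.0


def therapeutic_window(
    pi3k_fit: SigmoidFit,
    mda_fit: SigmoidFit,
    pi3k_required: float,
    mda_tolerated: float,
) -> dict:
    """Window of selective PI3K inhibition between two engagement curves.

    The window spans from the concentration reaching ``pi3k_required``
    percent PI3K engagement up to the concentration reaching
    ``mda_tolerated`` percent of the maximal MDA (pHH3) effect; it exists
    iff the lower bound is below the upper bound.  Unreachable thresholds
    close the window with a reason.
    """
    out = {"window_exists": False, "window_low_m": None, "window_high_m": None,
           "reason": None}
    try:
        low = concentration_for_engagement(pi3k_fit, pi3k_required)
    except ValueError as exc:
        out["reason"] = f"PI3K threshold unreachable: {exc}"
        return out
    try:
        high = concentration_for_engagement(mda_fit, mda_tolerated)
    except ValueError as exc:
        out["reason"] = f"MDA threshold unreachable: {exc}"
        return out
    out["window_low_m"] = low
    out["window_high_m"] = high
    out["window_exists"] = bool(low < high)
    if not out["window_exists"]:
        out["reason"] = (
            "required PI3K engagement is only reached at concentrations "
            "already exceeding the tolerated MDA effect"
        )
    return out
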