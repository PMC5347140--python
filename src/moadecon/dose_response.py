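"""Dose-response normalisation and variable-slope sigmoid fitting.

Every downstream stage of the package (panel profiling, target engagement,
binding affinity, turbidity analysis, high-content proliferation) reduces to
fitting the four-parameter logistic

    y(x) = bottom + (top - bottom) / (1 + 10**((log10(IC50) - log10(x)) * h))

to a percent-scale response measured over a dilution series.  ``h`` is the
Hill slope; for inhibition readouts it is negative (response falls with
concentration), for activation readouts (e.g. phospho-Histone H3 appearance)
it is positive.  The "normalized" three-parameter variant fixes
``top = 100`` and ``bottom = 0``.

Fits are least-squares on the log10-concentration scale with a multi-start
strategy (steep-slope objectives are multimodal) and curvature-based standard
errors.  A fit is flagged *ambiguous* when the slope is not reliably
determined; ambiguous slopes are excluded from downstream mechanism
classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseSet",
    "SigmoidFit",
    "normalize_viability",
    "doubling_time",
    "normalize_incellwestern",
    "fit_sigmoid",
    "evaluate_sigmoid",
    "invert_sigmoid",
]

#: log10 distance outside the tested range beyond which a fitted IC50 is
#: considered unsupported by the data (part of the ambiguity rule).
_RANGE_SLACK = 1.0

#: relative threshold on the slope standard error above which the slope is
#: declared ambiguous: |se_hill / hill| > 0.5.
_SE_HILL_FRAC = 0.5


@dataclass
class DoseResponseSet:
    """A single (drug, cell line, readout) dilution-series measurement.

    Concentrations are molar and strictly positive; responses are on a
    percent scale after normalisation (raw units are allowed pre-fit only
    for readouts fitted with the full 4-parameter model).
    """

    drug: str
    cell_line: str
    readout: str
    conc_m: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    vehicle_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc_m = np.asarray(self.conc_m, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc_m.shape != self.response.shape:
            raise ValueError("conc_m and response must have identical shape")
        if not np.all(np.isfinite(self.conc_m)) or np.any(self.conc_m <= 0):
            raise ValueError("concentrations must be finite and strictly positive")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")

    @property
    def n_distinct_conc(self) -> int:
        return np.unique(self.conc_m).size


@dataclass
class SigmoidFit:
    """Result of a variable-slope logistic fit.

    ``log_ic50`` is log10 molar.  ``ambiguous`` means the slope (and hence
    the mechanism classification) must not be used downstream; the IC50 may
    additionally be ``extrapolated`` when it falls more than one log10 unit
    outside the tested range.
    """

    log_ic50: float
    hill_slope: float
    top: float
    bottom: float
    se_log_ic50: float
    se_hill: float
    model: str  # "normalized3p" | "full4p"
    converged: bool
    ambiguous: bool
    rss: float
    n_points: int = 0
    log_conc_min: float = float("nan")
    log_conc_max: float = float("nan")
    extrapolated: bool = False

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)

    @property
    def span(self) -> float:
        return self.top - self.bottom


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize_viability(
    raw_t72: np.ndarray | Sequence[float],
    untreated_t72: float,
    t0: float | None = None,
) -> np.ndarray:
    """Percent growth after 72 h: ``100 * raw / untreated``.

    ``t0`` (the t=0 h signal of the parallel untreated plate) is used only
    for the doubling-time growth-control QC; when absent the QC is skipped
    with a warning.
    """
    raw = np.asarray(raw_t72, dtype=float)
    if not np.isfinite(untreated_t72) or untreated_t72 <= 0:
        raise ValueError("untreated t=72h signal must be positive")
    if t0 is None:
        warnings.warn("t=0 signal missing: doubling-time QC skipped", stacklevel=2)
    return 100.0 * raw / float(untreated_t72)


def doubling_time(t0: float, untreated_t72: float, hours: float = 72.0) -> float:
    """Cellular doubling time (h) from t=0 and untreated t=72 h signals."""
    if t0 <= 0 or untreated_t72 <= t0:
        raise ValueError("signals must satisfy 0 < t0 < untreated_t72 for growth")
    return hours * np.log(2.0) / np.log(untreated_t72 / t0)


def normalize_incellwestern(
    ppkb_signal: np.ndarray,
    tubulin_signal: np.ndarray,
    dmso_mask: np.ndarray,
    background_ppkb: float,
    background_tubulin: float,
) -> np.ndarray:
    """Percent remaining pSer473-PKB signal, tubulin-corrected.

    Per well: ``ratio = (pPKB - bg) / (tubulin - bg)``; the result is
    ``100 * ratio / mean(ratio over DMSO wells)``.  Wells whose corrected
    tubulin signal is non-positive are dropped (returned as NaN) with a
    warning, since the protein correction is undefined there.
    """
    ppkb = np.asarray(ppkb_signal, dtype=float)
    tub = np.asarray(tubulin_signal, dtype=float)
    dmso = np.asarray(dmso_mask, dtype=bool)
    if not dmso.any():
        raise ValueError("at least one DMSO control well is required")
    tub_corr = tub - background_tubulin
    bad = tub_corr <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} well(s) dropped: corrected tubulin signal <= 0",
            stacklevel=2,
        )
    ratio = np.where(bad, np.nan, (ppkb - background_ppkb) / np.where(bad, np.nan, tub_corr))
    dmso_mean = np.nanmean(ratio[dmso])
    if not np.isfinite(dmso_mean) or dmso_mean <= 0:
        raise ValueError("DMSO control ratio is non-positive; cannot normalise")
    return 100.0 * ratio / dmso_mean


# ---------------------------------------------------------------------------
# the logistic model
# ---------------------------------------------------------------------------

def _logistic(logx: np.ndarray, log_ic50: float, hill: float,
              top: float, bottom: float) -> np.ndarray:
    expo = np.clip((log_ic50 - logx) * hill, -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0 ** expo)


def evaluate_sigmoid(fit: SigmoidFit, x: float | np.ndarray) -> float | np.ndarray:
    """Closed-form response of a fitted curve at molar concentration ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    out = _logistic(np.log10(x), fit.log_ic50, fit.hill_slope, fit.top, fit.bottom)
    return float(out) if out.ndim == 0 else out


def invert_sigmoid(fit: SigmoidFit, y: float) -> float:
    """Unique molar concentration at which the fitted curve equals ``y``.

    Requires ``bottom < y < top`` (the open response span) and a
    non-ambiguous fit; the closed form is

        log10(x) = log_ic50 - log10((top - y)/(y - bottom)) / hill
    """
    if fit.ambiguous:
        raise ValueError("cannot invert an ambiguous fit")
    lo, hi = min(fit.bottom, fit.top), max(fit.bottom, fit.top)
    if not (lo < y < hi):
        raise ValueError(
            f"response level {y} is unreachable (span is ({lo}, {hi}))"
        )
    logx = fit.log_ic50 - np.log10((fit.top - y) / (y - fit.bottom)) / fit.hill_slope
    return float(10.0 ** logx)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _multistart_grid(logc: np.ndarray, resp: np.ndarray) -> tuple[list[float], list[float]]:
    """Starting values: hill over the canonical magnitudes, both signs chosen
    by the empirical trend; log IC50 over the quartiles of the tested range."""
    slope_sign = -1.0
    if logc.size >= 2:
        trend = np.polyfit(logc, resp, 1)[0]
        slope_sign = 1.0 if trend > 0 else -1.0
    hills = [slope_sign * m for m in (0.5, 1.0, 2.0, 4.0)]
    qs = np.quantile(logc, [0.25, 0.5, 0.75])
    return hills, list(dict.fromkeys(np.round(qs, 6)))


def _fit_once(logc, resp, model, x0, bounds):
    if model == "normalized3p":
        def residuals(p):
            return _logistic(logc, p[0], p[1], 100.0, 0.0) - resp
    else:
        def residuals(p):
            # p = (log_ic50, hill, bottom, span); span >= 0 enforces top >= bottom
            return _logistic(logc, p[0], p[1], p[2] + p[3], p[2]) - resp
    return least_squares(residuals, x0, bounds=bounds, method="trf",
                         xtol=1e-12, ftol=1e-12, gtol=1e-12)


def fit_sigmoid(
    data: DoseResponseSet,
    model: str = "full4p",
) -> SigmoidFit:
    """Fit the variable-slope logistic to a dilution series.

    ``model="normalized3p"`` fixes top = 100 and bottom = 0 (the normalised
    curve used for tubulin-corrected pPKB, tracer displacement and turbidity
    data); ``model="full4p"`` fits asymptotes with the constraint
    ``top >= bottom`` (parameterised as bottom + non-negative span).

    At least four distinct concentrations are required.  Standard errors come
    from the Gauss-Newton curvature of the objective at the optimum.  The fit
    is flagged ambiguous when it fails to converge, when
    ``|se_hill / hill| > 0.5``, when the fitted IC50 lies more than one
    log10 unit outside the tested range, or when the modelled response
    change across the tested range is below 10% of the curve span (no
    detectable response within the dilution series).
    """
    if model not in ("normalized3p", "full4p"):
        raise ValueError(f"unknown model {model!r}")
    if data.n_distinct_conc < 4:
        raise ValueError("at least 4 distinct concentrations are required to fit")

    logc = np.log10(data.conc_m)
    resp = data.response
    lo, hi = float(logc.min()), float(logc.max())
    hills, lics = _multistart_grid(logc, resp)

    if model == "normalized3p":
        bounds = ([lo - 6.0, -50.0], [hi + 6.0, 50.0])
        starts = [[l, h] for h in hills for l in lics]
    else:
        rmin, rmax = float(resp.min()), float(resp.max())
        span0 = max(rmax - rmin, 1e-6)
        bounds = (
            [lo - 6.0, -50.0, rmin - 10.0 * span0 - 1.0, 0.0],
            [hi + 6.0, 50.0, rmax + 10.0 * span0 + 1.0, 20.0 * span0 + 1.0],
        )
        starts = [[l, h, rmin, span0] for h in hills for l in lics]

    best = None
    for x0 in starts:
        try:
            res = _fit_once(logc, resp, model, x0, bounds)
        except Exception:  # pragma: no cover - solver pathologies
            continue
        if best is None:
            best = res
            continue
        rss_new, rss_old = 2 * res.cost, 2 * best.cost
        if rss_new < rss_old * (1 - 1e-9) or (
            abs(rss_new - rss_old) <= 1e-9 * max(rss_old, 1e-12)
            and abs(res.x[1]) < abs(best.x[1])
        ):
            best = res

    if best is None or not best.success:
        logger.warning("sigmoid fit did not converge for %s/%s/%s",
                       data.drug, data.cell_line, data.readout)
        nan = float("nan")
        return SigmoidFit(nan, nan, 100.0, 0.0, nan, nan, model,
                          converged=False, ambiguous=True, rss=nan,
                          n_points=resp.size, log_conc_min=lo, log_conc_max=hi)

    p = best.x
    rss = float(2 * best.cost)
    n, k = resp.size, p.size
    # curvature-based covariance; singular information -> infinite SEs
    jtj = best.jac.T @ best.jac
    sigma2 = rss / max(n - k, 1)
    try:
        cov = np.linalg.inv(jtj) * sigma2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)

    if model == "normalized3p":
        top, bottom = 100.0, 0.0
    else:
        bottom, span = float(p[2]), float(p[3])
        top = bottom + span

    log_ic50, hill = float(p[0]), float(p[1])
    se_l, se_h = float(se[0]), float(se[1])

    span = abs(top - bottom)
    in_range_change = abs(
        _logistic(np.array([lo]), log_ic50, hill, top, bottom)[0]
        - _logistic(np.array([hi]), log_ic50, hill, top, bottom)[0]
    )
    ambiguous = (
        not np.isfinite(se_h)
        or hill == 0.0
        or abs(se_h / hill) > _SE_HILL_FRAC
        or log_ic50 < lo - _RANGE_SLACK
        or log_ic50 > hi + _RANGE_SLACK
        or in_range_change < 0.1 * span
    )
    extrapolated = not (lo <= log_ic50 <= hi)
    if ambiguous:
        logger.info("ambiguous fit for %s/%s/%s (hill=%.3g, se_hill=%.3g)",
                    data.drug, data.cell_line, data.readout, hill, se_h)

    return SigmoidFit(
        log_ic50=log_ic50, hill_slope=hill, top=top, bottom=bottom,
        se_log_ic50=se_l, se_hill=se_h, model=model, converged=True,
        ambiguous=ambiguous, rss=rss, n_points=n,
        log_conc_min=lo, log_conc_max=hi, extrapolated=extrapolated,
    )
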