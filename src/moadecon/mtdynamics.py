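"""Microtubule dynamic-instability statistics and turbidity dose-response.

Input is a kymograph event table: alternating growth/shortening phases with
length (um), duration (s), end fate (catastrophe / rescue / unresolved) and a
completeness flag.  Upstream kymograph tracing (pixels -> events) is out of
scope; the event schema is the interface.

Two catastrophe-frequency conventions are implemented, because the in vitro
reconstitution and cellular imaging analyses differ:

* ``in_vitro``: per movie the inverse mean growth time (1 / <t_growth>),
  averaged across movies.  A ``per_event_inverse`` variant (mean of 1/t per
  movie) is exposed for comparison; it systematically overweights short
  events and is not the default.
* ``cellular``: per cell the number of growth events divided by the total
  growth time in minutes.

For a single group, N / sum(t) and 1 / mean(t) coincide; both converge to
the generating rate when growth durations are exponential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DoseResponseSet, SigmoidFit, fit_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_GROWTH_LENGTH_UM",
    "DynamicsSummary",
    "filter_events",
    "growth_rate",
    "catastrophe_frequency",
    "rescue_frequency",
    "turbidity_analysis",
    "compare_conditions",
]

#: growth events shorter than this are excluded (boundary inclusive: an
#: event of exactly 0.5 um is retained).
MIN_GROWTH_LENGTH_UM = 0.5

EVENT_COLUMNS = ["id", "phase", "length_um", "duration_s", "end_fate", "complete"]


@dataclass
class DynamicsSummary:
    """Per-condition summary used in condition comparisons."""

    condition: str
    growth_rate_um_min: float
    growth_rate_sd: float
    catastrophe_freq: float
    catastrophe_unit: str
    rescue_freq_per_s: float
    n_events: int
    grouping: str  # "per_movie" | "per_cell"


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    if (events["duration_s"] <= 0).any() or (events["length_um"] < 0).any():
        raise ValueError("durations must be > 0 and lengths >= 0")
    return events


def filter_events(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the kymograph quality filters.

    Removes (i) incomplete events (start or end not clearly observed) for
    all phases and (ii) growth events shorter than 0.5 um (the boundary is
    inclusive).  Counts of removed events are logged as the audit trail.
    """
    raw = _check_events(raw)
    complete = raw["complete"].astype(bool)
    n_incomplete = int((~complete).sum())
    kept = raw[complete]
    short = (kept["phase"] == "growth") & (kept["length_um"] < MIN_GROWTH_LENGTH_UM)
    n_short = int(short.sum())
    kept = kept[~short]
    logger.info("event filter: removed %d incomplete, %d short-growth; %d kept",
                n_incomplete, n_short, len(kept))
    return kept.reset_index(drop=True)


def growth_rate(events: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Growth velocities (um/min) grouped per movie/cell.

    Per-event velocity is length/duration; velocities are averaged within
    each group (movie in vitro, cell in cells), and the summary is the
    mean +/- s.d. across group means.  Empty groups are dropped with a
    warning.  Returns ``(group_means, mean, sd)``.
    """
    g = _check_events(events)
    g = g[g["phase"] == "growth"]
    if g.empty:
        raise ValueError("no growth events")
    vel = 60.0 * g["length_um"] / g["duration_s"]
    group_means = vel.groupby(g["id"]).mean()
    return group_means, float(group_means.mean()), float(group_means.std(ddof=1))


def catastrophe_frequency(
    events: pd.DataFrame,
    mode: str = "in_vitro",
    variant: str = "inverse_mean",
) -> tuple[pd.Series, float]:
    """Catastrophe frequency per group and its across-group mean.

    ``mode="in_vitro"`` returns per-second frequencies: per movie
    1/mean(growth duration) (default variant) or mean(1/duration)
    (``variant="per_event_inverse"``).  ``mode="cellular"`` returns
    per-minute frequencies: per cell N_growth_events / total growth time in
    minutes.  Returns ``(per_group, mean_over_groups)``.
    """
    g = _check_events(events)
    g = g[g["phase"] == "growth"]
    if g.empty or g["duration_s"].sum() <= 0:
        raise ValueError("no growth time observed")
    grouped = g.groupby("id")["duration_s"]
    if mode == "in_vitro":
        if variant == "inverse_mean":
            per_group = 1.0 / grouped.mean()
        elif variant == "per_event_inverse":
            per_group = grouped.apply(lambda t: float(np.mean(1.0 / t)))
        else:
            raise ValueError(f"unknown variant {variant!r}")
    elif mode == "cellular":
        per_group = grouped.count() / (grouped.sum() / 60.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return per_group, float(per_group.mean())


def rescue_frequency(events: pd.DataFrame) -> float:
    """Rescues per second of shortening: N_rescue / total shortening time.

    Undefined (NaN, with a warning) when no shortening time was observed.
    """
    s = _check_events(events)
    s = s[s["phase"] == "shortening"]
    total = float(s["duration_s"].sum())
    if total <= 0:
        logger.warning("rescue frequency undefined: no shortening time observed")
        return float("nan")
    n_rescue = int((s["end_fate"] == "rescue").sum())
    return n_rescue / total


def turbidity_analysis(
    curves: pd.DataFrame, vehicle_condition: str = "DMSO"
) -> tuple[pd.DataFrame, SigmoidFit | None]:
    """Tubulin-polymerisation dose-response from OD340 time series.

    ``curves`` columns: well, condition, conc_M, time_min, od340.  Per well
    the t=0 absorbance is subtracted (delta OD340); per condition the
    maximal delta OD340 is normalised to the vehicle mean (x100).  When at
    least four distinct drug concentrations are present, the normalised
    maxima are fitted with the normalised variable-slope curve.
    Returns ``(per-condition table, fit-or-None)``.
    """
    required = {"well", "condition", "conc_M", "time_min", "od340"}
    if not required.issubset(curves.columns):
        raise ValueError(f"turbidity table must have columns {sorted(required)}")

    def delta_max(well_df: pd.DataFrame) -> float:
        w = well_df.sort_values("time_min")
        return float((w["od340"] - w["od340"].iloc[0]).max())

    per_well = (
        curves.groupby(["condition", "conc_M", "well"], dropna=False)
        .apply(delta_max, include_groups=False)
        .rename("delta_od_max")
        .reset_index()
    )
    veh = per_well[per_well["condition"] == vehicle_condition]
    if veh.empty:
        raise ValueError(f"no vehicle condition {vehicle_condition!r} present")
    veh_max = float(veh["delta_od_max"].mean())
    if veh_max <= 0:
        raise ValueError("vehicle delta OD340 max must be positive")
    per_cond = (
        per_well.groupby(["condition", "conc_M"], dropna=False)["delta_od_max"]
        .mean()
        .reset_index()
    )
    per_cond["pct_of_vehicle"] = 100.0 * per_cond["delta_od_max"] / veh_max

    drug = per_cond[(per_cond["condition"] != vehicle_condition)
                    & per_cond["conc_M"].notna() & (per_cond["conc_M"] > 0)]
    fit = None
    if drug["conc_M"].nunique() >= 4:
        data = DoseResponseSet(
            drug=str(drug["condition"].iloc[0]), cell_line="", readout="turbidity",
            conc_m=drug["conc_M"].to_numpy(),
            response=drug["pct_of_vehicle"].to_numpy(),
        )
        fit = fit_sigmoid(data, model="normalized3p")
    return per_cond, fit


def compare_conditions(
    summaries_a: np.ndarray | pd.Series, summaries_b: np.ndarray | pd.Series
) -> float:
    """Two-sided Mann-Whitney rank test on per-movie / per-cell summaries."""
    a = np.asarray(summaries_a, dtype=float)
    b = np.asarray(summaries_b, dtype=float)
    if min(a.size, b.size) < 3:
        logger.warning("group size < 3: rank test is weakly powered")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
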