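"""End-to-end pipeline: simulate -> fit -> panel -> engagement -> report.

The driver reproduces the deconvolution logic on synthetic panels: fit every
(drug, line, readout) dilution series, build the Hill-slope matrix with the
exclusion audit, score drug pairs, summarise target engagement at the
proliferation IC50 and decide whether a window of selective PI3K inhibition
exists.  Optional stages exercise the binding, microtubule-dynamics and
high-content modules on matched synthetic inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding as bd
from . import cytometry as cy
from . import mtdynamics as mt
from .dose_response import SigmoidFit, fit_sigmoid
from .engagement import (concentration_for_engagement, effect_fraction,
                         engagement_at_growth_ic50, mitosis_pi3k_ratio)
from .io import RunConfig, dose_response_frame
from .panel import (PanelTable, hill_slope_table, penalty_score_matrix,
                    sensitivity_profile)
from .simulate import (BKM120_LIKE, MTD147_LIKE, PQR309_LIKE, MechanismSpec,
                       ScenarioSeed, gen_binding, gen_kymo_events, gen_nuclei,
                       gen_study)

logger = logging.getLogger(__name__)

__all__ = ["STUDY_DRUGS", "READOUT_MODELS", "fit_study", "mean_fit",
           "drug_engagement", "run_pipeline"]

#: the simulated study: one pure PI3K inhibitor plus two reference PI3K
#: inhibitors, the dual-activity parent, and the pure destabiliser.
STUDY_DRUGS: dict[str, MechanismSpec] = {
    "pqr309_like": PQR309_LIKE,
    "gdc0941_like": replace(PQR309_LIKE, pi3k_ec50=0.7e-6),
    "gdc0980_like": replace(PQR309_LIKE, pi3k_ec50=1.4e-6),
    "bkm120_like": BKM120_LIKE,
    "mtd147_like": MTD147_LIKE,
}

READOUT_MODELS = {"viability": "full4p", "pPKB": "normalized3p", "pHH3": "full4p"}


def fit_study(panels: dict) -> PanelTable:
    """Fit every dilution series of a simulated study."""
    table = PanelTable()
    for drug, lines in panels.items():
        for line, readouts in lines.items():
            for rdt, ds in readouts.items():
                table.add(ds, fit_sigmoid(ds, model=READOUT_MODELS[rdt]))
    return table


def mean_fit(fits: list[SigmoidFit]) -> SigmoidFit | None:
    """Panel-mean curve: average parameters over non-ambiguous fits."""
    ok = [f for f in fits if not f.ambiguous and np.isfinite(f.log_ic50)]
    if not ok:
        return None
    return SigmoidFit(
        log_ic50=float(np.mean([f.log_ic50 for f in ok])),
        hill_slope=float(np.mean([f.hill_slope for f in ok])),
        top=float(np.mean([f.top for f in ok])),
        bottom=float(np.mean([f.bottom for f in ok])),
        se_log_ic50=float(np.std([f.log_ic50 for f in ok], ddof=0)),
        se_hill=0.0, model=ok[0].model, converged=True, ambiguous=False,
        rss=float("nan"), n_points=len(ok),
        log_conc_min=min(f.log_conc_min for f in ok),
        log_conc_max=max(f.log_conc_max for f in ok),
    )


def _drug_fits(table: PanelTable, drug: str, readout: str) -> list[SigmoidFit]:
    return [fit for (line, d, r), (_, fit) in table.entries.items()
            if d == drug and r == readout]


def drug_engagement(table: PanelTable, drug: str, config: RunConfig) -> dict:
    """Per-drug engagement summary on the panel.

    Mean curves over lines give the proliferation IC50, the pPKB and pHH3
    EC50s, per-line engagement levels at each line's own growth IC50
    (mean +/- s.d.), the pHH3/pPKB EC50 ratio (with the non-responder cap),
    and the selective-inhibition window.
    """
    viab = mean_fit(_drug_fits(table, drug, "viability"))
    ppkb = mean_fit(_drug_fits(table, drug, "pPKB"))
    phh3 = mean_fit(_drug_fits(table, drug, "pHH3"))
    phh3_responsive = phh3 is not None and phh3.span >= config.phh3_min_response_pct

    out: dict = {"drug": drug,
                 "prolif_ic50_m": viab.ic50 if viab else None,
                 "viability_hill": viab.hill_slope if viab else None}

    # per-line engagement at that line's own proliferation IC50
    pi3k_lv, mda_lv = [], []
    lines = {line for (line, d, r) in table.entries if d == drug}
    for line in lines:
        vfit = table.entries.get((line, drug, "viability"), (None, None))[1]
        if vfit is None or vfit.ambiguous:
            continue
        pfit = table.entries.get((line, drug, "pPKB"), (None, None))[1]
        hfit = table.entries.get((line, drug, "pHH3"), (None, None))[1]
        if pfit is not None and not pfit.ambiguous:
            pi3k_lv.append(engagement_at_growth_ic50(vfit, pfit)[0])
        if (hfit is not None and not hfit.ambiguous
                and hfit.span >= config.phh3_min_response_pct):
            mda_lv.append(engagement_at_growth_ic50(vfit, hfit)[0])

    out["pi3k_engagement_at_ic50_pct"] = float(np.mean(pi3k_lv)) if pi3k_lv else None
    out["pi3k_engagement_sd"] = float(np.std(pi3k_lv, ddof=1)) if len(pi3k_lv) > 1 else None
    out["mda_engagement_at_ic50_pct"] = float(np.mean(mda_lv)) if mda_lv else None
    out["mda_engagement_sd"] = float(np.std(mda_lv, ddof=1)) if len(mda_lv) > 1 else None

    # EC50(pHH3) / IC50(pPKB) with the 20 uM non-responder cap
    if ppkb is not None:
        ic50_ppkb = ppkb.ic50
        ec50_phh3 = phh3.ic50 if phh3_responsive else None
        out["ec50_ratio"] = mitosis_pi3k_ratio(
            ec50_phh3, ic50_ppkb, config.nonresponder_cap_m)
        out["phh3_ec50_capped"] = ec50_phh3 is None
    else:
        out["ec50_ratio"] = None
        out["phh3_ec50_capped"] = None

    # window of selective PI3K inhibition
    if ppkb is not None:
        try:
            low = concentration_for_engagement(ppkb, config.pi3k_required_pct)
        except ValueError:
            low = None
        if phh3_responsive:
            high = concentration_for_engagement(phh3, config.mda_tolerated_pct)
        else:
            high = config.nonresponder_cap_m  # no mitotic response below the cap
        out["window_low_m"] = low
        out["window_high_m"] = high
        out["window_exists"] = bool(low is not None and low < high)
    else:
        out["window_low_m"] = out["window_high_m"] = out["window_exists"] = None
    return out


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the study end to end; returns the result bundle.

    Deterministic for a given config: every random draw descends from
    ``config.seed``.  With ``write=True`` the tables are saved under
    ``config.outdir`` together with a JSON window report.
    """
    drugs = (STUDY_DRUGS if config.scenario == "full"
             else {config.scenario: STUDY_DRUGS[config.scenario]})
    scenario = ScenarioSeed(seed=config.seed, n_lines=config.n_lines,
                            n_replicates=config.n_replicates)
    panels = gen_study(drugs, scenario)
    table = fit_study(panels)
    fits = table.fits_frame()

    results: dict = {"config": config, "panel": table, "fits": fits}

    viab_fits = fits[fits["readout"] == "viability"]
    if len(drugs) > 1:
        slopes = hill_slope_table(viab_fits)
        results["hill_slopes"] = slopes
        results["excluded_lines"] = slopes.attrs["excluded_lines"]
        results["penalty_scores"] = penalty_score_matrix(slopes)
        ic50s = viab_fits[~viab_fits["cell_line"].isin(
            slopes.attrs["excluded_lines"])].pivot(
            index="cell_line", columns="drug", values="ic50_m")
        sort_drug = "pqr309_like" if "pqr309_like" in ic50s.columns else ic50s.columns[0]
        results["sensitivity"] = sensitivity_profile(ic50s, sort_drug)

    engagement = pd.DataFrame([drug_engagement(table, d, config) for d in drugs])
    results["engagement"] = engagement

    if config.run_optional_stages:
        results["binding"] = _binding_stage(config)
        results["mtdynamics"] = _mtdyn_stage(config)
        results["cytometry"] = _cytometry_stage(config)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dose_response_frame(panels).to_csv(outdir / "dose_response.csv", index=False)
        fits.to_csv(outdir / "fits.csv", index=False)
        if "hill_slopes" in results:
            results["hill_slopes"].to_csv(outdir / "hill_slopes.csv")
            results["penalty_scores"].to_csv(outdir / "penalty_scores.csv")
            results["sensitivity"].to_csv(outdir / "sensitivity_profile.csv")
        engagement.to_csv(outdir / "engagement.csv", index=False)
        report = engagement.replace({np.nan: None}).to_dict(orient="records")
        (outdir / "window_report.json").write_text(json.dumps(report, indent=2))
    return results


def _binding_stage(config: RunConfig) -> pd.DataFrame:
    """Kd round trip per isoform at the published tracer constants."""
    concs = 120e-6 / 4.0 ** np.arange(10)  # fourfold series, 120 uM .. 0.46 nM
    rows = []
    for k, (iso, kd_tr) in enumerate(bd.TRACER_KD_NM.items()):
        true_kd = 50e-9
        tracer = bd.tracer_final_conc_nm(iso) * 1e-9
        assay, ratio0 = gen_binding(true_kd, kd_tr * 1e-9, tracer, concs,
                                    noise=0.02, seed=config.seed + 7000 + k,
                                    isoform=iso)
        ratios = bd.emission_ratio(assay.signals_665, assay.signals_620,
                                   assay.background_665, assay.background_620)
        pct = 100.0 * ratios / np.mean(ratio0)
        fit = bd.displacement_ic50(assay.compound_concs_m, pct, isoform=iso)
        kd = bd.kd_from_ic50(fit.ic50, tracer, kd_tr * 1e-9)
        rows.append({"isoform": iso, "true_kd_nm": true_kd * 1e9,
                     "ic50_nm": fit.ic50 * 1e9, "kd_nm": kd * 1e9,
                     "hill": fit.hill_slope})
    return pd.DataFrame(rows)


def _mtdyn_stage(config: RunConfig) -> dict:
    """Control vs destabiliser microtubule dynamics comparison."""
    ctrl = gen_kymo_events(2.0, 0.3, 0.01, 300, seed=config.seed + 8001)
    drug = gen_kymo_events(1.2, 0.9, 0.01, 300, seed=config.seed + 8002)
    out = {}
    for name, ev in (("control", ctrl), ("drug", drug)):
        ev = mt.filter_events(ev)
        gr_groups, gr_mean, gr_sd = mt.growth_rate(ev)
        fc_groups, fc_mean = mt.catastrophe_frequency(ev, mode="in_vitro")
        out[name] = {"growth_rate_um_min": gr_mean, "growth_rate_sd": gr_sd,
                     "catastrophe_per_s": fc_mean,
                     "rescue_per_s": mt.rescue_frequency(ev),
                     "_fc_groups": fc_groups}
    out["p_catastrophe"] = mt.compare_conditions(
        out["control"].pop("_fc_groups"), out["drug"].pop("_fc_groups"))
    return out


def _cytometry_stage(config: RunConfig) -> pd.DataFrame:
    """Dose series of high-content well summaries for the dual drug."""
    spec = STUDY_DRUGS["bkm120_like"]
    doses = [0.0, 0.1e-6, 0.3e-6, 1e-6, 3e-6, 10e-6]
    wells = [gen_nuclei(spec, d, seed=config.seed + 9000 + i,
                        well_id=f"W{i:02d}")
             for i, d in enumerate(doses)]
    thr_mean, thr_max = cy.phh3_threshold_from_vehicle(
        wells[0], config.phh3_threshold_percentile)
    n_vehicle = len(wells[0])
    rows = []
    for d, w in zip(doses, wells):
        s = cy.summarize_well(w, w["well_id"].iloc[0], thr_mean, thr_max,
                              condensed_threshold=0.0,
                              n_vehicle=n_vehicle,
                              gates=cy.CycleGates(**config.cycle_gates))
        rows.append({"dose_m": d, "n_nuclei": s.n_nuclei,
                     "pct_phh3": s.pct_phh3_positive,
                     "pct_condensed": s.pct_condensed,
                     **{k: v for k, v in s.cycle_fractions.items()},
                     "proliferation_pct": s.proliferation_pct_of_vehicle})
    return pd.DataFrame(rows)
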