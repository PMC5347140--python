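"""Seeded generators emulating the study's raw inputs.

Every generator is a pure function of (parameters, seed): the same seed and
spec give bitwise-identical tables.  The generators encode the statistical
structure the analysis stages assume:

* **Panels** of cell lines treated with drugs of three mechanism kinds —
  pure cytostatic PI3K inhibition (viability Hill slope ~ -1), pure
  cytotoxic microtubule destabilisation (slope steeper than -2), and dual
  activity composed by response independence (Bliss-type product of the two
  surviving fractions; a configurable alternative takes the minimum).
* **Target-engagement geometry**: the cellular pPKB (PI3K) readout is ~9x
  more potent than the cytostatic viability effect, so ~90% pathway
  inhibition coincides with half-maximal growth inhibition; the mitotic
  pHH3 readout sits ~1.75x above the cytotoxic viability EC50 with a steep
  (+2) slope, so growth is halved at ~25% of the maximal mitotic response.
  These offsets reproduce the regimes a dual drug cannot escape: its two
  engagement curves straddle its own proliferation IC50, closing the window
  of selective PI3K inhibition.
* **Per-nucleus tables** with bimodal pHH3 and 2N/4N DNA-content mixtures,
  dose-shifted toward G2/M + sub-G1 (cytotoxic) or G1 (cytostatic).
* **Kymograph events** with exponential growth durations (rate = the
  catastrophe frequency) and shortening phases ending in rescue in
  competition with shrinking back to the seed.
* **Competitive tracer displacement** under the single-site competition
  model bound = L / (L + Kd_L * (1 + I/Kd_I)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingAssay
from .dose_response import DoseResponseSet

__all__ = [
    "MechanismSpec",
    "ScenarioSeed",
    "PQR309_LIKE",
    "MTD147_LIKE",
    "BKM120_LIKE",
    "DEFAULT_CONCS_M",
    "gen_panel",
    "gen_study",
    "gen_nuclei",
    "gen_kymo_events",
    "gen_binding",
]

#: 9-point 3.16-fold (half-log) dilution series, 3.16e-9 .. 3.16e-5 M.
DEFAULT_CONCS_M = 10.0 ** -np.arange(4.5, 9.0, 0.5)[::-1]

# fixed engagement-geometry constants (see module docstring / methods note)
PPKB_POTENCY_OFFSET = 9.0     # pPKB EC50 = pi3k viability EC50 / 9
PHH3_EC50_FACTOR = 1.75       # pHH3 EC50 = 1.75 x mda viability EC50
PHH3_HILL = 2.0               # steepness of the mitotic-arrest response
PHH3_BASELINE_PCT = 2.0       # vehicle-level pHH3-positive fraction
PHH3_MAX_PCT = 40.0           # per-drug maximal pHH3-positive fraction


@dataclass(frozen=True)
class MechanismSpec:
    """Mechanism of one drug in the simulated study.

    ``pi3k_ec50`` / ``mda_ec50`` are the molar EC50s of the corresponding
    *viability* components; the pPKB and pHH3 target-readout curves are
    placed relative to them by the fixed engagement-geometry offsets above.
    Hills are signed as fitted on declining viability curves.
    """

    kind: str  # "pi3k_cytostatic" | "mda_cytotoxic" | "dual"
    pi3k_ec50: float = 1.0e-6
    pi3k_hill: float = -1.0
    mda_ec50: float = 1.0e-6
    mda_hill: float = -3.0
    line_ic50_dispersion: float = 0.25  # log10 s.d. of per-line sensitivity
    noise_sd: float = 5.0               # percent, viability / pPKB readouts
    composition: str = "product"        # "product" (Bliss) | "minimum"

    def __post_init__(self) -> None:
        if self.kind not in ("pi3k_cytostatic", "mda_cytotoxic", "dual"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.mda_hill > -2.0 and self.kind != "pi3k_cytostatic":
            raise ValueError("cytotoxic viability hill must be <= -2")
        if self.line_ic50_dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise must be non-negative")

    @property
    def has_pi3k(self) -> bool:
        return self.kind in ("pi3k_cytostatic", "dual")

    @property
    def has_mda(self) -> bool:
        return self.kind in ("mda_cytotoxic", "dual")


@dataclass(frozen=True)
class ScenarioSeed:
    seed: int
    n_lines: int = 44
    n_concs: int = 9
    n_replicates: int = 2


# reference scenarios: a pure PI3K inhibitor, a pure microtubule
# destabiliser, and the dual-activity parent compound whose two arms are
# both in the ~1 uM range with the destabilising arm slightly the stronger.
PQR309_LIKE = MechanismSpec(kind="pi3k_cytostatic", pi3k_ec50=1.0e-6)
MTD147_LIKE = MechanismSpec(kind="mda_cytotoxic", mda_ec50=1.0e-6)
BKM120_LIKE = MechanismSpec(kind="dual", pi3k_ec50=1.2e-6, mda_ec50=0.8e-6)


def _survival(x: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    """Surviving fraction of one viability component (1 at x=0, 0 at inf)."""
    return 1.0 / (1.0 + (x / ec50) ** abs(hill))


def _viability_fraction(spec: MechanismSpec, x: np.ndarray,
                        pi3k_f: float, mda_f: float) -> np.ndarray:
    parts = []
    if spec.has_pi3k:
        parts.append(_survival(x, spec.pi3k_ec50 * pi3k_f, spec.pi3k_hill))
    if spec.has_mda:
        parts.append(_survival(x, spec.mda_ec50 * mda_f, spec.mda_hill))
    if spec.composition == "product":
        out = parts[0]
        for p in parts[1:]:
            out = out * p
        return out
    if spec.composition == "minimum":
        return np.minimum.reduce(parts)
    raise ValueError(f"unknown composition {spec.composition!r}")


def _ppkb_percent(spec: MechanismSpec, x: np.ndarray, pi3k_f: float) -> np.ndarray:
    """Percent remaining pPKB signal (100 -> 0 for PI3K-active drugs)."""
    if not spec.has_pi3k:
        return np.full_like(x, 100.0)
    ec50 = spec.pi3k_ec50 * pi3k_f / PPKB_POTENCY_OFFSET
    return 100.0 * _survival(x, ec50, 1.0)


def _phh3_percent(spec: MechanismSpec, x: np.ndarray, mda_f: float) -> np.ndarray:
    """Percent pHH3-positive cells (rises under MDA, dips under PI3Ki)."""
    if spec.has_mda:
        ec50 = spec.mda_ec50 * mda_f * PHH3_EC50_FACTOR
        u = (x / ec50) ** PHH3_HILL
        return PHH3_BASELINE_PCT + (PHH3_MAX_PCT - PHH3_BASELINE_PCT) * u / (1 + u)
    # pure PI3K inhibition mildly depletes the mitotic population
    frac = _survival(x, spec.pi3k_ec50, 1.0)
    return PHH3_BASELINE_PCT * (0.25 + 0.75 * frac)


def gen_panel(
    spec: MechanismSpec,
    scenario: ScenarioSeed,
    concs_m: np.ndarray | None = None,
    drug: str = "drug",
    line_factors: dict[str, tuple[float, float]] | None = None,
) -> dict[str, dict[str, DoseResponseSet]]:
    """Simulate one drug across a panel of cell lines.

    Per line, component EC50s are drawn lognormally around the spec values
    (or taken from ``line_factors`` when several drugs must share the same
    per-line sensitivities); viability, pPKB and pHH3 dilution series are
    generated with Gaussian noise.  Returns
    ``{cell_line: {readout: DoseResponseSet}}``.
    """
    rng = np.random.default_rng(scenario.seed)
    x = np.asarray(concs_m if concs_m is not None else DEFAULT_CONCS_M[: scenario.n_concs])
    xr = np.tile(x, scenario.n_replicates)
    rep = np.repeat(np.arange(scenario.n_replicates), x.size)
    out: dict[str, dict[str, DoseResponseSet]] = {}
    for i in range(scenario.n_lines):
        line = f"line_{i + 1:02d}"
        if line_factors is not None:
            pi3k_f, mda_f = line_factors[line]
        else:
            pi3k_f = 10.0 ** rng.normal(0.0, spec.line_ic50_dispersion)
            mda_f = 10.0 ** rng.normal(0.0, spec.line_ic50_dispersion)
        viab = 100.0 * _viability_fraction(spec, xr, pi3k_f, mda_f)
        ppkb = _ppkb_percent(spec, xr, pi3k_f)
        phh3 = _phh3_percent(spec, xr, mda_f)
        viab = viab + rng.normal(0.0, spec.noise_sd, xr.size)
        ppkb = ppkb + rng.normal(0.0, spec.noise_sd, xr.size)
        phh3 = phh3 + rng.normal(0.0, max(spec.noise_sd * 0.2, 1e-12), xr.size)
        out[line] = {
            rdt: DoseResponseSet(drug=drug, cell_line=line, readout=rdt,
                                 conc_m=xr, response=resp, replicate=rep)
            for rdt, resp in (("viability", viab), ("pPKB", ppkb), ("pHH3", phh3))
        }
    return out


def gen_study(
    drug_specs: dict[str, MechanismSpec],
    scenario: ScenarioSeed,
    concs_m: np.ndarray | None = None,
) -> dict[str, dict[str, dict[str, DoseResponseSet]]]:
    """Simulate several drugs over one shared panel of cell lines.

    Per-line PI3K and MDA sensitivity factors are drawn once and shared by
    all drugs, so drugs of like mechanism show correlated sensitivity
    profiles across the panel (the structure the relative-sensitivity and
    penalty-score analyses exploit).  Returns ``{drug: gen_panel output}``.
    """
    rng = np.random.default_rng(scenario.seed)
    disp = max(s.line_ic50_dispersion for s in drug_specs.values())
    factors = {
        f"line_{i + 1:02d}": (10.0 ** rng.normal(0.0, disp),
                              10.0 ** rng.normal(0.0, disp))
        for i in range(scenario.n_lines)
    }
    out = {}
    for j, (drug, spec) in enumerate(drug_specs.items()):
        sub = ScenarioSeed(seed=scenario.seed + 1000 * (j + 1),
                           n_lines=scenario.n_lines, n_concs=scenario.n_concs,
                           n_replicates=scenario.n_replicates)
        out[drug] = gen_panel(spec, sub, concs_m=concs_m, drug=drug,
                              line_factors=factors)
    return out


# ---------------------------------------------------------------------------
# per-nucleus tables
# ---------------------------------------------------------------------------

_BASE_CYCLE = np.array([0.02, 0.55, 0.15, 0.28])          # subG1, G1, S, G2M
_MDA_CYCLE = np.array([0.25, 0.10, 0.05, 0.60])           # arrested/apoptotic
_PI3KI_CYCLE = np.array([0.02, 0.80, 0.05, 0.13])         # G1/S arrest


def gen_nuclei(
    spec: MechanismSpec,
    dose_m: float,
    seed: int,
    n_nuclei: int = 2000,
    well_id: str = "W01",
    g1_intensity: float = 1.0e5,
    phh3_positive_fraction: float | None = None,
    border_fraction: float = 0.08,
) -> pd.DataFrame:
    """Simulate one well's segmented-nuclei table.

    DNA content is a lognormal mixture with the G2/M peak at twice the G1
    peak; the cell-cycle composition shifts with dose toward G2/M + sub-G1
    under a destabilising mechanism or toward G1 under PI3K inhibition.
    pHH3 intensities are bimodal; the positive fraction follows the
    mechanism's mitotic-arrest curve unless fixed explicitly via
    ``phh3_positive_fraction``.
    """
    rng = np.random.default_rng(seed)
    if spec.has_mda:
        u = (dose_m / (spec.mda_ec50 * PHH3_EC50_FACTOR)) ** PHH3_HILL
        w = u / (1 + u)
        mix = (1 - w) * _BASE_CYCLE + w * _MDA_CYCLE
        pos_frac = (PHH3_BASELINE_PCT + (PHH3_MAX_PCT - PHH3_BASELINE_PCT)
                    * u / (1 + u)) / 100.0
    else:
        w = 1.0 - _survival(np.array([dose_m]), spec.pi3k_ec50, 1.0)[0]
        mix = (1 - w) * _BASE_CYCLE + w * _PI3KI_CYCLE
        pos_frac = PHH3_BASELINE_PCT * (1.0 - 0.75 * w) / 100.0
    if phh3_positive_fraction is not None:
        pos_frac = float(phh3_positive_fraction)
    mix = mix / mix.sum()

    phase = rng.choice(4, size=n_nuclei, p=mix)  # 0 subG1, 1 G1, 2 S, 3 G2M
    dna = np.empty(n_nuclei)
    g1 = rng.lognormal(np.log(g1_intensity), 0.08, n_nuclei)
    dna[phase == 1] = g1[phase == 1]
    dna[phase == 3] = 2.0 * g1[phase == 3]
    n_s = int(np.sum(phase == 2))
    dna[phase == 2] = g1[phase == 2] * rng.uniform(1.35, 1.65, n_s)
    n_sub = int(np.sum(phase == 0))
    dna[phase == 0] = g1[phase == 0] * rng.uniform(0.2, 0.55, n_sub)

    positive = rng.random(n_nuclei) < pos_frac
    phh3_mean = np.where(
        positive,
        rng.lognormal(np.log(500.0), 0.3, n_nuclei),
        rng.lognormal(np.log(50.0), 0.3, n_nuclei),
    )
    phh3_max = phh3_mean * rng.uniform(1.5, 3.0, n_nuclei)

    condensed = positive | (phase == 0)  # mitotic or apoptotic chromatin
    area = np.where(condensed, rng.normal(25.0, 3.0, n_nuclei),
                    rng.normal(150.0, 15.0, n_nuclei))
    intensity_density = dna / np.clip(area, 1.0, None)

    return pd.DataFrame({
        "well_id": well_id,
        "dna_int": dna,
        "phh3_mean": phh3_mean,
        "phh3_max": phh3_max,
        "border": rng.random(n_nuclei) < border_fraction,
        "intensity_density": intensity_density,
        "area": area,
        "true_phh3_positive": positive,
    })


# ---------------------------------------------------------------------------
# kymograph events
# ---------------------------------------------------------------------------

def gen_kymo_events(
    v_g_um_min: float,
    f_cat_per_min: float,
    f_res_per_s: float,
    n_growth: int,
    seed: int,
    n_movies: int = 5,
    length_noise_sd: float = 0.05,
    shrink_speed_um_min: float = 30.0,
) -> pd.DataFrame:
    """Simulate a kymograph event table.

    Growth durations are exponential with rate ``f_cat_per_min`` (each
    growth ends in a catastrophe); lengths are velocity x duration with
    multiplicative noise.  Each catastrophe starts a shortening phase that
    ends in a rescue (exponential waiting time, rate ``f_res_per_s``) unless
    the microtubule shrinks back to the seed first (fate "unresolved" for
    the rescue count, but a complete, timed event).
    """
    rng = np.random.default_rng(seed)
    movie = np.array([f"movie_{(i % n_movies) + 1}" for i in range(n_growth)])
    g_dur_s = rng.exponential(60.0 / f_cat_per_min, n_growth)
    g_len = (v_g_um_min / 60.0) * g_dur_s * (1.0 + rng.normal(0, length_noise_sd, n_growth))
    g_len = np.clip(g_len, 0.0, None)
    growth = pd.DataFrame({
        "id": movie, "phase": "growth", "length_um": g_len,
        "duration_s": g_dur_s, "end_fate": "catastrophe", "complete": True,
    })

    t_rescue = rng.exponential(1.0 / f_res_per_s, n_growth)
    t_seed = g_len / (shrink_speed_um_min / 60.0)
    rescued = t_rescue < t_seed
    s_dur = np.where(rescued, t_rescue, t_seed)
    shortening = pd.DataFrame({
        "id": movie, "phase": "shortening",
        "length_um": (shrink_speed_um_min / 60.0) * s_dur,
        "duration_s": s_dur,
        "end_fate": np.where(rescued, "rescue", "unresolved"),
        "complete": True,
    })
    events = pd.concat([growth, shortening], ignore_index=True)
    return events[events["duration_s"] > 0].reset_index(drop=True)


def gen_turbidity(
    ic50_m: float,
    concs_m: np.ndarray,
    seed: int,
    vehicle_delta_od: float = 0.30,
    tau_min: float = 10.0,
    t_max_min: float = 60.0,
    dt_min: float = 1.0,
    noise_od: float = 0.003,
    drug: str = "drug",
) -> pd.DataFrame:
    """Simulate tubulin-polymerisation turbidity (OD340) time series.

    Vehicle wells polymerise to a saturating delta OD340; a destabiliser
    suppresses the plateau with a hill-1 inhibition curve around
    ``ic50_m``.  Returns the tidy turbidity table (well, condition, conc_M,
    time_min, od340) including DMSO vehicle wells.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_min + dt_min, dt_min)
    rows = []

    def curve(dmax: float, well: str, condition: str, conc: float) -> None:
        base = rng.uniform(0.05, 0.15)
        od = base + dmax * (1.0 - np.exp(-t / tau_min)) + rng.normal(0, noise_od, t.size)
        od[0] = base
        for ti, oi in zip(t, od):
            rows.append({"well": well, "condition": condition, "conc_M": conc,
                         "time_min": ti, "od340": oi})

    for i in range(2):
        curve(vehicle_delta_od, f"V{i+1}", "DMSO", np.nan)
    for j, c in enumerate(np.asarray(concs_m, dtype=float)):
        dmax = vehicle_delta_od / (1.0 + c / ic50_m)
        curve(dmax, f"S{j+1}", drug, c)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# competitive tracer displacement
# ---------------------------------------------------------------------------

def bound_tracer_fraction(
    inhibitor_m: np.ndarray, kd_i_m: float, kd_tracer_m: float, tracer_m: float
) -> np.ndarray:
    """Single-site competition: bound = L / (L + Kd_L * (1 + I/Kd_I))."""
    inhibitor_m = np.asarray(inhibitor_m, dtype=float)
    return tracer_m / (tracer_m + kd_tracer_m * (1.0 + inhibitor_m / kd_i_m))


def gen_binding(
    kd_i_m: float,
    kd_tracer_m: float,
    tracer_m: float,
    concs_m: np.ndarray,
    noise: float,
    seed: int,
    isoform: str = "p110alpha",
    n_vehicle: int = 4,
    background_665: float = 1000.0,
    background_620: float = 800.0,
    donor_signal: float = 3000.0,
    ratio_scale: float = 4.0,
) -> tuple[BindingAssay, np.ndarray]:
    """Simulate a displacement plate under the competitive-binding model.

    The 665/620 emission ratio is proportional to tracer occupancy; raw
    665/620 signals (with backgrounds) are synthesised so the full analysis
    path (background subtraction -> ratio -> % of vehicle -> fit ->
    competition correction) can be exercised.  Returns the assay plus the
    vehicle (I=0) emission ratios.
    """
    rng = np.random.default_rng(seed)
    concs_m = np.asarray(concs_m, dtype=float)
    bf = bound_tracer_fraction(concs_m, kd_i_m, kd_tracer_m, tracer_m)
    bf0 = bound_tracer_fraction(np.zeros(n_vehicle), kd_i_m, kd_tracer_m, tracer_m)
    ratio = ratio_scale * bf * (1.0 + rng.normal(0, noise, bf.size))
    ratio0 = ratio_scale * bf0 * (1.0 + rng.normal(0, noise, n_vehicle))
    s620 = np.full(bf.size, donor_signal)
    s665 = background_665 + (s620 - background_620) * ratio
    assay = BindingAssay(
        isoform=isoform, compound_concs_m=concs_m,
        signals_665=s665, signals_620=s620,
        background_665=background_665, background_620=background_620,
        kd_tracer_nm=kd_tracer_m * 1e9, tracer_conc_nm=tracer_m * 1e9,
    )
    return assay, ratio0
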