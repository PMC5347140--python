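"""Per-nucleus classification, DNA-content gating and proliferation."""

import numpy as np
import pandas as pd
import pytest

from moadecon.cytometry import (cell_cycle_fractions, classify_phh3,
                                condensed_fraction, proliferation_from_counts,
                                summarize_well)
from moadecon.dose_response import DoseResponseSet, fit_sigmoid
from moadecon.simulate import (BKM120_LIKE, MTD147_LIKE, PQR309_LIKE,
                               gen_nuclei)


def nuclei_frame(rows):
    return pd.DataFrame(rows, columns=["well_id", "dna_int", "phh3_mean",
                                       "phh3_max", "border"])


class TestClassifyPhh3:
    def test_two_step_rule(self):
        n = nuclei_frame([
            ("w", 1e5, 200.0, 900.0, False),  # above both -> positive
            ("w", 1e5, 200.0, 100.0, False),  # above mean, below max -> negative
            ("w", 1e5, 50.0, 900.0, False),   # below mean -> negative
        ])
        assert classify_phh3(n, 150.0, 400.0) == pytest.approx(100 / 3)

    def test_border_nuclei_never_enter_denominator(self):
        n = nuclei_frame([("w", 1e5, 200.0, 900.0, False),
                          ("w", 1e5, 200.0, 900.0, True),
                          ("w", 1e5, 10.0, 10.0, False)])
        assert classify_phh3(n, 150.0, 400.0) == pytest.approx(50.0)

    def test_no_nonborder_nuclei_undefined(self):
        n = nuclei_frame([("w", 1e5, 200.0, 900.0, True)])
        assert np.isnan(classify_phh3(n, 150.0, 400.0))

    def test_raising_thresholds_never_increases_fraction(self):
        w = gen_nuclei(MTD147_LIKE, 1e-6, seed=3, n_nuclei=1500)
        fracs = [classify_phh3(w, m, 400.0) for m in (50.0, 150.0, 400.0, 800.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_known_positive_fraction_recovered(self):
        w = gen_nuclei(BKM120_LIKE, 0.0, seed=8, n_nuclei=5000,
                       phh3_positive_fraction=0.10)
        est = classify_phh3(w, 150.0, 400.0)
        # binomial 95% interval around 10% at n ~ 4600 non-border nuclei
        assert est == pytest.approx(10.0, abs=1.0)


class TestCondensedFraction:
    def test_degenerate_thresholds(self):
        w = gen_nuclei(BKM120_LIKE, 0.0, seed=1, n_nuclei=500)
        assert condensed_fraction(w, 1e12) == 0.0
        assert condensed_fraction(w, -1e12) == 100.0

    def test_known_mixture_recovered(self):
        w = gen_nuclei(BKM120_LIKE, 0.0, seed=21, n_nuclei=4000,
                       phh3_positive_fraction=0.25)
        truth = 100.0 * np.mean(w["true_phh3_positive"] | (w["area"] < 80))
        assert condensed_fraction(w, 0.0) == pytest.approx(truth, abs=1.0)

    def test_missing_features_rejected(self):
        n = nuclei_frame([("w", 1e5, 1.0, 1.0, False)])
        with pytest.raises(ValueError, match="features"):
            condensed_fraction(n, 0.0)


class TestCellCycleFractions:
    def test_pure_g1_population(self):
        rng = np.random.default_rng(2)
        fr = cell_cycle_fractions(rng.lognormal(np.log(1e5), 0.08, 2000))
        assert fr["G1"] == pytest.approx(100.0, abs=1.0)

    def test_known_mixture_within_three_points(self):
        rng = np.random.default_rng(1)
        n = 4000
        phase = rng.choice(3, n, p=[0.6, 0.1, 0.3])
        g1 = rng.lognormal(np.log(1e5), 0.08, n)
        dna = np.where(phase == 0, g1,
                       np.where(phase == 1, g1 * rng.uniform(1.35, 1.65, n),
                                2 * g1))
        fr = cell_cycle_fractions(dna)
        assert fr["G1"] == pytest.approx(60.0, abs=3.0)
        assert fr["S"] == pytest.approx(10.0, abs=3.0)
        assert fr["G2M"] == pytest.approx(30.0, abs=3.0)

    def test_fractions_sum_to_100(self):
        w = gen_nuclei(MTD147_LIKE, 1e-6, seed=4, n_nuclei=2000)
        fr = cell_cycle_fractions(w["dna_int"])
        assert fr["subG1"] + fr["G1"] + fr["S"] + fr["G2M"] == pytest.approx(
            100.0, abs=1e-6)

    def test_invariant_to_global_linear_rescaling(self):
        w = gen_nuclei(BKM120_LIKE, 0.0, seed=6, n_nuclei=2000)
        a = cell_cycle_fractions(w["dna_int"])
        b = cell_cycle_fractions(w["dna_int"] * 37.5)
        for k in ("subG1", "G1", "S", "G2M"):
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_too_few_nuclei_rejected(self):
        with pytest.raises(ValueError):
            cell_cycle_fractions(np.ones(5))


class TestMechanismShifts:
    """Dose-dependent cell-cycle signatures of the two mechanisms."""

    def test_destabiliser_accumulates_g2m_and_subg1(self):
        doses = [0.0, 3e-7, 1e-6, 3e-6, 1e-5]
        vals = []
        for i, d in enumerate(doses):
            fr = cell_cycle_fractions(
                gen_nuclei(MTD147_LIKE, d, seed=30 + i, n_nuclei=2500)["dna_int"])
            vals.append(fr["G2M"] + fr["subG1"])
        assert vals[-1] > vals[0] + 30
        assert all(b >= a - 5 for a, b in zip(vals, vals[1:]))

    def test_pi3k_inhibitor_accumulates_g1(self):
        doses = [0.0, 3e-7, 1e-6, 3e-6, 1e-5]
        vals = []
        for i, d in enumerate(doses):
            fr = cell_cycle_fractions(
                gen_nuclei(PQR309_LIKE, d, seed=40 + i, n_nuclei=2500)["dna_int"])
            vals.append(fr["G1"])
        assert vals[-1] > vals[0] + 15
        assert all(b >= a - 5 for a, b in zip(vals, vals[1:]))


class TestProliferation:
    def test_arithmetic(self):
        assert proliferation_from_counts(100, 100) == pytest.approx(100.0)
        assert proliferation_from_counts(50, 100) == pytest.approx(50.0)

    def test_zero_vehicle_rejected(self):
        with pytest.raises(ValueError):
            proliferation_from_counts(10, 0)

    def test_dose_series_feeds_ic50_fit(self):
        # nuclei counts following a hill-1 loss around 1 uM recover the IC50
        x = 10.0 ** -np.arange(4.5, 9.0, 0.5)[::-1]
        n_vehicle = 4000
        counts = np.round(n_vehicle / (1.0 + x / 1e-6)).astype(int)
        pct = np.array([proliferation_from_counts(c, n_vehicle) for c in counts])
        fit = fit_sigmoid(DoseResponseSet("d", "l", "cell_count", x, pct),
                          "normalized3p")
        assert fit.ic50 == pytest.approx(1e-6, rel=0.02)


class TestSummarizeWell:
    def test_bundle_is_consistent(self):
        w = gen_nuclei(BKM120_LIKE, 1e-6, seed=12, n_nuclei=1500, well_id="W5")
        s = summarize_well(w, "W5", 150.0, 400.0, condensed_threshold=0.0,
                           n_vehicle=2000)
        assert s.n_nuclei == 1500
        assert 0.0 <= s.pct_phh3_positive <= 100.0
        assert s.proliferation_pct_of_vehicle == pytest.approx(75.0)
        total = sum(s.cycle_fractions[k] for k in ("subG1", "G1", "S", "G2M"))
        assert total == pytest.approx(100.0, abs=1e-6)
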