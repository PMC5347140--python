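"""Hill-slope matrix, exclusion rule, penalty scores and panel profiles."""

import numpy as np
import pandas as pd
import pytest

from moadecon.dose_response import fit_sigmoid
from moadecon.panel import (hill_slope_table, penalty_score,
                            penalty_score_matrix, phh3_fold_change,
                            sensitivity_profile)
from moadecon.simulate import MechanismSpec, ScenarioSeed, gen_panel


def fits_frame(n_lines, drugs, ambiguous_map=None):
    """Tidy viability fits frame with optional per-(line, drug) ambiguity."""
    ambiguous_map = ambiguous_map or {}
    rows = []
    for i in range(n_lines):
        line = f"line_{i + 1:02d}"
        for j, drug in enumerate(drugs):
            rows.append({"cell_line": line, "drug": drug, "readout": "viability",
                         "hill_slope": -1.0 - 0.1 * j, "ic50_m": 1e-6,
                         "ambiguous": ambiguous_map.get((line, drug), False)})
    return pd.DataFrame(rows)


class TestHillSlopeTable:
    def test_panel_exclusion_rule_44_to_36(self):
        """8 of 44 lines carry >= 1 ambiguous fit -> 36 retained lines."""
        amb = {(f"line_{i:02d}", "drug_b"): True for i in range(1, 9)}
        mat = hill_slope_table(fits_frame(44, ["drug_a", "drug_b"], amb))
        assert mat.shape[0] == 36
        assert len(mat.attrs["excluded_lines"]) == 8

    def test_no_ambiguity_keeps_all_lines(self):
        mat = hill_slope_table(fits_frame(10, ["a", "b"]))
        assert mat.shape == (10, 2)
        assert mat.attrs["excluded_lines"] == []

    def test_single_ambiguous_fit_excludes_line_for_all_drugs(self):
        amb = {("line_03", "b"): True}
        mat = hill_slope_table(fits_frame(5, ["a", "b", "c"], amb))
        assert "line_03" not in mat.index
        assert mat.shape == (4, 3)

    def test_all_excluded_is_an_error(self):
        amb = {(f"line_{i:02d}", "a"): True for i in range(1, 4)}
        with pytest.raises(ValueError, match="retained"):
            hill_slope_table(fits_frame(3, ["a"], amb))


class TestPenaltyScore:
    def test_identical_slopes_zero(self):
        s = pd.Series([-1.0, -2.0, -3.0], index=list("abc"))
        assert penalty_score(s, s).total == 0.0

    def test_unit_offset_on_36_lines(self):
        idx = [f"l{i}" for i in range(36)]
        a = pd.Series(-1.0, index=idx)
        assert penalty_score(a, a - 1.0).total == pytest.approx(36.0)

    def test_symmetry_and_identical_line_invariance(self):
        rng = np.random.default_rng(0)
        idx = [f"l{i}" for i in range(12)]
        a = pd.Series(rng.normal(-1, 0.3, 12), index=idx)
        b = pd.Series(rng.normal(-3, 0.5, 12), index=idx)
        assert penalty_score(a, b).total == pytest.approx(penalty_score(b, a).total)
        a2 = pd.concat([a, pd.Series({"extra": -2.0})])
        b2 = pd.concat([b, pd.Series({"extra": -2.0})])
        assert penalty_score(a2, b2).total == pytest.approx(penalty_score(a, b).total)

    def test_misaligned_lines_rejected(self):
        a = pd.Series([-1.0], index=["x"])
        b = pd.Series([-1.0], index=["y"])
        with pytest.raises(ValueError, match="aligned"):
            penalty_score(a, b)

    def test_mechanism_discrimination_monte_carlo(self):
        """Destabiliser-vs-PI3Ki slope pairs exceed 100 in >=95% of panels.

        36-line panels, destabiliser slopes ~ Normal(-3.0, 0.4), PI3K
        inhibitor slopes ~ Normal(-1.0, 0.2); the expected total is
        36 * (4 + 0.16 + 0.04) = 151.2.
        """
        rng = np.random.default_rng(123)
        idx = [f"l{i}" for i in range(36)]
        totals = []
        for _ in range(1000):
            mda = pd.Series(rng.normal(-3.0, 0.4, 36), index=idx)
            pi3ki = pd.Series(rng.normal(-1.0, 0.2, 36), index=idx)
            totals.append(penalty_score(mda, pi3ki).total)
        totals = np.array(totals)
        assert np.mean(totals > 100) >= 0.95
        assert np.median(totals) == pytest.approx(36 * 4.2, rel=0.1)

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        mat = hill_slope_table(fits_frame(6, ["a", "b", "c"]))
        pen = penalty_score_matrix(mat)
        assert np.allclose(pen.values, pen.values.T)
        assert np.allclose(np.diag(pen.values), 0.0)


class TestSensitivityProfile:
    def test_uniform_panel_is_all_ones(self):
        ic50 = pd.DataFrame({"a": [2e-6] * 5}, index=[f"l{i}" for i in range(5)])
        rel = sensitivity_profile(ic50, "a")
        assert np.allclose(rel["a"], 1.0)

    def test_relative_value_from_analytic_mean(self):
        # nine lines at 1 uM, one at 2 uM: mean 1.1 uM, outlier entry 20/11
        vals = [1e-6] * 9 + [2e-6]
        ic50 = pd.DataFrame({"a": vals}, index=[f"l{i}" for i in range(10)])
        rel = sensitivity_profile(ic50, "a")
        assert rel["a"].max() == pytest.approx(2.0 / 1.1)
        # most sensitive line first
        assert rel["a"].iloc[0] == rel["a"].min()

    def test_missing_ic50_excluded_from_mean(self):
        ic50 = pd.DataFrame({"a": [1e-6, np.nan, 3e-6]}, index=list("xyz"))
        rel = sensitivity_profile(ic50, "a")
        assert rel["a"].dropna().tolist() == pytest.approx([0.5, 1.5])


class TestPhh3FoldChange:
    def test_arithmetic(self):
        assert phh3_fold_change(2.0, 2.0) == pytest.approx(1.0)
        assert phh3_fold_change(6.0, 2.0) == pytest.approx(3.0)

    def test_zero_vehicle_is_undefined(self):
        assert np.isnan(phh3_fold_change(3.0, 0.0))

    def test_panel_decrease_count_matches_enumeration(self):
        rng = np.random.default_rng(5)
        treated = rng.uniform(0.5, 6.0, 40)
        vehicle = rng.uniform(1.0, 3.0, 40)
        folds = phh3_fold_change(treated, vehicle)
        n_dec = int(np.sum(folds < 1.0))
        brute = sum(1 for t, v in zip(treated, vehicle) if t / v < 1.0)
        assert n_dec == brute


class TestSlopeRecoveryThroughPipeline:
    """Fitting synthetic panels recovers the mechanism's slope regime."""

    @pytest.mark.parametrize("kind, lo, hi", [
        ("pi3k_cytostatic", -1.3, -0.7),
        ("mda_cytotoxic", -np.inf, -2.0),
    ])
    def test_mean_hill_by_mechanism(self, kind, lo, hi):
        spec = MechanismSpec(kind=kind)
        panel = gen_panel(spec, ScenarioSeed(seed=42, n_lines=6))
        slopes = [fit_sigmoid(r["viability"], "full4p").hill_slope
                  for r in panel.values()]
        mean = np.mean([s for s in slopes if np.isfinite(s)])
        assert lo <= mean <= hi
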