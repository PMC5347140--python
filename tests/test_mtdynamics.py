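"""Event filtering, dynamic-instability estimators and turbidity analysis."""

import numpy as np
import pandas as pd
import pytest

from moadecon.mtdynamics import (catastrophe_frequency, compare_conditions,
                                 filter_events, growth_rate, rescue_frequency,
                                 turbidity_analysis)
from moadecon.simulate import gen_kymo_events, gen_turbidity


def events_frame(rows):
    return pd.DataFrame(rows, columns=["id", "phase", "length_um",
                                       "duration_s", "end_fate", "complete"])


class TestFilterEvents:
    def test_length_and_completeness_rules(self):
        ev = events_frame([
            ("m1", "growth", 0.4, 10.0, "catastrophe", True),   # too short
            ("m1", "growth", 0.5, 10.0, "catastrophe", True),   # boundary kept
            ("m1", "growth", 2.0, 10.0, "catastrophe", False),  # incomplete
            ("m1", "shortening", 0.3, 5.0, "rescue", True),     # length rule is growth-only
        ])
        out = filter_events(ev)
        assert len(out) == 2
        assert set(out["length_um"]) == {0.5, 0.3}

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            filter_events(events_frame([("m1", "growth", 1.0, 0.0, "catastrophe", True)]))


class TestGrowthRate:
    def test_unit_conversion(self):
        ev = events_frame([("m1", "growth", 2.0, 60.0, "catastrophe", True)])
        _, mean, _ = growth_rate(ev)
        assert mean == pytest.approx(2.0)  # um/min

    def test_identical_events_zero_sd(self):
        ev = events_frame([("m1", "growth", 1.0, 30.0, "catastrophe", True),
                           ("m2", "growth", 1.0, 30.0, "catastrophe", True)])
        _, mean, sd = growth_rate(ev)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(0.0)

    def test_seeded_recovery_of_generating_velocity(self):
        ev = gen_kymo_events(2.0, 0.5, 0.01, 400, seed=10, length_noise_sd=0.02)
        _, mean, sd = growth_rate(ev)
        assert mean == pytest.approx(2.0, rel=0.05)


class TestCatastropheFrequency:
    def test_single_event_inverse_time(self):
        ev = events_frame([("m1", "growth", 5.0, 100.0, "catastrophe", True)])
        _, f = catastrophe_frequency(ev, mode="in_vitro")
        assert f == pytest.approx(0.01)  # per s

    def test_cellular_events_over_total_time(self):
        rows = [("c1", "growth", 1.0, 30.0, "catastrophe", True)] * 10  # 5 min total
        _, f = catastrophe_frequency(events_frame(rows), mode="cellular")
        assert f == pytest.approx(2.0)  # per min

    def test_single_group_estimators_coincide(self):
        rng = np.random.default_rng(2)
        rows = [("c1", "growth", 1.0, d, "catastrophe", True)
                for d in rng.exponential(120.0, 50)]
        ev = events_frame(rows)
        _, f_vitro = catastrophe_frequency(ev, mode="in_vitro")
        _, f_cell = catastrophe_frequency(ev, mode="cellular")
        assert f_vitro * 60.0 == pytest.approx(f_cell, rel=1e-12)

    def test_unit_rescaling_factor_60(self):
        ev = events_frame([("m1", "growth", 5.0, 100.0, "catastrophe", True)])
        _, per_s = catastrophe_frequency(ev, mode="in_vitro")
        _, per_min = catastrophe_frequency(ev, mode="cellular")
        assert per_min == pytest.approx(60.0 * per_s)

    @pytest.mark.parametrize("n, tol", [(200, 0.10), (1000, 0.05)])
    def test_estimator_consistency(self, n, tol):
        """Both estimator conventions converge to the generating rate.

        The mean estimate over 20 seeded panels must fall within the stated
        fraction of the exponential rate (0.5 per min).
        """
        vitro, cell = [], []
        for s in range(20):
            ev = gen_kymo_events(5.0, 0.5, 0.01, n, seed=100 + s)
            vitro.append(catastrophe_frequency(ev, mode="in_vitro")[1] * 60.0)
            cell.append(catastrophe_frequency(ev, mode="cellular")[1])
        assert np.mean(vitro) == pytest.approx(0.5, rel=tol)
        assert np.mean(cell) == pytest.approx(0.5, rel=tol)

    def test_per_event_inverse_variant_overweights_short_events(self):
        rng = np.random.default_rng(8)
        rows = [("m1", "growth", 1.0, d, "catastrophe", True)
                for d in rng.exponential(120.0, 300)]
        ev = events_frame(rows)
        _, inv_mean = catastrophe_frequency(ev, mode="in_vitro")
        _, per_event = catastrophe_frequency(ev, mode="in_vitro",
                                             variant="per_event_inverse")
        assert per_event > inv_mean


class TestRescueFrequency:
    def test_counts_over_shortening_time(self):
        rows = [("m1", "shortening", 1.0, 100.0, "rescue", True)] * 3
        assert rescue_frequency(events_frame(rows)) == pytest.approx(0.01)
        rows = [("m1", "shortening", 1.0, 100.0, "rescue", True)] * 3 + \
               [("m1", "shortening", 1.0, 100.0, "unresolved", True)] * 3
        assert rescue_frequency(events_frame(rows)) == pytest.approx(0.005)

    def test_zero_rescues(self):
        rows = [("m1", "shortening", 1.0, 100.0, "unresolved", True)]
        assert rescue_frequency(events_frame(rows)) == 0.0

    def test_no_shortening_undefined(self):
        rows = [("m1", "growth", 1.0, 100.0, "catastrophe", True)]
        assert np.isnan(rescue_frequency(events_frame(rows)))

    def test_seeded_recovery_of_generating_rate(self):
        rates = [rescue_frequency(gen_kymo_events(5.0, 0.5, 0.01, 1000, seed=s))
                 for s in range(10)]
        assert np.mean(rates) == pytest.approx(0.01, rel=0.1)


class TestTurbidity:
    def test_vehicle_matched_condition_near_100(self):
        curves = gen_turbidity(1e-6, np.array([1e-12]), seed=4, noise_od=0.0)
        table, _ = turbidity_analysis(curves)
        drug = table[table["condition"] == "drug"]
        assert drug["pct_of_vehicle"].iloc[0] == pytest.approx(100.0, abs=0.5)

    def test_flat_trace_is_zero(self):
        t = np.arange(0.0, 61.0)
        rows = []
        for well, cond, conc, amp in (("V1", "DMSO", np.nan, 0.3),
                                      ("S1", "drug", 1e-6, 0.0)):
            for ti in t:
                rows.append({"well": well, "condition": cond, "conc_M": conc,
                             "time_min": ti,
                             "od340": 0.1 + amp * (1 - np.exp(-ti / 10.0))})
        table, _ = turbidity_analysis(pd.DataFrame(rows))
        assert table.loc[table["condition"] == "drug", "pct_of_vehicle"].iloc[0] \
            == pytest.approx(0.0, abs=1e-9)

    def test_dose_series_recovers_ic50(self):
        concs = 10.0 ** np.arange(-7.5, -4.4, 0.5)
        curves = gen_turbidity(1e-6, concs, seed=9, noise_od=0.001)
        _, fit = turbidity_analysis(curves)
        assert fit is not None and not fit.ambiguous
        assert fit.ic50 == pytest.approx(1e-6, rel=0.2)


class TestCompareConditions:
    def test_identical_groups_maximal_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert compare_conditions(a, a) == pytest.approx(1.0)

    def test_disjoint_supports_minimal_exact_p(self):
        p = compare_conditions([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252, rel=1e-9)  # 0.0079 by enumeration

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = [compare_conditions(rng.normal(size=8), rng.normal(size=8))
              for _ in range(300)]
        assert 0.005 <= np.mean(np.array(ps) < 0.05) <= 0.12
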