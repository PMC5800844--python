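"""Contraction detection, rate modelling and respirometry."""

import math

import numpy as np
import pandas as pd
import pytest

from hypoxiscan import physiology as phys
from hypoxiscan.simulate import make_experiment_truth, simulate_experiment
from hypoxiscan.simulate.experiment import PlannedEvent


def _flat_trace(hours=4.0, level=5000.0):
    ts = np.arange(0, hours * 3600, 30.0)
    return pd.DataFrame({"timestamp_s": ts, "value": level})


class TestDetectContractions:
    def test_constant_trace_no_events(self):
        assert phys.detect_contractions(_flat_trace()) == []

    def test_all_missing_trace_empty(self):
        trace = _flat_trace()
        trace["value"] = np.nan
        assert phys.detect_contractions(trace) == []

    def test_three_planted_full_body_events_recovered(self):
        events = tuple(
            PlannedEvent(t, 720.0, 0.6, "full_body")
            for t in (3600.0, 10800.0, 18000.0)
        )
        truth = make_experiment_truth(((8.0, 100.0),), 0.0, seed=1,
                                      events=events)
        area, _ = simulate_experiment(truth)
        detected = phys.detect_contractions(area)
        assert len(detected) == 3
        for det, planted in zip(detected, events):
            assert det.klass == "full_body"
            assert planted.onset_s <= det.trough_s <= planted.end_s
            assert det.amplitude == pytest.approx(0.6, abs=0.05)

    def test_small_dips_classified_sub(self):
        events = (PlannedEvent(3600.0, 720.0, 0.2, "sub"),)
        truth = make_experiment_truth(((4.0, 100.0),), 0.0, seed=1,
                                      events=events)
        area, _ = simulate_experiment(truth)
        (det,) = phys.detect_contractions(area)
        assert det.klass == "sub"

    def test_events_separated_by_under_merge_gap_merged(self):
        # two dips 2 min apart read as one behavioural event
        events = (
            PlannedEvent(3600.0, 300.0, 0.6, "full_body"),
            PlannedEvent(4020.0, 300.0, 0.6, "full_body"),
        )
        truth = make_experiment_truth(((4.0, 100.0),), 0.0, seed=1,
                                      events=events)
        area, _ = simulate_experiment(truth)
        assert len(phys.detect_contractions(area)) == 1

    def test_event_ordering_invariant(self):
        truth = make_experiment_truth(((24.0, 100.0),), 10.0, seed=4)
        area, _ = simulate_experiment(truth)
        detected = phys.detect_contractions(area)
        for ev in detected:
            assert ev.start_s <= ev.trough_s <= ev.end_s
            assert 0.0 <= ev.amplitude <= 1.0


class TestContractionRate:
    def test_arithmetic(self):
        events = [
            phys.ContractionEvent(i * 7200.0, i * 7200.0 + 300,
                                  i * 7200.0 + 600, 0.6, "full_body")
            for i in range(6)
        ]
        assert phys.contraction_rate(events, (0.0, 43200.0)) == pytest.approx(
            12.0
        )

    def test_empty_events_zero(self):
        assert phys.contraction_rate([], (0.0, 86400.0)) == 0.0

    def test_class_filter(self):
        events = [
            phys.ContractionEvent(0.0, 100.0, 200.0, 0.6, "full_body"),
            phys.ContractionEvent(5000.0, 5100.0, 5200.0, 0.2, "sub"),
        ]
        assert phys.contraction_rate(events, (0.0, 86400.0), "sub") == 1.0

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            phys.contraction_rate([], (10.0, 10.0))

    def test_poisson_rate_recovery_over_replicates(self):
        # lambda = 10/day, detection on 50 replicate days: the mean
        # detected rate must sit within 2 SE of the refractory-thinned
        # renewal rate of the generator
        lam = 10.0 / 86400.0
        block = 1200.0 + 720.0
        expected = 86400.0 / (1.0 / lam + block)
        rates = []
        for seed in range(50):
            truth = make_experiment_truth(((24.0, 100.0),), 10.0, seed=seed)
            area, _ = simulate_experiment(truth)
            events = phys.detect_contractions(area)
            rates.append(
                phys.contraction_rate(events, (0.0, 86400.0), "full_body")
            )
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - expected) <= 2 * se + 1e-9


class TestRateModel:
    def test_identical_rates_give_zero_lrt(self):
        df = pd.DataFrame(
            [
                {"individual": "a", "level": "x", "count": 5,
                 "exposure_days": 1.0},
                {"individual": "a", "level": "y", "count": 5,
                 "exposure_days": 1.0},
            ]
        )
        fit = phys.fit_rate_model(df)
        assert fit.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value == pytest.approx(1.0, abs=1e-6)

    def test_strong_contrast_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(8):
            for lvl, rate in (("high", 10.0), ("low", 2.0)):
                rows.append(
                    {"individual": f"s{i}", "level": lvl,
                     "count": int(rng.poisson(rate)), "exposure_days": 1.0}
                )
        fit = phys.fit_rate_model(pd.DataFrame(rows))
        assert fit.p_value < 0.01
        assert fit.lrt_stat == pytest.approx(
            2 * (fit.loglik_fit - fit.loglik_null), abs=1e-9
        )
        assert fit.lrt_stat >= 0

    def test_rate_ratio_recovery(self):
        # estimated high/low rate ratio near the simulated 5x contrast
        rng = np.random.default_rng(15)
        ratios = []
        for _ in range(100):
            rows = []
            for i in range(8):
                base = math.exp(rng.normal(0.0, 0.2))
                for lvl, rate in (("a_high", 10.0), ("b_low", 2.0)):
                    rows.append(
                        {"individual": f"s{i}", "level": lvl,
                         "count": int(rng.poisson(rate * base)),
                         "exposure_days": 1.0}
                    )
            fit = phys.fit_rate_model(pd.DataFrame(rows))
            ratios.append(1.0 / fit.rate_ratio["b_low"])
        assert np.median(ratios) == pytest.approx(5.0, rel=0.05)

    def test_zero_count_group_reported_as_boundary(self):
        df = pd.DataFrame(
            [
                {"individual": "a", "level": "x", "count": 6,
                 "exposure_days": 1.0},
                {"individual": "a", "level": "y", "count": 0,
                 "exposure_days": 1.0},
                {"individual": "b", "level": "x", "count": 8,
                 "exposure_days": 1.0},
                {"individual": "b", "level": "y", "count": 0,
                 "exposure_days": 1.0},
            ]
        )
        fit = phys.fit_rate_model(df)
        assert fit.level_effects["y"] == float("-inf")

    def test_single_level_rejected(self):
        df = pd.DataFrame(
            [{"individual": "a", "level": "x", "count": 5,
              "exposure_days": 1.0}]
        )
        with pytest.raises(ValueError):
            phys.fit_rate_model(df)

    def test_nonpositive_exposure_rejected(self):
        df = pd.DataFrame(
            [
                {"individual": "a", "level": "x", "count": 5,
                 "exposure_days": 0.0},
                {"individual": "a", "level": "y", "count": 5,
                 "exposure_days": 1.0},
            ]
        )
        with pytest.raises(ValueError):
            phys.fit_rate_model(df)

    def test_posthoc_table_covers_all_pairs(self):
        rng = np.random.default_rng(2)
        rows = [
            {"individual": f"s{i}", "level": lvl,
             "count": int(rng.poisson(8.0)), "exposure_days": 1.0}
            for i in range(4)
            for lvl in ("a", "b", "c")
        ]
        fit = phys.fit_rate_model(pd.DataFrame(rows))
        assert len(fit.posthoc) == 3
        assert set(fit.posthoc["p_holm"]) <= set(
            fit.posthoc["p_holm"].clip(0, 1)
        )


class TestRespiration:
    def test_linear_drawdown_exact_slope(self):
        ts = np.arange(0, 3630, 30.0)
        o2 = pd.DataFrame(
            {"timestamp_s": ts, "value": 211.0 - 11.0 * ts / 3600.0}
        )
        rates = phys.respiration_rate(o2, 5)
        mid = rates["uptake_uM_per_hr"].iloc[10:-10]
        assert np.allclose(mid, 11.0)

    def test_flat_trace_zero(self):
        ts = np.arange(0, 3630, 30.0)
        o2 = pd.DataFrame({"timestamp_s": ts, "value": 200.0})
        rates = phys.respiration_rate(o2, 7)
        assert np.allclose(
            rates["uptake_uM_per_hr"].dropna(), 0.0, atol=1e-9
        )

    def test_piecewise_slopes_recovered_away_from_breakpoint(self):
        ts = np.arange(0, 7200, 30.0)
        values = np.where(
            ts < 3600, 211.0 - 10.0 * ts / 3600.0,
            201.0 - 2.0 * (ts - 3600.0) / 3600.0,
        )
        rates = phys.respiration_rate(
            pd.DataFrame({"timestamp_s": ts, "value": values}), 5
        )
        r = rates["uptake_uM_per_hr"]
        assert np.allclose(r.iloc[10:100], 10.0)
        assert np.allclose(r.iloc[130:-10], 2.0)

    def test_window_too_small_or_large_rejected(self):
        ts = np.arange(0, 300, 30.0)
        o2 = pd.DataFrame({"timestamp_s": ts, "value": 200.0})
        with pytest.raises(ValueError):
            phys.respiration_rate(o2, 2)
        with pytest.raises(ValueError):
            phys.respiration_rate(o2, 100)


class TestPhaseCoupling:
    @staticmethod
    def _rates_with_events(contrast=2.0):
        ts = np.arange(0, 14400, 30.0)
        events = [
            phys.ContractionEvent(1800.0, 2100.0, 2520.0, 0.6, "full_body"),
            phys.ContractionEvent(9000.0, 9300.0, 9720.0, 0.6, "full_body"),
        ]
        in_phase = np.zeros(len(ts), dtype=bool)
        for ev in events:
            in_phase |= (ts >= ev.start_s) & (ts <= ev.end_s)
        rr = np.where(in_phase, 10.0 * contrast, 10.0)
        return pd.DataFrame({"timestamp_s": ts, "uptake_uM_per_hr": rr}), events

    def test_identical_phases_difference_zero(self):
        rates, events = self._rates_with_events(contrast=1.0)
        out = phys.phase_coupled_uptake(rates, events, n_shifts=99, seed=0)
        assert out["difference"] == pytest.approx(0.0)
        assert out["p_value"] == 1.0

    def test_planted_contrast_recovered_exactly(self):
        rates, events = self._rates_with_events(contrast=2.0)
        out = phys.phase_coupled_uptake(rates, events, n_shifts=199, seed=0)
        assert out["difference"] == pytest.approx(10.0)
        assert out["p_value"] < 0.05

    def test_same_seed_identical_p(self):
        rates, events = self._rates_with_events()
        a = phys.phase_coupled_uptake(rates, events, n_shifts=99, seed=3)
        b = phys.phase_coupled_uptake(rates, events, n_shifts=99, seed=3)
        assert a == b

    def test_no_events_rejected(self):
        rates, _ = self._rates_with_events()
        with pytest.raises(ValueError):
            phys.phase_coupled_uptake(rates, [], n_shifts=9, seed=0)
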