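"""Time-course quantification: reference normalization, integrated signal
strength, fold changes, and re-activation onset detection."""

import dataclasses

import numpy as np
import pytest

import ligandswitch as ls
from ligandswitch.signal_quant import (
    InsufficientCoverageError,
    InvalidReferenceError,
    OnsetResult,
    UndefinedRatioError,
    WindowMismatchError,
)

from conftest import oracle_onset


def tc_from(times, *intensity_rows, condition="E-EGF", target="pERK",
            normalized=False):
    reps = tuple(ls.Replicate(np.asarray(times, float), np.asarray(row, float))
                 for row in intensity_rows)
    return ls.TimeCourseData(condition=condition, target=target,
                             replicates=reps, normalized=normalized)


class TestNormalize:
    def test_intensities_divided_by_reference(self):
        tc = tc_from([0, 10, 20], [50, 100, 200])
        norm = ls.normalize_timecourse(tc, ("E-EGF", "pERK", 10.0))
        assert np.allclose(norm.replicates[0].intensities, [0.5, 1.0, 2.0])
        assert norm.normalized

    def test_reference_point_maps_to_one(self):
        tc = tc_from([0, 10, 20], [3.0, 7.0, 9.0])
        norm = ls.normalize_timecourse(tc, ("E-EGF", "pERK", 10.0))
        assert norm.replicates[0].intensities[1] == pytest.approx(1.0)

    def test_idempotent_once_normalized(self):
        tc = tc_from([0, 10, 20], [50, 100, 200])
        once = ls.normalize_timecourse(tc, ("E-EGF", "pERK", 10.0))
        twice = ls.normalize_timecourse(once, ("E-EGF", "pERK", 10.0))
        assert twice is once

    def test_replicate_matched_normalization(self):
        tc = tc_from([0, 10], [10, 20], [100, 50])
        norm = ls.normalize_timecourse(tc, ("E-EGF", "pERK", 10.0))
        assert np.allclose(norm.replicates[0].intensities, [0.5, 1.0])
        assert np.allclose(norm.replicates[1].intensities, [2.0, 1.0])

    def test_external_reference_series(self):
        ref = tc_from([0, 10], [1.0, 4.0], condition="E-EGF")
        tc = tc_from([0, 10], [2.0, 8.0], condition="A-AREG")
        norm = ls.normalize_timecourse(tc, ("E-EGF", "pERK", 10.0),
                                       reference_data=ref)
        assert np.allclose(norm.replicates[0].intensities, [0.5, 2.0])

    def test_missing_or_zero_reference_signalled(self):
        tc = tc_from([0, 10], [0.0, 5.0])
        with pytest.raises(InvalidReferenceError):
            ls.normalize_timecourse(tc, ("E-EGF", "pERK", 0.0))  # zero band
        with pytest.raises(InvalidReferenceError):
            ls.normalize_timecourse(tc, ("E-EGF", "pERK", 99.0))  # absent


class TestIntegratedSignal:
    def test_constant_signal_is_a_rectangle(self):
        tc = tc_from([0, 30, 60], [1.0, 1.0, 1.0], normalized=True)
        s = ls.integrated_signal(tc, (0.0, 60.0))
        assert s.auc == pytest.approx(60.0)

    def test_trapezoid_exact_on_linear_signal(self):
        tc = tc_from([0, 30, 60], [0.0, 0.5, 1.0], normalized=True)
        s = ls.integrated_signal(tc, (0.0, 60.0))
        assert s.auc == pytest.approx(30.0, abs=1e-12)

    def test_zero_signal_zero_area(self):
        tc = tc_from([0, 30, 60], [0.0, 0.0, 0.0], normalized=True)
        assert ls.integrated_signal(tc, (0.0, 60.0)).auc == 0.0

    def test_edge_interpolation_when_sampled_beyond_window(self):
        # f(t) = t on [0, 100]; window [10, 50] -> integral 1200
        tc = tc_from([0, 100], [0.0, 100.0], normalized=True)
        s = ls.integrated_signal(tc, (10.0, 50.0))
        assert s.auc == pytest.approx(1200.0)

    def test_linearity_in_the_signal(self):
        t = np.arange(0.0, 61.0, 5.0)
        y = np.exp(-t / 30.0) + 0.1
        a1 = ls.integrated_signal(tc_from(t, y, normalized=True), (0, 60)).auc
        a3 = ls.integrated_signal(tc_from(t, 3 * y, normalized=True),
                                  (0, 60)).auc
        assert a3 == pytest.approx(3 * a1, rel=1e-12)

    def test_additivity_over_adjacent_windows(self):
        t = np.arange(0.0, 311.0, 10.0)
        y = np.exp(-t / 80.0) + 0.05 * np.sin(t / 25.0) + 0.2
        tc = tc_from(t, y, normalized=True)
        a = ls.integrated_signal(tc, (0.0, 60.0)).auc
        b = ls.integrated_signal(tc, (60.0, 310.0)).auc
        c = ls.integrated_signal(tc, (0.0, 310.0)).auc
        assert abs((a + b) - c) < 1e-9

    def test_matches_fine_grid_riemann_oracle(self):
        # smooth curve sampled every 2 min vs a 1e-3-min midpoint Riemann sum
        f = lambda t: np.exp(-t / 50.0) + 0.2 * np.sin(t / 15.0) ** 2 + 0.1
        t = np.arange(0.0, 61.0, 2.0)
        tc = tc_from(t, f(t), normalized=True)
        auc = ls.integrated_signal(tc, (0.0, 60.0)).auc
        fine = np.arange(0.0, 60.0, 1e-3) + 5e-4
        riemann = float(np.sum(f(fine)) * 1e-3)
        assert auc == pytest.approx(riemann, rel=5e-3)

    def test_replicate_mean_and_sd(self):
        tc = tc_from([0, 60], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0],
                     normalized=True)
        s = ls.integrated_signal(tc, (0.0, 60.0))
        assert s.auc == pytest.approx(120.0)
        assert s.auc_sd == pytest.approx(np.std([60.0, 120.0, 180.0], ddof=1))
        assert s.n_replicates == 3

    def test_uncovered_window_signalled(self):
        tc = tc_from([0, 30], [1.0, 1.0], normalized=True)
        with pytest.raises(InsufficientCoverageError):
            ls.integrated_signal(tc, (0.0, 60.0))

    def test_unnormalized_input_rejected(self):
        tc = tc_from([0, 30, 60], [1, 1, 1])
        with pytest.raises(ValueError):
            ls.integrated_signal(tc, (0.0, 60.0))


def summary(auc, window=(0.0, 60.0)):
    return ls.SignalSummary(auc=auc, auc_sd=0.0, window=window, n_replicates=3)


class TestFoldChange:
    def test_identity_and_simple_ratio(self):
        assert ls.fold_change(summary(2.0), summary(2.0)) == 1.0
        assert ls.fold_change(summary(60.0), summary(6.0)) == pytest.approx(10.0)

    def test_reciprocity(self):
        a, b = summary(3.7), summary(1.3)
        assert ls.fold_change(a, b) * ls.fold_change(b, a) == pytest.approx(1.0)

    def test_scale_invariance_under_common_normalization(self):
        a, b = summary(5.0), summary(2.0)
        a2, b2 = summary(5.0 / 7.0), summary(2.0 / 7.0)
        assert ls.fold_change(a, b) == pytest.approx(ls.fold_change(a2, b2))

    def test_errors(self):
        with pytest.raises(UndefinedRatioError):
            ls.fold_change(summary(1.0), summary(0.0))
        with pytest.raises(WindowMismatchError):
            ls.fold_change(summary(1.0), summary(1.0, window=(0.0, 310.0)))


class TestReactivationOnset:
    def two_pulse_tc(self, onset=160.0, noise_cv=0.0, seed=0,
                     n_replicates=1):
        sc = next(s for s in ls.scenario_presets() if s.name == "A-EGF-switch")
        sc = dataclasses.replace(
            sc, noise_cv=noise_cv, n_replicates=n_replicates,
            perk_shape=dataclasses.replace(sc.perk_shape, second_onset=onset),
        )
        gen = ls.gen_timecourse(sc, seed=seed)
        return dataclasses.replace(gen.perk, normalized=True)

    def test_monotone_decay_returns_none(self):
        t = np.arange(0.0, 101.0, 10.0)
        tc = tc_from(t, np.exp(-t / 30.0) + 1e-3, normalized=True)
        res = ls.reactivation_onset(tc)
        assert res.onset_min is None and res.reason is not None

    def test_monotone_rise_returns_none(self):
        t = np.arange(0.0, 101.0, 10.0)
        tc = tc_from(t, t / 100.0, normalized=True)
        assert ls.reactivation_onset(tc).onset_min is None

    def test_programmed_onset_detected_within_one_interval(self):
        res = ls.reactivation_onset(self.two_pulse_tc())
        assert res.onset_min is not None
        assert abs(res.onset_min - 160.0) <= 10.0

    def test_zero_rise_fraction_finds_first_uptick(self):
        t = np.arange(0.0, 91.0, 10.0)
        y = np.array([0.0, 1.0, 0.5, 0.3, 0.2, 0.2, 0.25, 0.3, 0.4, 0.5])
        tc = tc_from(t, y, normalized=True)
        res = ls.reactivation_onset(tc, rise_fraction=0.0)
        assert res.onset_min == 60.0  # first strictly-above-trough sample

    @pytest.mark.parametrize("onset,rise_fraction,seed", [
        (160.0, 0.2, 0), (160.0, 0.2, 1), (200.0, 0.2, 2),
        (120.0, 0.1, 3), (160.0, 0.5, 4),
    ])
    def test_agrees_with_brute_force_scan(self, onset, rise_fraction, seed):
        tc = self.two_pulse_tc(onset=onset, noise_cv=0.1, seed=seed,
                               n_replicates=3)
        times, mean = tc.mean_curve()
        expected = oracle_onset(times, mean, rise_fraction)
        res = ls.reactivation_onset(tc, rise_fraction=rise_fraction)
        assert res.onset_min == expected
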