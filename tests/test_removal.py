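"""Virtual-removal framework: BR/AR/RR correlations, rho_hat, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seegsp.core import FrameworkConfig, SegmentRates, build_spatial_system
from seegsp.removal import (
    MissingSOZError,
    choose_threshold,
    cliffs_delta,
    patient_perturbation,
    perturbation_strength,
    rho_after_removal,
    rho_before_removal,
    rho_random_removal,
    segment_is_valid,
)
from helpers import build_patient


def seg(rates, n_minutes=10.0):
    return SegmentRates(segment_id="S", rates=rates, n_minutes=n_minutes)


class TestSegmentValidity:
    def test_above_threshold(self, cfg):
        assert segment_is_valid(seg({"a": 2.0, "b": 0.1}), cfg)

    def test_all_zero(self, cfg):
        assert not segment_is_valid(seg({"a": 0.0, "b": 0.0}), cfg)

    def test_exactly_one_per_minute_is_invalid(self, cfg):
        # "more than one per minute" is a strict inequality
        assert not segment_is_valid(seg({"a": 1.0}), cfg)


class TestBeforeAfterRemoval:
    def test_noiseless_power_law_gives_minus_one(self, power_law_patient, cfg):
        rho = rho_before_removal(
            power_law_patient, power_law_patient.segments[0], cfg
        )
        assert rho == pytest.approx(-1.0, abs=1e-9)

    def test_reference_constrained_to_soz(self, cfg):
        # a non-SOZ channel holds the global maximum; the reference must
        # still be the best SOZ channel
        coords = {"s": (0, 0, 0), "n": (5, 0, 0), "a": (10, 0, 0),
                  "b": (0, 7, 0), "c": (0, 0, 9)}
        rates = {"s": 3.0, "n": 8.0, "a": 1.0, "b": 0.5, "c": 0.4}
        patient = build_patient(coords, rates, soz={"s"})
        direct = build_spatial_system(patient, patient.segments[0], "s", cfg)
        assert rho_before_removal(patient, patient.segments[0], cfg) == direct.rho

    def test_missing_soz_errors(self, cfg):
        coords = {"a": (0, 0, 0), "b": (1, 0, 0), "c": (2, 0, 0)}
        patient = build_patient(coords, {"a": 1.0, "b": 1.0, "c": 1.0})
        with pytest.raises(MissingSOZError):
            rho_before_removal(patient, patient.segments[0], cfg)

    def test_quiescent_after_removal_is_exact_zero(self, cfg):
        coords = {"s": (0, 0, 0)}
        rates = {"s": 5.0}
        rng = np.random.default_rng(0)
        for i in range(6):
            coords[f"n{i}"] = tuple(rng.uniform(-20, 20, 3))
            rates[f"n{i}"] = 0.2  # everything left is below 1/min
        patient = build_patient(coords, rates, soz={"s"})
        assert rho_after_removal(patient, patient.segments[0], cfg) == 0.0

    def test_empty_soz_equals_unconstrained_before(self, cfg):
        rng = np.random.default_rng(1)
        coords = {f"c{i}": tuple(rng.uniform(-15, 15, 3)) for i in range(7)}
        rates = {f"c{i}": float(rng.uniform(0.5, 6.0)) for i in range(7)}
        patient = build_patient(coords, rates)  # no SOZ flags
        best = max(rates, key=lambda c: (rates[c], c))
        direct = build_spatial_system(patient, patient.segments[0], best, cfg)
        assert rho_after_removal(patient, patient.segments[0], cfg) == pytest.approx(
            direct.rho
        )

    def test_too_few_nonsoz_is_undefined(self, cfg):
        coords = {"s": (0, 0, 0), "a": (1, 0, 0), "b": (2, 0, 0), "c": (3, 0, 0)}
        patient = build_patient(
            coords, {"s": 5.0, "a": 2.0, "b": 1.5, "c": 1.2}, soz={"s", "a"}
        )
        assert rho_after_removal(patient, patient.segments[0], cfg) is None


class TestRandomRemoval:
    def test_noiseless_subset_stays_on_line(self, power_law_patient, cfg):
        rho = rho_random_removal(
            power_law_patient, power_law_patient.segments[0],
            cfg.with_(rr_iterations=10), np.random.default_rng(0),
        )
        assert rho == pytest.approx(-1.0, abs=1e-9)

    def test_minimum_one_channel_removed(self, power_law_patient, cfg):
        # N_SOZ = 1 so round(0.2 * 1) = 0 would remove nothing; the floor
        # rule removes one channel and the subset system has one point less
        small = cfg.with_(rr_iterations=1)
        rho = rho_random_removal(
            power_law_patient, power_law_patient.segments[0], small,
            np.random.default_rng(0),
        )
        assert rho == pytest.approx(-1.0, abs=1e-9)  # still on the exact line

    def test_random_removal_tracks_before_removal(self, small_cohort, cfg):
        """Deleting 20% of the SOZ size at random barely moves rho."""
        diffs = []
        for sp in small_cohort:
            result = patient_perturbation(
                sp.data, cfg, np.random.default_rng(0)
            )
            diffs.append(abs(result.rho_br - result.rho_rr))
        assert float(np.median(diffs)) < 0.05


class TestPerturbationStrength:
    def test_unit_ratio(self, cfg):
        assert perturbation_strength(-0.4, -0.4, cfg) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_printed_example_correlations(self, cfg):
        # BR -0.50, AR 0.04 -> log(1 + 12.5) = log(13.5)
        assert perturbation_strength(-0.50, 0.04, cfg) == pytest.approx(
            np.log(13.5), abs=1e-12
        )
        assert np.log(13.5) == pytest.approx(2.6026, abs=1e-4)

    def test_zero_after_removal_capped(self, cfg):
        value = perturbation_strength(-0.5, 0.0, cfg)
        assert value == pytest.approx(np.log(1.0 + 0.5e6))
        assert np.isfinite(value)

    def test_both_zero(self, cfg):
        assert perturbation_strength(0.0, 0.0, cfg) == pytest.approx(np.log(1.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(0.001, 0.3))
    def test_monotone_in_before_magnitude(self, br, delta):
        cfg = FrameworkConfig()
        ar = -0.3
        assert perturbation_strength(-(br + delta), ar, cfg) > perturbation_strength(
            -br, ar, cfg
        )


class TestPatientPerturbation:
    def test_single_segment_equals_segment_values(self, power_law_patient, cfg):
        result = patient_perturbation(
            power_law_patient, cfg.with_(rr_iterations=5),
            np.random.default_rng(0),
        )
        assert result.n_valid_segments == 1
        assert result.rho_br == result.rho_br_per_segment[0]
        assert result.rho_ar == result.rho_ar_per_segment[0]

    def test_medians_and_strength_consistent(self, small_cohort, cfg):
        sp = small_cohort[0]
        result = patient_perturbation(sp.data, cfg, np.random.default_rng(3))
        assert result.rho_br == pytest.approx(np.median(result.rho_br_per_segment))
        assert result.rho_ar == pytest.approx(np.median(result.rho_ar_per_segment))
        assert result.strength == pytest.approx(
            perturbation_strength(result.rho_br, result.rho_ar, cfg)
        )

    def test_median_robust_to_one_outlier(self):
        # medians of 3 values ignore a single outlier
        assert np.median([-0.6, -0.55, 0.9]) == -0.55


class TestChooseThreshold:
    def test_perfectly_separable(self):
        strengths = {"a": 2.0, "b": 2.0, "c": 0.1, "d": 0.1}
        labels = {"a": True, "b": True, "c": False, "d": False}
        report = choose_threshold(strengths, labels, n_bootstrap=50)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.auc == 1.0
        assert report.per_patient_calls["a"] == "well_sampled"
        assert report.per_patient_calls["c"] == "poorly_sampled"

    def test_threshold_separates_printed_cohort_medians(self):
        # the class medians 1.40 / 0.99 must land on opposite sides
        strengths = {"w1": 1.40, "w2": 2.2, "p1": 0.99, "p2": 0.4}
        labels = {"w1": True, "w2": True, "p1": False, "p2": False}
        report = choose_threshold(strengths, labels, n_bootstrap=50)
        assert 0.99 < report.threshold <= 1.40
        assert report.per_patient_calls["w1"] == "well_sampled"
        assert report.per_patient_calls["p1"] == "poorly_sampled"

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        strengths = {f"p{i}": float(rng.uniform(0, 3)) for i in range(200)}
        labels = {f"p{i}": bool(rng.integers(2)) for i in range(200)}
        report = choose_threshold(strengths, labels, n_bootstrap=100,
                                  rng=np.random.default_rng(1))
        assert abs(report.auc - 0.5) < 0.15

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            choose_threshold({"a": 1.0, "b": 2.0}, {"a": True, "b": True})


class TestCliffsDelta:
    def test_complete_dominance(self):
        assert cliffs_delta([3, 4], [1, 2]) == 1.0

    def test_identical_samples(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0

    def test_interleaved(self):
        assert cliffs_delta([1, 3], [2]) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
    )
    def test_matches_exhaustive_count(self, x, y):
        gt = sum(1 for xi in x for yj in y if xi > yj)
        lt = sum(1 for xi in x for yj in y if xi < yj)
        assert cliffs_delta(x, y) == pytest.approx((gt - lt) / (len(x) * len(y)))
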