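"""Rupture detection, per-event WLC fitting, filters, classification."""

import numpy as np
import pytest

from forcespec.curves import ProcessedCurve, convert_to_force_separation
from forcespec.events import (
    DetectionConfig,
    FilterCriteria,
    analyze_curve,
    apply_filters,
    classify_curve,
    detect_events,
    fit_event_wlc,
    hit_rate,
    loading_rate_at_rupture,
)
from forcespec.polymer import WLCParams, wlc_force, wlc_stiffness
from forcespec.simulate import (
    PullingConfig,
    scenario_presets,
    simulate_map,
    simulate_pull,
)


def _processed(force, separation=None, curve_id="p", velocity=1000.0):
    force = np.asarray(force, dtype=float)
    if separation is None:
        separation = np.linspace(0, force.size * 0.05, force.size)
    return ProcessedCurve(
        tip_sample_separation_nm=np.asarray(separation, dtype=float),
        force_pN=force,
        baseline_offset_pN=0.0,
        contact_offset_nm=0.0,
        curve_id=curve_id,
        retraction_velocity_nm_s=velocity,
        spring_constant_pN_per_nm=30.0,
    )


class TestDetection:
    def test_double_rupture_found_at_truth_positions(self, processed_noise_free_double):
        proc, truth = processed_noise_free_double
        peaks = detect_events(proc)
        assert len(peaks) == 2
        for peak, ev in zip(peaks, truth):
            assert abs(peak - ev.sample_index) <= 2

    def test_monotone_wlc_has_no_candidates(self):
        params = WLCParams(0.4, 60.0)
        x = np.linspace(0, 50, 1200)
        proc = _processed(wlc_force(params, x), x)
        assert detect_events(proc) == []

    def test_pure_noise_has_no_candidates(self):
        rng = np.random.default_rng(123)
        proc = _processed(rng.normal(0, 5.0, 3000))
        assert detect_events(proc) == []

    def test_curve_shorter_than_window_rejected(self):
        proc = _processed(np.zeros(8))
        with pytest.raises(ValueError, match="window"):
            detect_events(proc)

    def test_candidates_ordered_by_separation(self, wildtype_curves):
        for curve, _ in wildtype_curves[:20]:
            proc = convert_to_force_separation(curve)
            peaks = detect_events(proc)
            seps = proc.tip_sample_separation_nm[peaks]
            assert np.all(np.diff(seps) >= 0)


class TestEventFit:
    def test_noise_free_edge_recovers_contour_length(self, processed_noise_free_double):
        proc, truth = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[0])
        assert ev.fitted_Lc_nm == pytest.approx(truth[0].Lc_before_nm, abs=0.5)
        ev2 = fit_event_wlc(proc, peaks[1], previous_peak=peaks[0], event_index=1)
        assert ev2.fitted_Lc_nm == pytest.approx(truth[1].Lc_before_nm, abs=0.5)

    def test_rupture_force_read_at_last_pre_rupture_sample(
        self, processed_noise_free_double
    ):
        proc, truth = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[1], previous_peak=peaks[0])
        assert ev.rupture_force_pN == pytest.approx(truth[1].force_pN, rel=0.05)

    def test_linear_edge_flagged_by_nonlinearity_filter(self):
        # adhesion-like: straight ramp then release, away from the surface
        sep = np.linspace(0, 60, 1200)
        force = np.where(sep < 30, 4.0 * sep, 0.0)
        proc = _processed(force, sep)
        peaks = detect_events(proc)
        assert peaks
        events = [fit_event_wlc(proc, peaks[0])]
        apply_filters(events)
        assert not events[0].accepted
        assert events[0].reason == "linear_profile"

    def test_wildtype_modal_contour_lengths_recovered(self, wildtype_analysis):
        # generated with Lc1 = 47 nm (unfolding) and Lc2 = 67 nm (unbinding)
        lc1 = [r.Lc_values_nm[0] for r in wildtype_analysis.delta_lc_records]
        lc2 = [r.Lc_values_nm[1] for r in wildtype_analysis.delta_lc_records]
        assert np.median(lc1) == pytest.approx(47.0, abs=1.5)
        assert np.median(lc2) == pytest.approx(67.0, abs=1.5)


class TestLoadingRate:
    def test_typical_event_order_1e4_at_1um_per_s(self, wildtype_analysis):
        rates = [ev.loading_rate_pN_s for ev in wildtype_analysis.accepted_events]
        assert 1e3 < np.median(rates) < 1e5
        assert np.median(rates) == pytest.approx(1e4, rel=1.0)

    def test_linear_in_velocity(self, processed_noise_free_double):
        proc, _ = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[0])
        r1 = loading_rate_at_rupture(ev, 1000.0)
        r2 = loading_rate_at_rupture(ev, 2000.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_slope_matches_finite_difference(self, processed_noise_free_double):
        proc, _ = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[0])
        params = WLCParams(0.4, ev.fitted_Lc_nm, proc.temperature_K)
        x = ev.extension_at_rupture_nm
        h = 1e-5
        fd = (wlc_force(params, x + h) - wlc_force(params, x - h)) / (2 * h)
        assert wlc_stiffness(params, x) == pytest.approx(fd, rel=1e-3)

    def test_missing_velocity_rejected(self, processed_noise_free_double):
        proc, _ = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[0])
        with pytest.raises(ValueError, match="velocity"):
            loading_rate_at_rupture(ev, 0.0)


class TestFilters:
    def test_adhesion_spike_below_min_separation(self):
        sep = np.linspace(0, 60, 1200)
        force = np.where(sep < 6, 20.0 * sep, 0.0)
        proc = _processed(force, sep)
        peaks = detect_events(proc)
        assert peaks
        events = [fit_event_wlc(proc, peaks[0])]
        apply_filters(events)
        assert not events[0].accepted
        assert events[0].reason == "below_min_separation"

    def test_short_contour_rejected(self, processed_noise_free_double):
        proc, _ = processed_noise_free_double
        peaks = detect_events(proc)
        ev = fit_event_wlc(proc, peaks[0])
        ev.fitted_Lc_nm = 15.0
        apply_filters([ev])
        assert not ev.accepted
        assert ev.reason == "contour_below_linker"

    def test_filter_conservation(self, wildtype_curves):
        """Every detected candidate ends exactly one of accepted / rejected
        with a reason."""
        for curve, _ in wildtype_curves[:30]:
            proc = convert_to_force_separation(curve)
            events, cls = analyze_curve(proc)
            n_accepted = sum(ev.accepted for ev in events)
            n_rejected = sum((not ev.accepted) and bool(ev.reason) for ev in events)
            assert n_accepted + n_rejected == len(events)
            assert cls.n_accepted_events == n_accepted

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(min_separation_nm=-1.0)


class TestClassification:
    def test_classify_counts_accepted(self, wildtype_curves):
        curve, truth = wildtype_curves[0]
        events, cls = analyze_curve(convert_to_force_separation(curve))
        assert cls.n_accepted_events == sum(ev.accepted for ev in events)
        assert cls.accepted == (cls.n_accepted_events >= 1)

    def test_hit_rate_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hit_rate([])

    def test_all_empty_map_zero_hit_rate(self):
        cfg = PullingConfig(seed=77)
        dataset = simulate_map(cfg, "wild-type", n_curves=25, fractions=(0.0, 0.0))
        classes = []
        for curve in dataset.curves:
            _, cls = analyze_curve(convert_to_force_separation(curve))
            classes.append(cls)
        assert hit_rate(classes) == 0.0

    def test_triple_events_in_destabilized_scenario(self):
        cfg = PullingConfig(seed=4)
        rng = np.random.default_rng(42)
        n_triple = 0
        for i in range(40):
            curve, truth = simulate_pull(
                cfg, scenario_presets("3A"), f"3a-{i}", rng=rng
            )
            if len(truth) != 3:
                continue
            _, cls = analyze_curve(convert_to_force_separation(curve))
            if cls.n_accepted_events == 3:
                n_triple += 1
        assert n_triple >= 10

    def test_event_order_preserved_through_pipeline(self, wildtype_curves):
        for curve, _ in wildtype_curves[:15]:
            events, _ = analyze_curve(convert_to_force_separation(curve))
            seps = [ev.extension_at_rupture_nm for ev in events]
            assert seps == sorted(seps)


class TestVelocityInvariance:
    def test_fitted_lc_invariant_to_velocity(self):
        """The fitted contour length is a mechanical property, not a
        kinetic one: the same construct pulled at different speeds gives
        the same Lc (within 1%)."""
        lcs = {}
        for v in (500.0, 2000.0):
            cfg = PullingConfig(
                retraction_velocity_nm_s=v, force_noise_sigma_pN=0.0, seed=13
            )
            rng = np.random.default_rng(99)
            vals = []
            for i in range(12):
                curve, truth = simulate_pull(
                    cfg, scenario_presets("XL_barrel"), f"v{v}-{i}", rng=rng
                )
                events, _ = analyze_curve(convert_to_force_separation(curve))
                vals.extend(ev.fitted_Lc_nm for ev in events if ev.accepted)
            lcs[v] = np.median(vals)
        assert lcs[500.0] == pytest.approx(lcs[2000.0], rel=0.01)
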