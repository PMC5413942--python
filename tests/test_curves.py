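"""Curve data model, frame conversion, and TSV I/O."""

import numpy as np
import pytest

from forcespec.curves import (
    CurveFormatError,
    ForceMap,
    RawForceCurve,
    convert_to_force_separation,
    read_curve,
    read_map,
    write_curve,
    write_events_table,
    read_events_table,
)
from forcespec.events import RuptureEvent
from forcespec.simulate import PullingConfig, scenario_presets, simulate_pull


def _tether_curve(baseline_pN=0.0, contact_nm=0.0, noise=0.0, seed=0):
    """Synthetic retraction with a contact wall, a tether ramp and a free tail."""
    cfg = PullingConfig(
        force_noise_sigma_pN=noise,
        baseline_offset_pN=baseline_pN,
        contact_offset_nm=contact_nm,
        seed=seed,
    )
    curve, _ = simulate_pull(cfg, scenario_presets("wild-type"), "synth")
    return curve


class TestConversion:
    def test_recovers_known_offsets(self):
        curve = _tether_curve(baseline_pN=7.0, contact_nm=3.0, noise=1.0)
        proc = convert_to_force_separation(curve)
        assert proc.baseline_offset_pN == pytest.approx(7.0, abs=0.07 * 7)
        assert proc.contact_found
        assert proc.contact_offset_nm == pytest.approx(3.0, abs=0.03 * 3 + 0.2)
        # baseline region re-zeroed
        tail = proc.force_pN[-proc.n_samples // 5 :]
        assert abs(tail.mean()) < 0.5

    def test_all_zero_deflection_passthrough(self):
        n = 64
        curve = RawForceCurve(
            time_s=np.linspace(0, 1, n),
            piezo_displacement_nm=np.linspace(0, 100, n),
            deflection_nm=np.zeros(n),
            spring_constant_pN_per_nm=30.0,
            retraction_velocity_nm_s=100.0,
            curve_id="zero",
        )
        proc = convert_to_force_separation(curve)
        assert np.allclose(proc.force_pN, 0.0)
        assert np.allclose(proc.tip_sample_separation_nm, curve.piezo_displacement_nm)
        assert not proc.contact_found

    def test_preconverted_force_only_zeroed(self):
        n = 64
        force = np.concatenate([np.linspace(0, 40, n // 2), np.zeros(n // 2)])
        curve = RawForceCurve(
            time_s=np.linspace(0, 1, n),
            piezo_displacement_nm=np.linspace(0, 100, n),
            deflection_nm=None,
            force_pN=force,
            spring_constant_pN_per_nm=30.0,
            retraction_velocity_nm_s=100.0,
            curve_id="pre",
        )
        proc = convert_to_force_separation(curve)
        # already baseline-zeroed input: offsets are (near) zero
        assert proc.baseline_offset_pN == pytest.approx(0.0, abs=1e-9)
        assert proc.contact_offset_nm == 0.0

    def test_conversion_is_linear_in_deflection(self):
        curve = _tether_curve(noise=0.0)
        doubled = RawForceCurve(
            time_s=curve.time_s,
            piezo_displacement_nm=curve.piezo_displacement_nm,
            deflection_nm=2.0 * curve.deflection_nm,
            spring_constant_pN_per_nm=curve.spring_constant_pN_per_nm,
            retraction_velocity_nm_s=curve.retraction_velocity_nm_s,
            curve_id="x2",
        )
        assert np.allclose(doubled.raw_force_pN(), 2.0 * curve.raw_force_pN())

    def test_zeroing_is_idempotent(self):
        curve = _tether_curve(baseline_pN=5.0, contact_nm=2.0)
        once = convert_to_force_separation(curve)
        again = convert_to_force_separation(
            RawForceCurve(
                time_s=curve.time_s,
                piezo_displacement_nm=once.tip_sample_separation_nm
                + once.force_pN / curve.spring_constant_pN_per_nm,
                deflection_nm=once.force_pN / curve.spring_constant_pN_per_nm,
                spring_constant_pN_per_nm=curve.spring_constant_pN_per_nm,
                retraction_velocity_nm_s=curve.retraction_velocity_nm_s,
                curve_id="again",
            )
        )
        assert np.allclose(again.force_pN, once.force_pN, atol=0.2)
        assert np.allclose(
            again.tip_sample_separation_nm, once.tip_sample_separation_nm, atol=0.3
        )

    def test_missing_retract_segment(self):
        curve = _tether_curve()
        curve.segment = "approach"
        with pytest.raises(ValueError, match="retract"):
            convert_to_force_separation(curve)


class TestValidation:
    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            RawForceCurve(
                time_s=np.arange(5, dtype=float),
                piezo_displacement_nm=np.arange(5, dtype=float),
                deflection_nm=np.zeros(5),
                spring_constant_pN_per_nm=30.0,
                retraction_velocity_nm_s=100.0,
                curve_id="short",
            )

    def test_nonincreasing_time(self):
        t = np.linspace(0, 1, 32)
        t[10] = t[9]
        with pytest.raises(ValueError, match="time"):
            RawForceCurve(
                time_s=t,
                piezo_displacement_nm=np.linspace(0, 10, 32),
                deflection_nm=np.zeros(32),
                spring_constant_pN_per_nm=30.0,
                retraction_velocity_nm_s=100.0,
                curve_id="bad-time",
            )

    def test_map_cycle_count_must_match(self):
        curve = _tether_curve()
        with pytest.raises(ValueError, match="cycles"):
            ForceMap(curves=[curve], cycles=2)


class TestIO:
    def test_round_trip_bit_identical(self, tmp_path):
        curve = _tether_curve(baseline_pN=3.0, contact_nm=1.5, noise=5.0, seed=9)
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        assert np.array_equal(back.time_s, curve.time_s)
        assert np.array_equal(back.piezo_displacement_nm, curve.piezo_displacement_nm)
        assert np.array_equal(back.deflection_nm, curve.deflection_nm)
        assert back.curve_id == curve.curve_id
        assert back.spring_constant_pN_per_nm == curve.spring_constant_pN_per_nm
        assert back.retraction_velocity_nm_s == curve.retraction_velocity_nm_s

    def test_map_of_600_curves(self, tmp_path):
        n = 16
        base = RawForceCurve(
            time_s=np.linspace(0, 1, n),
            piezo_displacement_nm=np.linspace(0, 10, n),
            deflection_nm=np.zeros(n),
            spring_constant_pN_per_nm=30.0,
            retraction_velocity_nm_s=1000.0,
            curve_id="c",
        )
        for i in range(600):
            base.curve_id = f"c{i:04d}"
            write_curve(base, tmp_path / f"c{i:04d}.tsv")
        fmap = read_map(tmp_path)
        assert len(fmap) == 600
        assert fmap.cycles == 600

    def test_missing_spring_constant_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["#curve_id\tx", "#retraction_velocity_nm_s\t100", "time_s\tpiezo_nm\tdeflection_nm"]
        lines += [f"{i * 0.1}\t{i}\t0" for i in range(20)]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CurveFormatError, match="spring_constant"):
            read_curve(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        lines = [
            "#curve_id\tx",
            "#spring_constant_pN_per_nm\t30",
            "#retraction_velocity_nm_s\t100",
            "time_s\tpiezo_nm\tdeflection_nm",
        ]
        lines += [f"{i * 0.1}\t{i}\t0" for i in range(20)]
        lines[10] = "0.6\t6"  # drop a column
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CurveFormatError, match="ragged"):
            read_curve(path)

    def test_empty_directory(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no curves"):
            read_map(tmp_path)

    def test_events_table_round_trip(self, tmp_path):
        ev = RuptureEvent(
            curve_id="c1",
            event_index=0,
            peak_sample=100,
            edge_start=10,
            edge_end=95,
            extension_at_rupture_nm=36.5,
            rupture_force_pN=112.0,
            fitted_Lc_nm=47.1,
            fit_residual_rms_pN=4.2,
            force_drop_pN=110.0,
            loading_rate_pN_s=1.1e4,
            accepted=True,
        )
        path = tmp_path / "events.tsv"
        write_events_table([ev], path)
        df = read_events_table(path)
        assert len(df) == 1
        assert df.loc[0, "Lc_nm"] == pytest.approx(47.1)
        assert bool(df.loc[0, "accepted"]) is True
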