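import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dibh_margin import (
    RpmTrace,
    SimulationSpec,
    SyntheticImageSpec,
    compute_amplitude,
    render_frames,
    simulate_errors,
    simulate_rpm_trace,
)
from dibh_margin.synth import TRACE_COLUMNS, SimulationSpecError

from ._oracles import brute_force_amplitude
from .conftest import TRUTH


class TestSimulateErrors:
    def test_degenerate_variances_give_constant_trace(self):
        spec = SimulationSpec(n_patients=3, n_fractions=2, frames_per_field=4,
                              mean_m=0.3, sigma_pt=0, sigma_fr=0, sigma_intra=0)
        df = simulate_errors(spec)
        assert list(df.columns) == TRACE_COLUMNS
        np.testing.assert_allclose(df["error_mm"], 0.3)

    def test_seeded_generation_is_bit_reproducible(self):
        spec = SimulationSpec(n_patients=4, n_fractions=3, seed=11)
        a, b = simulate_errors(spec), simulate_errors(spec)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_errors(spec.with_seed(12))
        assert not np.array_equal(a["error_mm"], c["error_mm"])

    def test_grand_mean_near_truth_at_study_scale(self, study_scale_trace):
        """At the study design the sample grand mean sits within ~3 SE of M."""
        patient_means = study_scale_trace.groupby("patient_id")["error_mm"].mean()
        # Patient means are iid with variance ~ (Sigma_pt^2 + sigma_fr^2/F).
        se = np.sqrt((TRUTH["sigma_pt"] ** 2 + TRUTH["sigma_fr"] ** 2 / 16) / 25)
        assert abs(patient_means.mean() - TRUTH["mean_m"]) < 3 * se

    def test_law_of_total_variance(self):
        spec = SimulationSpec(n_patients=400, n_fractions=8, n_fields=1,
                              frames_per_field=12, sigma_pt=0.8, sigma_fr=1.2,
                              sigma_intra=1.6, seed=5)
        df = simulate_errors(spec)
        total = 0.8**2 + 1.2**2 + 1.6**2
        # Dominant MC error: patient-level chi2 with P terms.
        mc_se = total * np.sqrt(2 / 400)
        assert abs(df["error_mm"].var() - total) < 3 * mc_se

    def test_patient_mean_dispersion_matches_closed_form(self):
        f, k = 6, 20
        spec = SimulationSpec(n_patients=600, n_fractions=f, n_fields=1,
                              frames_per_field=k, sigma_pt=0.8, sigma_fr=1.2,
                              sigma_intra=1.6, seed=9)
        df = simulate_errors(spec)
        pm = df.groupby("patient_id")["error_mm"].mean()
        expected_var = 0.8**2 + 1.2**2 / f + 1.6**2 / (f * k)
        assert pm.var(ddof=1) == pytest.approx(expected_var,
                                               abs=3 * expected_var * np.sqrt(2 / 599))

    def test_fraction_effect_shared_across_fields(self):
        """Fields are labels, not a variance level: with sigma_intra=0 both
        fields of a fraction carry the identical error."""
        spec = SimulationSpec(n_patients=2, n_fractions=3, n_fields=2,
                              frames_per_field=4, sigma_intra=0.0, seed=3)
        df = simulate_errors(spec)
        per_field = df.groupby(["patient_id", "fraction", "field"])["error_mm"].first()
        for (p, f), group in per_field.groupby(level=[0, 1]):
            assert group.nunique() == 1

    def test_unbalanced_frame_counts_from_breath_holds(self):
        spec = SimulationSpec(n_patients=3, n_fractions=4, seed=2)
        counts = simulate_errors(spec).groupby(
            ["patient_id", "fraction", "field"]).size()
        assert counts.nunique() > 1  # draws differ across fields
        expected = spec.breath_hold_mean_s * spec.frame_rate_hz
        assert abs(counts.mean() - expected) < 5 * spec.breath_hold_sd_s * spec.frame_rate_hz

    @pytest.mark.parametrize("bad", [
        {"n_patients": 0}, {"sigma_pt": -1.0}, {"frame_rate_hz": 0.0},
        {"frames_per_field": 0}, {"breath_hold_sd_s": -0.1},
    ])
    def test_invalid_spec_names_offending_field(self, bad):
        with pytest.raises(SimulationSpecError) as err:
            SimulationSpec(**bad)
        assert next(iter(bad)) in str(err.value)


class TestRpmTrace:
    def test_flat_trace_has_zero_amplitude(self):
        trace = simulate_rpm_trace(10.0, amplitude_mm=0.0, baseline_mm=4.0)
        assert compute_amplitude(trace) == 0.0
        np.testing.assert_allclose(trace.position_mm, 4.0)

    def test_target_amplitude_is_reproduced(self):
        trace = simulate_rpm_trace(20.4, amplitude_mm=1.36, seed=8)
        assert compute_amplitude(trace) == pytest.approx(1.36, rel=0.01)
        assert trace.gate_lower_mm < trace.position_mm.min()
        assert trace.gate_upper_mm > trace.position_mm.max()

    def test_sample_count_is_duration_times_rate(self):
        trace = simulate_rpm_trace(20.4, 1.36, sample_rate_hz=25.0)
        assert trace.time_s.size == 510

    def test_amplitude_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(10.0, 2.0, size=137)
        trace = RpmTrace(time_s=np.arange(pos.size) * 0.04, position_mm=pos,
                         gate_upper_mm=20.0, gate_lower_mm=0.0)
        assert compute_amplitude(trace) == pytest.approx(
            brute_force_amplitude(pos), abs=1e-12)

    def test_amplitude_by_inspection(self):
        trace = RpmTrace(time_s=np.array([0.0, 1.0, 2.0]),
                         position_mm=np.array([10.0, 11.2, 10.5]),
                         gate_upper_mm=12.0, gate_lower_mm=9.0)
        assert compute_amplitude(trace) == pytest.approx(1.2)

    def test_empty_trace_and_negative_amplitude_rejected(self):
        empty = RpmTrace(time_s=np.array([]), position_mm=np.array([]),
                         gate_upper_mm=1.0, gate_lower_mm=0.0)
        with pytest.raises(ValueError):
            compute_amplitude(empty)
        with pytest.raises(ValueError):
            simulate_rpm_trace(10.0, amplitude_mm=-1.0)

    def test_time_must_increase(self):
        with pytest.raises(ValueError):
            RpmTrace(time_s=np.array([0.0, 0.0]), position_mm=np.array([1.0, 2.0]),
                     gate_upper_mm=3.0, gate_lower_mm=0.0)

    @given(amplitude=st.floats(0.0, 10.0), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_invariant_over_waveform_draws(self, amplitude, seed):
        trace = simulate_rpm_trace(15.0, amplitude, baseline_mm=-2.0, seed=seed)
        assert compute_amplitude(trace) == pytest.approx(amplitude, rel=0.01, abs=1e-9)


class TestRenderFrames:
    def test_noiseless_render_recovers_exact_pixel(self):
        spec = SyntheticImageSpec(noise_sd=0.0, blur_sigma_px=1.0)
        stack = render_frames(spec, [0.0])
        # Edge at frame centre: symmetric erf profile around the centre column.
        centre = (spec.frame_shape[1] - 1) / 2.0
        col_profile = stack.frames[0].astype(float).mean(axis=0)
        mid_level = spec.base_level + spec.contrast / 2.0
        crossing = np.interp(mid_level, col_profile, np.arange(col_profile.size))
        assert crossing == pytest.approx(centre, abs=0.51)

    def test_offset_shifts_edge_by_projected_pixels(self):
        spec = SyntheticImageSpec(frame_shape=(64, 256), noise_sd=0.0)
        iso = spec.isocenter_pixel_mm
        stack = render_frames(spec, [0.0, 2.0])
        prof0 = stack.frames[0].astype(float).mean(axis=0)
        prof1 = stack.frames[1].astype(float).mean(axis=0)
        mid = spec.base_level + spec.contrast / 2.0
        x = np.arange(prof0.size)
        shift = np.interp(mid, prof1, x) - np.interp(mid, prof0, x)
        assert shift == pytest.approx(2.0 / iso, abs=0.05)

    def test_geometry_invariants(self):
        spec = SyntheticImageSpec(frame_shape=(128, 1280), detector_size_cm=43.0,
                                  sid_cm=160.0)
        assert spec.detector_pitch_mm == pytest.approx(430.0 / 1280)
        assert spec.isocenter_pixel_mm == pytest.approx(430.0 / 1280 * 100 / 160)

    def test_metadata_propagates_to_stack(self):
        spec = SyntheticImageSpec(sid_cm=150.0)
        stack = render_frames(spec, np.zeros(3), patient_id=7, fraction=2)
        assert stack.sid_cm == 150.0
        assert stack.detector_pitch_mm == pytest.approx(spec.detector_pitch_mm)
        assert stack.patient_id == 7 and stack.fraction == 2
        r0, r1, c0, c1 = stack.roi
        assert 0 <= r0 < r1 <= stack.frames.shape[1]
        assert 0 <= c0 < c1 <= stack.frames.shape[2]

    def test_render_is_seed_reproducible(self):
        spec = SyntheticImageSpec()
        a = render_frames(spec, [0.0, 1.0], seed=4)
        b = render_frames(spec, [0.0, 1.0], seed=4)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticImageSpec(frame_shape=(0, 10))
        with pytest.raises(ValueError):
            render_frames(SyntheticImageSpec(), [np.nan])
        with pytest.raises(ValueError):
            render_frames(SyntheticImageSpec(), [])
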