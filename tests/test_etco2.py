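"""End-tidal extraction, regressor construction, delta-EtCO2 and QC tests.

Detection correctness is checked against exhaustive windowed-maximum
oracles; normalization against hand arithmetic and its scale/offset
algebra; delta-EtCO2 against hand-computed block means.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvrpipe import (
    AcquisitionSpec,
    BreathModel,
    CapnoTrace,
    EtCO2Series,
    ParadigmSpec,
    build_regressor,
    compute_delta_etco2,
    extract_end_tidal,
    normalize_etco2,
    qc_trace,
    simulate_capnometry,
)


def triangular_trace(n_breaths=3, peak=40.0, fs=10.0, period=4.0):
    """Triangular breaths 0 -> peak -> 0."""
    t = np.arange(int(n_breaths * period * fs)) / fs
    phase = (t % period) / period
    values = peak * (1 - np.abs(2 * phase - 1))
    return CapnoTrace(sampling_rate=fs, values=values)


class TestExtractEndTidal:
    def test_triangular_breaths_all_plateaus_found(self):
        trace = triangular_trace()
        et = extract_end_tidal(trace, min_breath_period=2.0, baseline_window=(0, 12))
        assert et.n_breaths == 3
        assert np.allclose(et.etco2_values, 40.0)

    def test_matches_generator_ground_truth_step_case(self, paradigm, step_capno):
        trace, truth = step_capno
        et = extract_end_tidal(trace)
        assert et.n_breaths == truth.n_breaths
        assert np.array_equal(et.etco2_values, truth.etco2_values)

    def test_matches_exhaustive_windowed_maximum(self, paradigm):
        """Oracle: brute-force maximum within each breath window."""
        breath = BreathModel(breathing_rate=15.0, plateau_jitter_sd=0.3)
        trace, truth = simulate_capnometry(paradigm, breath, seed=13)
        et = extract_end_tidal(trace)
        period = breath.breath_period
        assert et.n_breaths == truth.n_breaths
        for k in range(truth.n_breaths):
            sel = (trace.times >= k * period) & (trace.times < (k + 1) * period)
            oracle = trace.values[sel].max()
            assert et.etco2_values[k] == pytest.approx(oracle, abs=1e-12)

    def test_constant_trace_errors(self):
        trace = CapnoTrace(sampling_rate=10.0, values=np.full(100, 40.0))
        with pytest.raises(ValueError, match="no breaths"):
            extract_end_tidal(trace, baseline_window=(0, 10))

    def test_negative_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            CapnoTrace(sampling_rate=-1.0, values=np.array([1.0, 2.0]))


class TestBuildRegressor:
    def test_constant_series_gives_constant_interpolant_and_zero_delay(self):
        et = EtCO2Series(
            breath_times=np.arange(0.0, 360.0, 5.0) + 2.5,
            etco2_values=np.full(72, 40.0),
            baseline_window=(0, 60),
        )
        reg = build_regressor(et, AcquisitionSpec(n_volumes=178))
        assert np.allclose(reg.raw_values, 40.0)
        assert reg.bulk_delay == 0.0
        assert np.allclose(reg.normalized_values, 0.0)

    def test_hand_linear_interpolation(self):
        et = EtCO2Series(
            breath_times=np.array([0.0, 10.0]),
            etco2_values=np.array([40.0, 48.0]),
            baseline_window=(0, 5),
        )
        reg = build_regressor(et, AcquisitionSpec(repetition_time=2.0, n_volumes=2))
        assert reg.raw_values[1] == pytest.approx(41.6, abs=1e-12)

    def test_cross_correlation_recovers_planted_delay(self, step_capno, acq, paradigm):
        from cvrpipe.cvr import BoldSeries

        _, truth = step_capno
        t = acq.sample_times
        shifted = np.interp(t - 6.0, truth.breath_times, truth.etco2_values)
        bold = BoldSeries(sample_times=t, values=shifted, units="raw")
        reg = build_regressor(
            truth, acq, paradigm=paradigm, bold_for_alignment=bold, delay_step=1.0
        )
        assert reg.bulk_delay == 6.0

    def test_acquisition_beyond_support_errors(self):
        et = EtCO2Series(
            breath_times=np.array([0.0, 10.0, 20.0]),
            etco2_values=np.array([40.0, 41.0, 42.0]),
            baseline_window=(0, 20),
        )
        with pytest.raises(ValueError, match="acquisition window"):
            build_regressor(et, AcquisitionSpec(repetition_time=2.0, n_volumes=100))


class TestNormalize:
    def test_constant_series_maps_to_zero(self):
        out = normalize_etco2(np.full(5, 40.0), np.arange(5.0), (0, 2))
        assert np.allclose(out, 0.0)

    def test_hand_arithmetic(self):
        out = normalize_etco2(
            np.array([40.0, 40.0, 48.0, 48.0]), np.arange(4.0), (0, 1)
        )
        assert np.allclose(out, [0.0, 0.0, 8 / 48, 8 / 48])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        x = np.array([40.0, 39.0, 48.0, 47.0, 41.0])
        t = np.arange(5.0)
        base = normalize_etco2(x, t, (0, 1))
        scaled = normalize_etco2(scale * x, t, (0, 1))
        assert np.allclose(base, scaled, atol=1e-12)

    def test_offset_equivariance(self):
        """Adding c mmHg shifts the output by -c/max plus a max change:
        with the divisor held fixed, the shift is exactly c-cancelling."""
        x = np.array([40.0, 39.0, 48.0, 47.0, 41.0])
        t = np.arange(5.0)
        c = 5.0
        base = normalize_etco2(x, t, (0, 1), divisor=48.0)
        shifted = normalize_etco2(x + c, t, (0, 1), divisor=48.0)
        assert np.allclose(base, shifted, atol=1e-12)

    def test_zero_maximum_errors(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_etco2(np.zeros(4), np.arange(4.0), (0, 1))


def series_from_blocks(baseline=40.0, block_values=(48.0, 48.0), paradigm=None):
    """Breaths every 2.5 s; constant values per block."""
    paradigm = paradigm or ParadigmSpec()
    times, values = [], []
    for gas, start, end in paradigm.intervals():
        bt = np.arange(start + 1.25, end, 2.5)
        times.append(bt)
        values.append(np.full(bt.size, baseline))
    times = np.concatenate(times)
    values = np.concatenate(values)
    for (s, e), v in zip(paradigm.co2_intervals(), block_values):
        sel = (times >= s) & (times < e)
        values[sel] = v
    return EtCO2Series(breath_times=times, etco2_values=values, baseline_window=paradigm.baseline_window)


class TestDeltaEtCO2:
    def test_step_series_recovers_boost(self, paradigm):
        et = series_from_blocks(40.0, (48.0, 48.0))
        assert compute_delta_etco2(et, paradigm) == pytest.approx(8.0, abs=1e-12)

    def test_two_block_means_average(self, paradigm):
        et = series_from_blocks(40.0, (48.0, 50.0))
        assert compute_delta_etco2(et, paradigm) == pytest.approx(9.0, abs=1e-12)

    def test_within_block_linear_ramp(self, paradigm):
        """Ramp 44 -> 48 over each 75-s block; breaths symmetric about the
        second-half midpoint give a second-half mean of exactly 47."""
        times, values = [np.arange(1.25, 60, 2.5)], [np.full(24, 40.0)]
        for start, end in paradigm.co2_intervals():
            mid = 0.5 * (start + end)
            first = np.array([start + 10.0, start + 25.0])
            # symmetric pairs about 0.75 of the block
            second = np.array([mid + 2.5, end - 2.5, mid + 12.5, end - 12.5])
            bt = np.sort(np.concatenate([first, second]))
            times.append(bt)
            values.append(44.0 + 4.0 * (bt - start) / (end - start))
        air_tail = [np.arange(s + 1.25, e, 2.5) for s, e in
                    ParadigmSpec().air_intervals_after_co2()]
        for bt in air_tail:
            times.append(bt)
            values.append(np.full(bt.size, 40.0))
        order = np.argsort(np.concatenate(times))
        et = EtCO2Series(
            breath_times=np.concatenate(times)[order],
            etco2_values=np.concatenate(values)[order],
            baseline_window=paradigm.baseline_window,
        )
        assert compute_delta_etco2(et, paradigm) == pytest.approx(7.0, abs=1e-12)

    def test_empty_window_names_block(self, paradigm):
        et = EtCO2Series(
            breath_times=np.arange(1.25, 100, 2.5),
            etco2_values=np.full(40, 40.0),
            baseline_window=(0, 60),
        )
        with pytest.raises(ValueError, match="CO2 block 2"):
            compute_delta_etco2(et, paradigm)

    def test_generator_bias_vanishes_with_time_constant(self, paradigm):
        deltas = []
        for tau in (8.0, 2.0, 0.0):
            _, truth = simulate_capnometry(
                paradigm, BreathModel(transition_time_constant=tau), seed=2
            )
            deltas.append(compute_delta_etco2(truth, paradigm))
        biases = [8.0 - d for d in deltas]
        assert biases[0] > biases[1] > biases[2]
        assert biases[-1] == pytest.approx(0.0, abs=1e-12)


class TestQC:
    def test_step_trace_passes_all_flags(self, paradigm, step_et):
        report = qc_trace(step_et, paradigm)
        assert report.overall_pass
        assert all(report.steady_state_ok) and all(report.baseline_return_ok)
        assert np.allclose(report.steady_state_slopes, 0.0, atol=1e-12)

    def test_baseline_shift_fails_return_check(self, paradigm):
        et = series_from_blocks(40.0, (48.0, 48.0))
        values = et.etco2_values.copy()
        for s, e in paradigm.air_intervals_after_co2():
            sel = (et.breath_times >= s) & (et.breath_times < e)
            values[sel] = 43.0
        # keep the initial baseline at 40
        sel0 = et.breath_times < 60
        values[sel0] = 40.0
        shifted = EtCO2Series(et.breath_times, values, baseline_window=(0, 60))
        report = qc_trace(shifted, paradigm, baseline_tolerance=2.0)
        assert not any(report.baseline_return_ok)
        assert np.allclose(report.baseline_deviations, 3.0, atol=1e-12)
        assert not report.overall_pass

    def test_second_half_slope_fails_steady_state(self, paradigm):
        et = series_from_blocks(40.0, (48.0, 48.0))
        values = et.etco2_values.copy()
        for s, e in paradigm.co2_intervals():
            sel = et.breath_times > 0.5 * (s + e)
            sel &= et.breath_times <= e
            values[sel] += 0.05 * (et.breath_times[sel] - 0.5 * (s + e))
        drifting = EtCO2Series(et.breath_times, values, baseline_window=(0, 60))
        report = qc_trace(drifting, paradigm, slope_tolerance=0.02)
        assert not any(report.steady_state_ok)
        for slope in report.steady_state_slopes:
            assert slope == pytest.approx(0.05, abs=1e-9)

    def test_drifting_generator_trace_fails_qc(self, paradigm):
        trace, _ = simulate_capnometry(
            paradigm, BreathModel(baseline_drift=0.02), seed=4
        )
        et = extract_end_tidal(trace)
        report = qc_trace(et, paradigm)
        assert not report.overall_pass
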