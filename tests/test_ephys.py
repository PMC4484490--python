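"""Feature-extraction correctness against constructed waveforms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippophys.ephys import (
    QCRecord,
    ap_threshold,
    ap_waveform_features,
    detect_spikes,
    dvdt,
    extract_cell_features,
    find_rheobase,
    passive_features,
    qc_filter,
    train_features,
)
from hippophys.errors import (
    ClampModeError,
    DataError,
    RheobaseNotFoundError,
    ThresholdUndefinedError,
)
from hippophys.sweeps import StepStimulus, Sweep

from conftest import gaussian_bump_sweep


def _double_sweep(recording):
    res = find_rheobase(recording.sweeps)
    assert res.double_is_exact
    return res.double_amplitude_sweep


class TestDetectSpikes:
    def test_flat_trace_gives_no_spikes(self):
        sw = Sweep(np.full(2000, -70.0), sampling_rate=20.0)
        assert detect_spikes(sw).size == 0

    def test_two_bumps_detected_at_apices(self):
        sw = gaussian_bump_sweep([200.0, 300.0], peak_mv=20.0)
        times = detect_spikes(sw)
        assert times.size == 2
        np.testing.assert_allclose(times, [200.0, 300.0], atol=sw.dt)

    def test_simulated_ground_truth_recovered(self, nmr_recording):
        for sw, truth in zip(nmr_recording.sweeps, nmr_recording.spike_times):
            det = detect_spikes(sw)
            assert det.size == truth.size
            if truth.size:
                assert np.max(np.abs(det - truth)) <= sw.dt + 1e-12

    def test_voltage_clamp_sweep_rejected(self):
        sw = Sweep(np.zeros(100), sampling_rate=20.0, clamp_mode="voltage",
                   holding_potential=-80.0)
        with pytest.raises(ClampModeError):
            detect_spikes(sw)


class TestApThreshold:
    def test_piecewise_linear_slope_switch(self):
        """5 mV/ms rise switching to 20 mV/ms at -45 mV: threshold = -45 mV."""
        fs = 20.0  # kHz: 5 mV/ms = 0.25 mV/sample, 20 mV/ms = 1 mV/sample
        rise_slow = np.arange(-70.0, -45.0 + 1e-9, 5.0 / fs)
        rise_fast = np.arange(-45.0 + 20.0 / fs, 30.0, 20.0 / fs)
        down = np.linspace(rise_fast[-1], -70.0, 400)
        v = np.concatenate([np.full(200, -70.0), rise_slow, rise_fast, down])
        sw = Sweep(v, sampling_rate=fs)
        peak = detect_spikes(sw)[0]
        t_thr, v_thr = ap_threshold(sw, peak, criterion=10.0)
        assert v_thr == pytest.approx(-45.0, abs=5.0 / fs + 1e-9)

    def test_dvdt_at_threshold_brackets_criterion(self, nmr_recording):
        """The returned sample is the first of the rising run at/above the
        criterion, so dV/dt(threshold) >= 10 while the previous sample is
        below — one-sample discretization of the stated definition."""
        sw = _double_sweep(nmr_recording)
        deriv = dvdt(sw)
        for peak in detect_spikes(sw):
            t_thr, _ = ap_threshold(sw, peak, criterion=10.0)
            i = sw.time_to_index(t_thr)
            assert deriv[i] >= 10.0
            assert deriv[i - 1] < 10.0

    def test_slow_ramp_has_no_threshold(self):
        fs = 20.0
        t = np.arange(0, 500, 1 / fs)
        sw = Sweep(-70.0 + 0.1 * t, sampling_rate=fs)  # 0.1 mV/ms everywhere
        with pytest.raises(ThresholdUndefinedError):
            ap_threshold(sw, t[-1] / 2, criterion=10.0)


class TestApWaveform:
    def test_amplitude_and_ahp_are_simple_differences(self, nmr_recording):
        sw = _double_sweep(nmr_recording)
        tf = train_features(sw)
        for ap in tf.per_spike:
            assert ap.amplitude == pytest.approx(
                ap.peak_voltage - ap.threshold_voltage, abs=1e-12
            )
            if np.isfinite(ap.ahp_amplitude):
                assert ap.ahp_amplitude == pytest.approx(
                    ap.threshold_voltage - ap.ahp_minimum, abs=1e-12
                )
                assert ap.ahp_amplitude >= 0.0

    def test_brute_force_scan_oracle(self, nmr_recording):
        """Per-spike peak/AHP equal an exhaustive scan over the raw samples."""
        sw = _double_sweep(nmr_recording)
        v = sw.samples
        tf = train_features(sw)
        peaks = [ap.peak_time for ap in tf.per_spike]
        for k, ap in enumerate(tf.per_spike):
            i_pk = sw.time_to_index(ap.peak_time)
            assert ap.peak_voltage == v[i_pk]
            # AHP minimum: brute-force minimum between this peak and the
            # next spike's threshold (or the stimulus end for the last one)
            if k + 1 < len(tf.per_spike):
                j = sw.time_to_index(tf.per_spike[k + 1].threshold_time)
            else:
                j = sw.time_to_index(min(ap.peak_time + 100.0, sw.stimulus.offset))
            assert ap.ahp_minimum == pytest.approx(v[i_pk:j + 1].min(), abs=1e-12)
            assert ap.max_upstroke > 0 > ap.max_downstroke


class TestTrainFeatures:
    def _sweep_with_spikes(self, offsets_ms, onset=100.0, duration=750.0):
        stim = StepStimulus(onset, duration, 200.0)
        return gaussian_bump_sweep(
            [onset + o for o in offsets_ms], peak_mv=20.0, width_ms=0.8,
            duration_ms=1000.0, stimulus=stim,
        )

    def test_hand_computed_adaptation_ratio(self):
        # ISIs 50, 60, 80, 100 -> ((80+100)/2)/50 = 1.8
        tf = train_features(self._sweep_with_spikes([0.0, 50.0, 110.0, 190.0, 290.0]))
        assert tf.n_spikes == 5
        assert tf.adaptation_ratio == pytest.approx(1.8, rel=1e-3)

    def test_constant_isi_train_has_unit_ratio(self):
        tf = train_features(self._sweep_with_spikes(np.arange(0, 500, 100.0)))
        assert tf.adaptation_ratio == pytest.approx(1.0, rel=1e-3)

    def test_firing_frequency_is_count_over_step(self):
        tf = train_features(self._sweep_with_spikes(np.linspace(10, 710, 9)))
        assert tf.n_spikes == 9
        assert tf.firing_frequency == pytest.approx(9 / 0.75)

    def test_too_few_spikes_leave_ratio_undefined(self):
        tf = train_features(self._sweep_with_spikes([100.0, 300.0, 500.0]))
        assert np.isnan(tf.adaptation_ratio)

    def test_spikes_outside_step_excluded(self):
        sw = self._sweep_with_spikes([-50.0, 100.0, 200.0, 900.0])
        tf = train_features(sw)
        assert tf.n_spikes == 2

    @given(scale=st.floats(min_value=0.25, max_value=2.5))
    @settings(max_examples=10, deadline=None)
    def test_adaptation_ratio_invariant_under_time_rescaling(self, scale):
        # the rescaled train must stay inside the 750 ms step
        base = np.array([0.0, 50.0, 110.0, 190.0, 290.0])
        tf1 = train_features(self._sweep_with_spikes(base))
        tf2 = train_features(
            self._sweep_with_spikes(base * scale, duration=750.0)
        )
        assert tf2.adaptation_ratio == pytest.approx(tf1.adaptation_ratio, rel=0.02)


class TestRheobase:
    def test_constructed_family(self):
        sweeps = []
        for amp in (25.0, 50.0, 75.0, 100.0):
            spikes = [300.0] if amp >= 75.0 else []
            sweeps.append(
                gaussian_bump_sweep(spikes, stimulus=StepStimulus(100.0, 750.0, amp))
            )
        res = find_rheobase(sweeps)
        assert res.rheobase == 75.0
        assert not res.double_is_exact  # 150 pA absent from the protocol

    def test_all_subthreshold_raises(self):
        sweeps = [
            gaussian_bump_sweep([], stimulus=StepStimulus(100.0, 750.0, amp))
            for amp in (25.0, 50.0)
        ]
        with pytest.raises(RheobaseNotFoundError):
            find_rheobase(sweeps)

    def test_simulated_double_amplitude_is_exact(self, nmr_recording):
        res = find_rheobase(nmr_recording.sweeps)
        assert res.double_is_exact
        assert res.double_amplitude_sweep.stimulus.amplitude == 2 * res.rheobase


class TestPassive:
    def _hyper_sweep(self, amp_pa, rin_mohm=100.0, tau_ms=20.0, fs=20.0):
        stim = StepStimulus(100.0, 500.0, amp_pa)
        t = np.arange(0.0, 700.0, 1 / fs)
        dv = amp_pa * rin_mohm / 1000.0  # pA * MOhm -> mV
        v = np.full_like(t, -70.0)
        on = t >= stim.onset
        v[on] += dv * (1 - np.exp(-(t[on] - stim.onset) / tau_ms))
        off = t >= stim.offset
        v[off] = -70.0 + dv * np.exp(-(t[off] - stim.offset) / tau_ms)
        return Sweep(v, sampling_rate=fs, stimulus=stim)

    def test_single_step_ohms_law(self):
        pf = passive_features([self._hyper_sweep(-50.0)])
        assert pf.input_resistance == pytest.approx(100.0, rel=0.01)
        assert pf.resting_potential == pytest.approx(-70.0, abs=1e-9)

    def test_two_step_slope_matches_single_step(self):
        pf = passive_features([self._hyper_sweep(-25.0), self._hyper_sweep(-50.0)])
        assert pf.input_resistance == pytest.approx(100.0, rel=0.01)

    def test_time_constant_recovered(self):
        pf = passive_features([self._hyper_sweep(-50.0, tau_ms=20.0)])
        assert pf.membrane_time_constant == pytest.approx(20.0, abs=0.5)

    def test_no_hyperpolarizing_steps_raises(self):
        with pytest.raises(DataError):
            passive_features(
                [gaussian_bump_sweep([], stimulus=StepStimulus(100.0, 500.0, 50.0))]
            )


class TestQC:
    @pytest.mark.parametrize(
        "series,retained,change",
        [
            ([10.0, 13.0], False, 30.0),
            ([10.0, 11.0], True, 10.0),
            ([10.0, 10.0, 10.0], True, 0.0),
            ([10.0, 12.0], True, 20.0),  # boundary: exactly 20% is kept
        ],
    )
    def test_partition_at_twenty_percent(self, series, retained, change):
        rec = qc_filter(QCRecord(cell_id="c", access_resistance_series=series))
        assert rec.retained is retained
        assert rec.max_fractional_change == pytest.approx(change)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(DataError):
            qc_filter(QCRecord(cell_id="c", access_resistance_series=[10.0, -1.0]))

    def test_single_measurement_rejected(self):
        with pytest.raises(DataError):
            qc_filter(QCRecord(cell_id="c", access_resistance_series=[10.0]))


class TestCellRollup:
    def test_feature_row_is_order_independent(self, nmr_recording):
        sweeps = list(nmr_recording.sweeps)
        row1 = extract_cell_features(sweeps)
        row2 = extract_cell_features(sweeps[::-1])
        for key in row1:
            np.testing.assert_allclose(row1[key], row2[key], equal_nan=True)

    def test_idempotent(self, nmr_recording):
        row1 = extract_cell_features(nmr_recording.sweeps)
        row2 = extract_cell_features(nmr_recording.sweeps)
        assert row1 == row2
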