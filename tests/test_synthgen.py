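"""Generator correctness: determinism, ground truth, and event statistics."""

import numpy as np
import pytest
from scipy import stats

from hippophys.ephys import detect_spikes
from hippophys.errors import ConfigError, EmptyMorphologyError
from hippophys.morphometry import summarize_morphology, write_swc
from hippophys.synthgen import (
    MorphoGenParams,
    NeuronPreset,
    StimulusProtocol,
    generate_morphology,
    get_preset,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from hippophys.synthgen.synaptic import SynapticParams


class TestCurrentClamp:
    def test_deterministic_for_fixed_seed(self):
        proto = StimulusProtocol(step_amplitudes=(100.0, 300.0), step_duration=200.0,
                                 post_step_duration=50.0)
        preset = get_preset("naked_mole_rat")
        a = simulate_current_clamp(preset, proto, seed=11)
        b = simulate_current_clamp(preset, proto, seed=11)
        for sa, sb in zip(a.sweeps, b.sweeps):
            np.testing.assert_array_equal(sa.samples, sb.samples)
        c = simulate_current_clamp(preset, proto, seed=12)
        assert not np.array_equal(a.sweeps[0].samples, c.sweeps[0].samples)

    def test_zero_amplitude_zero_noise_settles_at_leak_reversal(self):
        preset = get_preset("naked_mole_rat")
        quiet = NeuronPreset(
            name="quiet", membrane_capacitance=preset.membrane_capacitance,
            leak_conductance=preset.leak_conductance,
            leak_reversal=preset.leak_reversal,
            spike_channel_params=preset.spike_channel_params,
            adaptation_strength=preset.adaptation_strength, noise_sd=0.0,
        )
        proto = StimulusProtocol(step_amplitudes=(0.0,), step_duration=300.0,
                                 post_step_duration=50.0)
        rec = simulate_current_clamp(quiet, proto, seed=0)
        assert rec.spike_times[0].size == 0
        tail = rec.sweeps[0].samples[-100:]
        # rest sits near the leak reversal (small offset from the
        # subthreshold-activated conductances is expected)
        assert abs(np.mean(tail) - quiet.leak_reversal) < 3.0

    def test_ground_truth_spikes_lie_within_sweep(self, nmr_recording):
        for sw, st in zip(nmr_recording.sweeps, nmr_recording.spike_times):
            assert np.all((st >= 0) & (st <= sw.duration))

    def test_ground_truth_matches_detector_on_noise_free_traces(self, full_protocol):
        preset = get_preset("naked_mole_rat")
        noiseless = NeuronPreset(
            name="nf", membrane_capacitance=preset.membrane_capacitance,
            leak_conductance=preset.leak_conductance,
            leak_reversal=preset.leak_reversal,
            spike_channel_params=preset.spike_channel_params,
            adaptation_strength=preset.adaptation_strength, noise_sd=0.0,
        )
        rec = simulate_current_clamp(noiseless, full_protocol, seed=0)
        dt = 1.0 / full_protocol.sampling_rate
        for sw, st in zip(rec.sweeps, rec.spike_times):
            det = detect_spikes(sw)
            assert det.size == st.size
            if st.size:
                assert np.max(np.abs(det - st)) <= dt + 1e-12


class TestVoltageClamp:
    def test_zero_rates_flat_baseline(self):
        rec = simulate_voltage_clamp(-80.0, 0.0, 0.0, 1.0, seed=4,
                                     params=SynapticParams(noise_sd=0.0))
        assert rec.event_times.size == 0
        assert np.all(rec.sweeps[0].samples == rec.sweeps[0].samples[0])

    def test_excitatory_events_inward_below_reversal(self):
        rec = simulate_voltage_clamp(-80.0, 5.0, 0.0, 5.0, seed=7)
        assert rec.event_times.size > 0
        assert np.all(rec.event_amplitudes < 0)

    def test_event_count_is_the_seeded_poisson_draw(self):
        rate, dur, seed = 5.0, 10.0, 7
        rec = simulate_voltage_clamp(-80.0, rate, 0.0, dur, seed=seed)
        expected = np.random.default_rng(seed).poisson(rate * dur)
        assert rec.event_times.size == expected

    def test_holding_at_reversal_warns_and_zeroes_that_class(self):
        with pytest.warns(UserWarning, match="zero-amplitude"):
            rec = simulate_voltage_clamp(0.0, 5.0, 0.0, 2.0, seed=3)
        assert np.all(rec.event_amplitudes == 0.0)

    def test_event_counts_poisson_distributed_across_seeds(self):
        """Chi-square goodness of fit of counts to Poisson(rate*duration)."""
        rate, dur = 5.0, 2.0
        lam = rate * dur
        counts = np.array([
            simulate_voltage_clamp(
                -80.0, rate, 0.0, dur, seed=s, sampling_rate=2.0,
            ).event_times.size
            for s in range(250)
        ])
        edges = [0, 6, 8, 10, 12, 14, 100]
        obs = np.histogram(counts, bins=edges)[0]
        k = np.arange(0, 100)
        pmf = stats.poisson.pmf(k, lam)
        exp = np.array([pmf[(k >= lo) & (k < hi)].sum() for lo, hi in
                        zip(edges[:-1], edges[1:])]) * counts.size
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            simulate_voltage_clamp(-80.0, -1.0, 0.0, 1.0, seed=0)


class TestMorphologyGenerator:
    def test_unbranched_trunk_is_single_segment(self):
        params = MorphoGenParams(trunk_length_mean=100.0, branch_probability=0.0)
        gen = generate_morphology(params, seed=5)
        assert gen.n_segments == 1
        assert gen.total_length == pytest.approx(100.0, abs=1e-9)
        summ = summarize_morphology(gen.tree)
        assert summ.n_segments == 1
        assert summ.total_length == pytest.approx(100.0, abs=1e-6)

    def test_swc_byte_identical_for_fixed_seed(self, tmp_path):
        params = MorphoGenParams(n_stems=2)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(generate_morphology(params, seed=9).tree, p1)
        write_swc(generate_morphology(params, seed=9).tree, p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_summary_matches_generation_ground_truth(self, seed):
        gen = generate_morphology(MorphoGenParams(n_stems=2), seed=seed)
        summ = summarize_morphology(gen.tree)
        assert summ.n_segments == gen.n_segments
        assert summ.total_length == pytest.approx(gen.total_length, abs=1e-6)
        assert summ.maximal_length == pytest.approx(gen.maximal_length, abs=1e-6)
        assert summ.max_branch_order == gen.max_branch_order

    def test_degenerate_params_rejected(self):
        with pytest.raises((ConfigError, EmptyMorphologyError)):
            generate_morphology(
                MorphoGenParams(trunk_length_mean=0.0), seed=0
            )
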