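"""Preprocessing, Morlet theta power, time normalization and ERD/S."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dancedsp import (
    Epoch,
    FilterSpec,
    InvalidInputError,
    SignalStream,
    ThetaPower,
    artifact_removal_hook,
    average_reference,
    bandpass,
    baseline_power,
    erds_percent,
    erds_profile,
    morlet_theta_power,
    step_bins,
    time_normalize,
)

FS = 500.0


def _sine_stream(freq, amp=1.0, dur=20.0, n_ch=2):
    t = np.arange(int(dur * FS)) / FS
    sig = amp * np.sin(2 * np.pi * freq * t)
    return SignalStream(
        name="eeg",
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        fs_hz=FS,
        start_time_s=0.0,
        samples=np.tile(sig, (n_ch, 1)),
    )


def _mid_rms(x):
    n = x.shape[-1]
    return float(np.sqrt((x[..., n // 4 : 3 * n // 4] ** 2).mean()))


class TestBandpass:
    def test_passband_tone_preserved_within_1pct(self):
        s = _sine_stream(6.0)
        out = bandpass(s)
        assert _mid_rms(out.samples) == pytest.approx(_mid_rms(s.samples), rel=0.01)

    def test_50hz_attenuated_at_least_20db(self):
        s = _sine_stream(50.0)
        out = bandpass(s)
        assert _mid_rms(out.samples) <= 0.1 * _mid_rms(s.samples)

    def test_dc_rejected(self):
        s = _sine_stream(6.0)
        s.samples[:] = 3.0
        out = bandpass(s)
        assert np.abs(out.samples[:, 1000:-1000]).max() < 1e-3

    def test_sampling_rate_must_exceed_band(self):
        s = _sine_stream(6.0)
        s.fs_hz = 50.0
        with pytest.raises(InvalidInputError):
            bandpass(s)


class TestAverageReference:
    def test_antiphase_pair_unchanged(self):
        s = _sine_stream(6.0, n_ch=2)
        s.samples[1] *= -1
        out = average_reference(s)
        assert np.allclose(out.samples, s.samples)

    def test_common_offset_removed_and_columns_sum_to_zero(self):
        s = _sine_stream(6.0, n_ch=3)
        s.samples += 5.0
        out = average_reference(s)
        assert np.allclose(out.samples.sum(axis=0), 0.0, atol=1e-10)

    def test_single_channel_rejected(self):
        s = _sine_stream(6.0, n_ch=1)
        with pytest.raises(InvalidInputError):
            average_reference(s)


class TestArtifactHook:
    def test_none_is_identity(self):
        s = _sine_stream(6.0)
        assert artifact_removal_hook(s, "none") is s

    def test_injected_callable_applied(self):
        s = _sine_stream(6.0)

        def zero_first(stream):
            out = stream.copy_with(stream.samples.copy())
            out.samples[0] = 0.0
            return out

        out = artifact_removal_hook(s, zero_first)
        assert np.all(out.samples[0] == 0.0)
        assert not np.all(out.samples[1] == 0.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidInputError):
            artifact_removal_hook(_sine_stream(6.0), "infomax")


def _epoch(data, step_offsets, cue_offset=0.3, pad=0.1):
    return Epoch(
        trial_index=0,
        data=np.atleast_2d(data),
        fs_hz=FS,
        t0_s=0.0,
        cue_offset_s=cue_offset,
        step_offsets_s=list(step_offsets),
        pad_s=pad,
    )


class TestMorletThetaPower:
    def test_stationary_sinusoid_gives_flat_calibrated_power(self):
        t = np.arange(int(4.0 * FS)) / FS
        amp = 10.0
        ep = _epoch(amp * np.sin(2 * np.pi * 6.0 * t), np.arange(1, 7) * 0.6)
        tp = morlet_theta_power(ep)
        assert tp.power.std() / tp.power.mean() < 0.05
        # calibrated to physical units: band power of A*sin = A^2/2
        assert tp.power.mean() == pytest.approx(amp**2 / 2, rel=0.1)

    def test_amplitude_step_doubles_band_power(self):
        t = np.arange(int(6.0 * FS)) / FS
        sig = np.sin(2 * np.pi * 6.0 * t)
        half = len(sig) // 2
        sig[half:] *= np.sqrt(2)
        ep = _epoch(sig, np.arange(1, 7) * 0.9)
        tp = morlet_theta_power(ep)
        n = tp.power.shape[1]
        first = tp.power[0, n // 8 : 3 * n // 8].mean()
        second = tp.power[0, 5 * n // 8 : 7 * n // 8].mean()
        assert second / first == pytest.approx(2.0, rel=0.1)

    def test_zero_signal_zero_power(self):
        ep = _epoch(np.zeros(int(3 * FS)), np.arange(1, 7) * 0.4)
        tp = morlet_theta_power(ep)
        assert np.allclose(tp.power, 0.0)

    def test_trim_removes_padding_samples(self):
        ep = _epoch(np.random.default_rng(0).normal(size=int(3 * FS)),
                    np.arange(1, 7) * 0.4)
        trimmed = morlet_theta_power(ep, trim=True)
        full = morlet_theta_power(ep, trim=False)
        assert full.power.shape[1] - trimmed.power.shape[1] == 100

    def test_too_short_epoch_rejected(self):
        ep = _epoch(np.zeros(50), [0.05], cue_offset=0.02, pad=0.0)
        with pytest.raises(InvalidInputError):
            morlet_theta_power(ep)


class TestBaselinePower:
    def _theta(self, power):
        n = len(power)
        return ThetaPower(
            channel_labels=["c"],
            times_s=np.arange(n) / FS - 0.3,
            power=np.asarray(power, float)[None, :],
            fs_hz=FS,
        )

    def test_constant_power_recovered_exactly(self):
        tp = self._theta(np.full(1000, 4.2))
        assert baseline_power(tp)[0] == pytest.approx(4.2)

    def test_window_outside_epoch_rejected(self):
        tp = self._theta(np.full(1000, 4.2))
        with pytest.raises(InvalidInputError):
            baseline_power(tp, (-5.0, -4.8))

    def test_empty_window_rejected(self):
        tp = self._theta(np.full(1000, 4.2))
        with pytest.raises(InvalidInputError):
            baseline_power(tp, (0.0, 0.0))

    def test_simulated_baseline_power_within_10pct(self, tiny_session):
        from dancedsp import extract_sequence_epochs

        eps = extract_sequence_epochs(tiny_session.eeg, tiny_session.markers)
        amp = tiny_session.truth.baseline_theta_amp_uv
        vals = []
        for ep in eps:
            tp = morlet_theta_power(ep)
            vals.append(baseline_power(tp).mean())
        expected = amp**2 / 2 + 5.7  # oscillation + in-band pink-noise power
        assert np.mean(vals) == pytest.approx(expected, rel=0.10)


def _brute_force_global_bins(x, n_bins):
    """Independent oracle: explicit per-bin index windows, midpoint rule."""
    n = len(x)
    out = np.empty(n_bins)
    for b in range(n_bins):
        members = [
            j
            for j in range(n)
            if (b == 0 or (j + 0.5) * n_bins > b * n)
            and (j + 0.5) * n_bins <= (b + 1) * n
        ]
        if not members:
            center = (b + 0.5) * n / n_bins - 0.5
            members = [int(np.clip(np.floor(center + 0.5), 0, n - 1))]
        out[b] = np.mean([x[j] for j in members])
    return out


class TestTimeNormalize:
    def _series(self, n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n) ** 2
        t = np.arange(n) / FS
        return x, t

    def test_output_length_always_300(self):
        for n in (317, 1500, 2999):
            x, t = self._series(n)
            edges = np.linspace(0, t[-1], 7)
            edges[0] = 0.0
            out = time_normalize(x, t, edges, n_bins=300, mode="per_step")
            assert out.shape == (300,)
            out_g = time_normalize(x, t, edges, n_bins=300, mode="global")
            assert out_g.shape == (300,)

    def test_constant_series_maps_to_constant_bins(self):
        x = np.full(1234, 3.3)
        t = np.arange(1234) / FS
        out = time_normalize(x, t, [0.0, t[-1]], n_bins=300, mode="global")
        assert np.allclose(out, 3.3)

    def test_3000_samples_global_is_means_of_tens(self):
        x, t = self._series(3000, seed=1)
        out = time_normalize(x, t, [0.0, 6.0], n_bins=300, mode="global")
        expected = x.reshape(300, 10).mean(axis=1)
        assert np.allclose(out, expected)

    def test_global_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for n in rng.integers(300, 3001, size=25):
            x, t = self._series(int(n), seed=int(n))
            out = time_normalize(x, t, [0.0, n / FS], n_bins=300, mode="global")
            assert np.allclose(out, _brute_force_global_bins(x, 300)), n

    def test_mean_conserved_when_bins_divide_evenly(self):
        x, t = self._series(3000, seed=2)
        out = time_normalize(x, t, [0.0, 6.0], n_bins=300, mode="global")
        assert out.mean() == pytest.approx(x.mean())

    def test_per_step_requires_divisible_bins(self):
        x, t = self._series(700)
        edges = np.linspace(0, t[-1], 7)
        with pytest.raises(InvalidInputError):
            time_normalize(x, t, edges, n_bins=301, mode="per_step")

    def test_degenerate_segment_filled_with_warning(self):
        x, t = self._series(600)
        edges = [0.0, 0.5, 0.5001, 0.7, 0.8, 0.9, 1.0]
        with pytest.warns(UserWarning, match="shorter than one sample"):
            out = time_normalize(x, t, edges, n_bins=300, mode="per_step")
        assert out.shape == (300,)

    def test_multichannel_binning_matches_per_channel(self):
        x, t = self._series(1000, seed=3)
        stacked = np.vstack([x, 2 * x])
        edges = [0.0, 1.0, 2.0 - 0.5 / FS]
        out = time_normalize(stacked, t, edges, n_bins=300, mode="global")
        single = time_normalize(x, t, edges, n_bins=300, mode="global")
        assert np.allclose(out[0], single)
        assert np.allclose(out[1], 2 * single)


class TestStepBins:
    def test_constant_input(self):
        assert np.allclose(step_bins(np.full(300, 2.5)), np.full(6, 2.5))

    def test_bin_index_input_means(self):
        out = step_bins(np.arange(300.0))
        assert np.allclose(out, [24.5, 74.5, 124.5, 174.5, 224.5, 274.5])

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            step_bins(np.arange(299.0))


class TestErdsPercent:
    @pytest.mark.parametrize("pt,pb,expected", [(2, 1, 100.0), (1, 1, 0.0), (0.5, 1, -50.0)])
    def test_analytic_cases(self, pt, pb, expected):
        assert erds_percent(pt, pb) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidInputError):
            erds_percent(1.0, 0.0)

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, k, pt, pb):
        assert erds_percent(k * pt, k * pb) == pytest.approx(
            erds_percent(pt, pb), rel=1e-9, abs=1e-9
        )


class TestErdsProfile:
    def test_zero_modulation_profile_near_zero(self, base_pair, novel_pair):
        import warnings

        from dancedsp import SimParams, extract_sequence_epochs, schedule_session, simulate_session

        schedule = schedule_session(
            base_pair, novel_pair, n_training=1, n_test=0, seed=6,
            n_go_per_seq=2, n_nogo=0,
        )
        params = SimParams(
            n_channels=2, seed=13, pink_noise_sd_uv=0.0,
            erds_per_step_pct=(0.0,) * 6, rt_noise_sd_ms=0.0, error_prob=0.0,
            rt_asymptote_ms=600.0, rt_gain_ms=0.0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = simulate_session(schedule, params)
        eps = extract_sequence_epochs(sim.eeg, sim.markers)
        profiles = erds_profile(eps[0])
        assert len(profiles) == 2
        for p in profiles:
            assert len(p.erds_pct) == 6
            assert np.abs(p.erds_pct).max() < 5.0

    def test_five_segment_anchoring_supported(self):
        """First-step anchoring: 5 inter-step segments, 60 bins each."""
        x = np.arange(3000.0)
        t = np.arange(3000) / FS
        edges = np.linspace(0.5, 5.5, 6)  # step1..step6
        out = time_normalize(x, t, edges, n_bins=300, mode="per_step")
        assert out.shape == (300,)
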