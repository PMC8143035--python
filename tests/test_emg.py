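"""EMG conditioning, spike interpolation, and activation recovery."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wbvphysio.channels import SpectralEstimate, TimeSeriesChannel
from wbvphysio.config import CohortConfig
from wbvphysio.emg import (
    SpikeSpec,
    activation_summary,
    activation_table,
    bandpass_emg,
    emg_psd,
    extract_segments,
    interpolate_spikes,
    rms_from_psd,
    spike_intervals,
)
from wbvphysio.synthio import EmgRecord, artifact_lines, band_limited_noise, generate_emg

RATE = 1000.0


def make_channel(samples, rate=RATE):
    return TimeSeriesChannel(samples=samples, rate=rate, units="au", site="VL")


def sinusoid(freq, duration=4.0, amp=1.0, rate=RATE):
    t = np.arange(int(rate * duration)) / rate
    return make_channel(amp * np.sin(2 * np.pi * freq * t))


def enumerate_intervals_oracle(bases, half_width, f_max, band):
    """Independent enumeration + merge oracle for spike intervals."""
    centers = sorted(
        k * f0 for f0 in bases for k in range(1, int(f_max / f0) + 1) if k * f0 <= f_max
    )
    spans = [(max(c - half_width, band[0]), min(c + half_width, band[1])) for c in centers]
    merged = []
    for lo, hi in spans:
        if hi <= lo:
            continue
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


class TestBandpass:
    def test_passband_preserved(self):
        ch = sinusoid(100.0)
        assert bandpass_emg(ch).rms() == pytest.approx(ch.rms(), rel=0.02)

    def test_stopband_removed(self):
        # squared 8th-order response at 2 Hz (vs 10 Hz edge) is ~1e-14
        ch = sinusoid(2.0)
        assert bandpass_emg(ch).rms() < 0.05 * ch.rms()

    def test_dc_removed(self):
        ch = make_channel(np.full(4000, 3.0))
        assert abs(bandpass_emg(ch).samples.mean()) < 1e-6

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_emg(make_channel(np.zeros(4000), rate=800.0))


class TestExtractSegments:
    def _record(self, duration, onset):
        # samples equal to their index so slices are verifiable exactly
        n = int(RATE * duration)
        return EmgRecord(
            muscle="VL",
            channel=make_channel(np.arange(n, dtype=float)),
            vibration_onset=onset,
            mvic=[make_channel(np.zeros(5000))],
        )

    def test_vibration_segment_covers_60_to_70_s_after_onset(self):
        rec = self._record(duration=380.0, onset=300.0)
        segs = extract_segments(rec)
        vib = segs["vibration"]
        assert vib.n == 10_000
        assert vib.samples[0] == 360.0 * RATE
        assert vib.samples[-1] == 370.0 * RATE - 1
        base = segs["baseline"]
        assert base.n == 1000
        assert base.samples[-1] == 300.0 * RATE - 1

    def test_record_ending_too_early_rejected(self):
        rec = self._record(duration=365.0, onset=300.0)
        with pytest.raises(ValueError, match="vibration"):
            extract_segments(rec)

    def test_shifted_onset_shifts_segment(self):
        rec = self._record(duration=100.0, onset=10.0)
        segs = extract_segments(rec)
        assert segs["vibration"].samples[0] == 70.0 * RATE

    def test_missing_baseline_rejected(self):
        rec = self._record(duration=80.0, onset=0.5)
        with pytest.raises(ValueError, match="baseline"):
            extract_segments(rec)


class TestSpikeIntervals:
    def test_line_counts_match_enumeration_oracle(self):
        spec = SpikeSpec()
        counts = {
            f0: len([k for k in range(1, 100) if k * f0 <= spec.f_max])
            for f0 in spec.base_frequencies
        }
        assert counts == {15.0: 26, 25.0: 16, 60.0: 6}
        oracle = enumerate_intervals_oracle((15, 25, 60), 2.0, 400.0, (10.0, 400.0))
        got = spike_intervals(spec)
        assert got == pytest.approx(oracle)

    def test_coincident_harmonics_merge_without_duplicates(self):
        got = spike_intervals(SpikeSpec(base_frequencies=(15.0, 60.0)))
        los = [lo for lo, _ in got]
        assert len(los) == len(set(los))
        covering_60 = [iv for iv in got if iv[0] <= 60 <= iv[1]]
        assert len(covering_60) == 1

    def test_touching_intervals_from_two_bases_merge(self):
        got = spike_intervals(SpikeSpec(base_frequencies=(15.0, 25.0), f_max=80.0))
        covering_75 = [iv for iv in got if iv[0] <= 75 <= iv[1]]
        assert covering_75 == [(73.0, 77.0)]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SpikeSpec(half_width=0)
        with pytest.raises(ValueError):
            SpikeSpec(f_max=500.0)

    @given(st.floats(min_value=11, max_value=90), st.floats(min_value=0.5, max_value=5))
    def test_intervals_sorted_disjoint_within_band(self, f0, w):
        got = spike_intervals(SpikeSpec(base_frequencies=(f0,), half_width=w))
        for (lo1, hi1), (lo2, hi2) in zip(got, got[1:]):
            assert hi1 < lo2
        for lo, hi in got:
            assert 10.0 <= lo < hi <= 400.0


class TestInterpolateSpikes:
    def _flat_psd(self, level=2.0):
        f = np.arange(0, 501, 1.0)
        return SpectralEstimate(f, np.full(f.size, level), 1.0, 10)

    def test_flat_psd_with_delta_spikes_restored_exactly(self):
        psd = self._flat_psd(2.0)
        intervals = spike_intervals(SpikeSpec())
        spiked = psd.copy()
        for lo, hi in intervals:
            inside = (psd.frequencies >= lo) & (psd.frequencies <= hi)
            spiked.psd[inside] += 50.0
        out = interpolate_spikes(spiked, intervals)
        np.testing.assert_array_equal(out.psd, psd.psd)

    def test_idempotent_on_spike_free_linear_psd(self):
        f = np.arange(0, 501, 1.0)
        psd = SpectralEstimate(f, 1.0 + 0.01 * f, 1.0, 10)
        out = interpolate_spikes(psd, spike_intervals(SpikeSpec()))
        np.testing.assert_allclose(out.psd, psd.psd, rtol=1e-12)

    def test_bins_outside_intervals_bit_identical(self, rng):
        f = np.arange(0, 501, 1.0)
        psd = SpectralEstimate(f, rng.random(f.size), 1.0, 10)
        intervals = spike_intervals(SpikeSpec())
        out = interpolate_spikes(psd, intervals)
        outside = np.ones(f.size, bool)
        for lo, hi in intervals:
            outside &= ~((f >= lo) & (f <= hi))
        np.testing.assert_array_equal(out.psd[outside], psd.psd[outside])
        np.testing.assert_array_equal(psd.frequencies, out.frequencies)

    def test_edge_interval_constant_extension_logged(self, caplog):
        f = np.arange(0, 11, 1.0)
        psd = SpectralEstimate(f, np.ones(f.size), 1.0, 1)
        with caplog.at_level("WARNING"):
            out = interpolate_spikes(psd, [(9.0, 10.0)])
        assert any("edge" in r.message for r in caplog.records)
        np.testing.assert_allclose(out.psd, 1.0)


class TestRmsFromPsd:
    def test_sinusoid(self):
        est = emg_psd(bandpass_emg(sinusoid(100.0, duration=10.0, amp=2.0)))
        assert rms_from_psd(est) == pytest.approx(2.0 / np.sqrt(2), rel=0.02)

    def test_white_noise_band_fraction(self, rng):
        x = make_channel(rng.standard_normal(20_000))
        est = emg_psd(x)
        # [10, 400] band carries 390/500 of white-noise power
        expected = np.sqrt(390.0 / 500.0)
        assert rms_from_psd(est) == pytest.approx(expected, rel=0.03)

    def test_matches_time_domain_rms_of_bandpassed_signal(self, rng):
        x = band_limited_noise(20_000, RATE, rng) * 0.7
        filtered = bandpass_emg(make_channel(x))
        est = emg_psd(filtered)
        assert rms_from_psd(est) == pytest.approx(filtered.rms(), rel=0.03)

    def test_empty_band_rejected(self):
        est = emg_psd(make_channel(np.random.default_rng(0).standard_normal(4000)))
        with pytest.raises(ValueError, match="band"):
            rms_from_psd(est, band=(600.0, 700.0))


def _synthetic_record(
    config, vibration_rms=0.3, mvic_rms=1.0, baseline_rms=0.1, artifact_ratio=0.0
):
    params = {
        "VL": {
            "baseline_rms": baseline_rms,
            "vibration_rms": vibration_rms,
            "mvic_rms": mvic_rms,
            "artifact": artifact_lines(total_rms=artifact_ratio * vibration_rms),
        }
    }
    subs, gt = generate_emg(config, params, subject_cv=0.0, condition_cv=0.0)
    return subs[0]["VL"], gt["S01"]["VL"]


class TestActivationSummary:
    def test_vibration_equal_to_mvic_with_unit_bias_gives_100_pct(self, small_config):
        rec, _ = _synthetic_record(small_config, vibration_rms=1.0, mvic_rms=1.0)
        res = activation_summary(rec, SpikeSpec(base_frequencies=()))
        assert res.bias == 1.0  # no intervals: filtered == unfiltered exactly
        assert res.pct_mvic_vibration == pytest.approx(100.0, rel=0.04)

    def test_artifact_free_bias_is_retention_ratio(self, small_config):
        rec, _ = _synthetic_record(small_config)
        res = activation_summary(rec)
        # without artifacts the interpolation only planes off spectral noise
        assert 0.9 < res.bias <= 1.05
        assert res.rms_vibration / res.bias == pytest.approx(res.rms_vibration, rel=0.1)

    def test_ground_truth_pct_recovery_at_30(self, small_config):
        rec, gt = _synthetic_record(small_config, artifact_ratio=1.5)
        res = activation_summary(rec)
        assert gt["pct_mvic_vibration"] == pytest.approx(30.0)
        assert res.pct_mvic_vibration == pytest.approx(30.0, abs=2.0)

    def test_spike_removal_recovers_physiological_rms(self, small_config):
        """Artifact spikes at 2x physiological RMS inflate raw power 5x; the
        interpolation must bring RMS back within 3% of truth."""
        rec, gt = _synthetic_record(small_config, artifact_ratio=2.0)
        segs = extract_segments(rec)
        est = emg_psd(bandpass_emg(segs["vibration"]))
        clean = interpolate_spikes(est, spike_intervals(SpikeSpec()))
        assert rms_from_psd(clean) == pytest.approx(gt["vibration_rms"], rel=0.03)

    def test_scaling_invariance_of_pct_mvic(self, small_config):
        rec, _ = _synthetic_record(small_config, artifact_ratio=1.0)
        k = 7.3
        scaled = EmgRecord(
            muscle=rec.muscle,
            channel=rec.channel.replace(k * rec.channel.samples),
            vibration_onset=rec.vibration_onset,
            mvic=[m.replace(k * m.samples) for m in rec.mvic],
        )
        a, b = activation_summary(rec), activation_summary(scaled)
        assert b.pct_mvic_vibration == pytest.approx(a.pct_mvic_vibration, rel=1e-9)
        assert b.pct_mvic_baseline == pytest.approx(a.pct_mvic_baseline, rel=1e-9)

    def test_zero_mvic_rejected(self, small_config):
        rec, _ = _synthetic_record(small_config, mvic_rms=0.0, vibration_rms=0.1)
        with pytest.raises(ValueError, match="MVIC"):
            activation_summary(rec)

    def test_artifact_sweep_recovery_stays_within_5pct(self, small_config):
        """Recovered physiological RMS error <= 5% for artifact RMS from 0 to
        10x physiological (power 0-100x)."""
        errors = []
        for ratio in (0.0, 1.0, 3.0, 10.0):
            rec, gt = _synthetic_record(small_config, artifact_ratio=ratio)
            segs = extract_segments(rec)
            est = emg_psd(bandpass_emg(segs["vibration"]))
            clean = interpolate_spikes(est, spike_intervals(SpikeSpec()))
            errors.append(abs(rms_from_psd(clean) - gt["vibration_rms"]) / gt["vibration_rms"])
        assert max(errors) <= 0.05

    def test_distal_vs_proximal_ordering_recovered(self, small_config):
        """Generator parameters with larger distal ratios must reproduce the
        distal > proximal activation-increase ordering in the output table."""
        params = {
            m: {
                "baseline_rms": 0.05,
                "vibration_rms": 0.05 * mult,
                "mvic_rms": 1.0,
                "artifact": artifact_lines(total_rms=0.05),
            }
            for m, mult in (("SO", 1.6), ("TA", 1.5), ("RF", 1.05), ("ST", 1.0))
        }
        subs, _ = generate_emg(small_config, params, subject_cv=0.0, condition_cv=0.0)
        table = activation_table(subs, ["S01", "S02", "S03"])
        inc = (
            table.assign(ratio=table["vibration"] / table["baseline"])
            .groupby("variable")["ratio"]
            .mean()
        )
        assert min(inc["SO"], inc["TA"]) > max(inc["RF"], inc["ST"])
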