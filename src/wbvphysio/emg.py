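"""Surface-EMG conditioning and vibration-artifact-corrected activation.

Raw vibration EMG is contaminated by sharp narrowband spikes at the
excitation frequencies (15, 25 Hz), the mains frequency (60 Hz) and their
harmonics. The correction operates in the PSD domain: bins within ±2 Hz of
every such line (up to 400 Hz) are replaced by the straight line joining
the nearest retained bins on either side, leaving the broadband
physiological spectrum untouched. RMS is then read directly off the
corrected density.

Because the interpolation also removes a sliver of genuine broadband power
under each line, a bias factor — the baseline (artifact-free) ratio of
spike-filtered to unfiltered RMS — rescales the vibration RMS before
normalization to the maximal voluntary contraction (MVIC) reference:

    bias = RMS_filtered(baseline) / RMS_unfiltered(baseline)
    %MVIC(vibration) = 100 · (RMS_vibration / bias) / RMS_MVIC
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .channels import ActivationResult, SpectralEstimate, TimeSeriesChannel
from .synthio import EmgRecord

log = logging.getLogger(__name__)

ANALYSIS_BAND = (10.0, 400.0)


@dataclass
class SpikeSpec:
    """Artifact line set: base frequencies whose harmonics up to ``f_max``
    are excised with a uniform ±``half_width`` Hz."""

    base_frequencies: tuple = (15.0, 25.0, 60.0)
    half_width: float = 2.0
    f_max: float = 400.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError(f"half_width must be positive, got {self.half_width}")
        if any(f <= 0 for f in self.base_frequencies):
            raise ValueError("every base frequency must be positive")
        if self.f_max > ANALYSIS_BAND[1]:
            raise ValueError(
                f"f_max {self.f_max} exceeds the analysis band upper edge {ANALYSIS_BAND[1]}"
            )


def bandpass_emg(
    channel: TimeSeriesChannel, band: tuple = ANALYSIS_BAND, order: int = 8
) -> TimeSeriesChannel:
    """Zero-phase 8th-order Butterworth band-pass (10–400 Hz)."""
    if channel.rate <= 2 * band[1]:
        raise ValueError(
            f"rate {channel.rate} Hz violates Nyquist for a {band[1]} Hz band edge "
            f"(need rate > {2 * band[1]} Hz)"
        )
    sos = _bandpass_sos(order, band[0], band[1], channel.rate)
    return channel.replace(signal.sosfiltfilt(sos, channel.samples))


@lru_cache(maxsize=32)
def _bandpass_sos(order: int, lo: float, hi: float, rate: float) -> np.ndarray:
    return signal.butter(order, (lo, hi), btype="bandpass", fs=rate, output="sos")


def extract_segments(
    record: EmgRecord,
    *,
    baseline_s: float = 1.0,
    vibration_offset_s: float = 60.0,
    vibration_s: float = 10.0,
) -> dict:
    """Analysis segments from one muscle's session record.

    Baseline: the ``baseline_s`` seconds immediately preceding vibration
    onset. Vibration: ``vibration_s`` seconds starting exactly
    ``vibration_offset_s`` after onset. MVIC trials pass through whole.
    Segments are contiguous sample slices; no resampling.
    """
    ch = record.channel
    rate = ch.rate
    onset_idx = int(round(record.vibration_onset * rate))
    b0 = onset_idx - int(round(baseline_s * rate))
    if b0 < 0:
        raise ValueError(
            f"record for {record.muscle} too short for the {baseline_s}-s baseline segment"
        )
    v0 = onset_idx + int(round(vibration_offset_s * rate))
    v1 = v0 + int(round(vibration_s * rate))
    if v1 > ch.n:
        raise ValueError(
            f"record for {record.muscle} ends at {ch.duration:.1f} s, before the vibration "
            f"segment [{record.vibration_onset + vibration_offset_s:.1f}, "
            f"{record.vibration_onset + vibration_offset_s + vibration_s:.1f}) s"
        )
    baseline = ch.replace(ch.samples[b0:onset_idx])
    baseline.condition = "baseline"
    vibration = ch.replace(ch.samples[v0:v1])
    vibration.condition = "vibration"
    return {"baseline": baseline, "vibration": vibration, "mvic": list(record.mvic)}


def spike_intervals(spec: SpikeSpec, band: tuple = ANALYSIS_BAND) -> list:
    """Merged, band-clipped frequency intervals around every harmonic line.

    For each base f0: [k·f0 − w, k·f0 + w] for all k ≥ 1 with k·f0 ≤ f_max.
    Overlapping or touching intervals merge; intervals are clipped to the
    analysis band.
    """
    raw = []
    for f0 in spec.base_frequencies:
        k = 1
        while k * f0 <= spec.f_max:
            raw.append((k * f0 - spec.half_width, k * f0 + spec.half_width))
            k += 1
    raw.sort()
    merged = []
    for lo, hi in raw:
        lo, hi = max(lo, band[0]), min(hi, band[1])
        if hi <= lo:
            continue
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def interpolate_spikes(psd: SpectralEstimate, intervals) -> SpectralEstimate:
    """Replace PSD bins inside each interval by a straight line between the
    nearest retained bins; all other bins are bit-identical to the input.

    An interval abutting the spectrum edge with no anchor bin on one side
    falls back to constant extension from the available anchor (logged).
    """
    out = psd.copy()
    f = out.frequencies
    # anchors must be bins retained by EVERY interval: two intervals closer
    # than one bin spacing would otherwise anchor on each other's spikes
    excised = np.zeros(f.size, dtype=bool)
    for lo, hi in intervals:
        excised |= (f >= lo) & (f <= hi)
    retained = np.flatnonzero(~excised)
    if retained.size == 0:
        raise ValueError("intervals excise every PSD bin; nothing to anchor on")
    for lo, hi in intervals:
        inside = np.flatnonzero((f >= lo) & (f <= hi))
        if inside.size == 0:
            continue
        below = retained[retained < inside[0]]
        above = retained[retained > inside[-1]]
        if below.size and above.size:
            i_lo, i_hi = below[-1], above[0]
            out.psd[inside] = np.interp(
                f[inside], [f[i_lo], f[i_hi]], [out.psd[i_lo], out.psd[i_hi]]
            )
        else:
            anchor = below[-1] if below.size else above[0]
            log.warning(
                "spike interval [%.1f, %.1f] Hz abuts the spectrum edge; "
                "constant extension from %.2f Hz",
                lo, hi, f[anchor],
            )
            out.psd[inside] = out.psd[anchor]
    out.psd = np.maximum(out.psd, 0.0)
    return out


def emg_psd(
    channel: TimeSeriesChannel, resolution: float = 1.0
) -> SpectralEstimate:
    """Welch PSD for EMG segments; a segment exactly one window long yields
    a single-window periodogram (the 1-s baseline case)."""
    from .accel import welch_psd

    return welch_psd(channel, resolution=resolution, min_segments=1)


def rms_from_psd(psd: SpectralEstimate, band: tuple = ANALYSIS_BAND) -> float:
    """RMS = sqrt(∫ psd df) over ``band`` (one-sided density convention)."""
    f = psd.frequencies
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} contains no PSD bins")
    return float(np.sqrt(np.sum(psd.psd[mask]) * psd.resolution))


def _segment_rms_pair(
    channel: TimeSeriesChannel,
    intervals,
    resolution: float,
    band: tuple,
) -> tuple:
    """(spike-filtered RMS, unfiltered RMS) for one band-passed segment."""
    filtered = bandpass_emg(channel, band=band)
    psd = emg_psd(filtered, resolution=resolution)
    clean = interpolate_spikes(psd, intervals)
    return rms_from_psd(clean, band=band), rms_from_psd(psd, band=band)


def activation_summary(
    record: EmgRecord,
    spec: SpikeSpec = None,
    *,
    resolution: float = 1.0,
    band: tuple = ANALYSIS_BAND,
    mvic_reduce: str = "max",
) -> ActivationResult:
    """Full activation pipeline for one muscle's record set.

    Order per segment: band-pass → Welch PSD → spike interpolation → RMS,
    applied identically to baseline, vibration, and MVIC segments. The
    bias factor comes from the baseline segment; the vibration RMS is
    divided by it before MVIC normalization. MVIC RMS reduces across the
    trials by ``"max"`` (standard practice) or ``"mean"``.
    """
    spec = spec or SpikeSpec()
    intervals = spike_intervals(spec, band=band)
    segs = extract_segments(record)

    base_filt, base_unfilt = _segment_rms_pair(segs["baseline"], intervals, resolution, band)
    vib_filt, _ = _segment_rms_pair(segs["vibration"], intervals, resolution, band)
    mvic_vals = [
        _segment_rms_pair(trial, intervals, resolution, band)[0] for trial in segs["mvic"]
    ]
    if not mvic_vals:
        raise ValueError(f"no MVIC trials for muscle {record.muscle}")
    rms_mvic = max(mvic_vals) if mvic_reduce == "max" else float(np.mean(mvic_vals))
    if rms_mvic == 0:
        raise ValueError(f"MVIC RMS is zero for {record.muscle}: normalization undefined")
    if base_unfilt == 0:
        raise ValueError(f"unfiltered baseline RMS is zero for {record.muscle}")
    bias = base_filt / base_unfilt
    if bias == 0:
        raise ValueError(f"bias is zero for {record.muscle}")
    return ActivationResult(
        muscle=record.muscle,
        rms_baseline_filtered=base_filt,
        rms_baseline_unfiltered=base_unfilt,
        rms_vibration=vib_filt,
        rms_mvic=rms_mvic,
        bias=bias,
        pct_mvic_baseline=100.0 * base_filt / rms_mvic,
        pct_mvic_vibration=100.0 * (vib_filt / bias) / rms_mvic,
    )


def activation_results(
    subject_records: list, subject_ids: list, spec: SpikeSpec = None, **kw
) -> list:
    """``(subject_id, ActivationResult)`` pairs for a whole cohort."""
    return [
        (sid, activation_summary(rec, spec, **kw))
        for sid, records in zip(subject_ids, subject_records)
        for rec in records.values()
    ]


def activation_table(subject_records: list, subject_ids: list, spec: SpikeSpec = None, **kw):
    """Long-format paired table (subject, variable, baseline, vibration) of
    %MVIC activation across a cohort, ready for the inference stage."""
    return paired_table_from_results(activation_results(subject_records, subject_ids, spec, **kw))


def paired_table_from_results(results: list):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject": sid,
                "variable": res.muscle,
                "baseline": res.pct_mvic_baseline,
                "vibration": res.pct_mvic_vibration,
            }
            for sid, res in results
        ]
    )


def details_table_from_results(results: list):
    """Per-subject, per-muscle table with every ActivationResult field."""
    import dataclasses

    import pandas as pd

    return pd.DataFrame(
        [{"subject": sid, **dataclasses.asdict(res)} for sid, res in results]
    )
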