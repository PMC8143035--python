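"""Accelerometry: preprocessing, segment RMS, and cross-spectral
transmissibility/coherence.

Tissue acceleration is related to actuator drive through the H1 estimator
H(f) = Gio(f)/Gii(f), with coherence γ²(f) = |Gio(f)|² / (Gii(f) Goo(f))
quantifying how much of the output is linearly explained by the input at
each frequency. Spectra are Welch estimates at 0.25 Hz resolution; the
windowing details (Hann, 50% overlap, per-segment mean removal) are field
defaults and configurable.

Zero-phase filtering applies the 6th-order low-pass design forward and
backward, so the effective magnitude response is 12th order.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

from .channels import CrossSpectralResult, SpectralEstimate, TimeSeriesChannel


@lru_cache(maxsize=32)
def _lowpass_sos(order: int, cutoff: float, rate: float) -> np.ndarray:
    return signal.butter(order, cutoff, btype="low", fs=rate, output="sos")


def preprocess_accel(
    channel: TimeSeriesChannel, cutoff_hz: float = 35.0, order: int = 6
) -> TimeSeriesChannel:
    """Linear detrend followed by zero-phase Butterworth low-pass at 35 Hz."""
    if channel.rate <= 2 * cutoff_hz:
        raise ValueError(
            f"rate {channel.rate} Hz violates Nyquist for a {cutoff_hz} Hz cutoff "
            f"(need rate > {2 * cutoff_hz} Hz)"
        )
    x = signal.detrend(channel.samples, type="linear")
    y = signal.sosfiltfilt(_lowpass_sos(order, cutoff_hz, channel.rate), x)
    return channel.replace(y)


def segment_rms(channel: TimeSeriesChannel, window_s: float = 4.0) -> dict:
    """RMS of consecutive non-overlapping windows plus their mean.

    Only full windows count; a trailing partial window is discarded.
    Returns ``{"per_segment": ndarray, "intra_mean": float}``.
    """
    w = int(round(window_s * channel.rate))
    if channel.n < w or w < 1:
        raise ValueError(
            f"channel of {channel.n} samples shorter than one {window_s}-s window ({w} samples)"
        )
    n_seg = channel.n // w
    segs = channel.samples[: n_seg * w].reshape(n_seg, w)
    per = np.sqrt(np.mean(segs**2, axis=1))
    return {"per_segment": per, "intra_mean": float(per.mean())}


def cohort_rms(intra_means) -> float:
    """Inter-subject mean of the per-subject intra-mean RMS values."""
    arr = np.asarray(intra_means, dtype=float)
    if arr.size == 0:
        raise ValueError("cohort_rms requires at least one subject")
    return float(arr.mean())


def _welch_params(channel: TimeSeriesChannel, resolution: float, min_segments: int) -> dict:
    nperseg = int(round(channel.rate / resolution))
    if nperseg < 2:
        raise ValueError(f"resolution {resolution} Hz too coarse for rate {channel.rate} Hz")
    if channel.n < min_segments * nperseg:
        raise ValueError(
            f"record of {channel.duration:.3f} s too short for {resolution} Hz resolution: "
            f"need at least {min_segments * nperseg / channel.rate:.3f} s "
            f"({min_segments} averaging segments of {nperseg} samples)"
        )
    return {
        "nperseg": nperseg,
        "noverlap": nperseg // 2,
        "window": "hann",
        "detrend": "constant",
        "scaling": "density",
    }


def _n_segments(n: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    return (n - nperseg) // step + 1


def welch_psd(
    channel: TimeSeriesChannel, resolution: float = 0.25, *, min_segments: int = 2
) -> SpectralEstimate:
    """One-sided Welch PSD with segment length = rate/resolution samples.

    Hann window, 50% overlap, per-segment mean removal. For stationary
    input the integral of the density over frequency matches the
    time-domain variance.
    """
    kw = _welch_params(channel, resolution, min_segments)
    f, pxx = signal.welch(channel.samples, fs=channel.rate, **kw)
    return SpectralEstimate(
        frequencies=f,
        psd=pxx,
        resolution=channel.rate / kw["nperseg"],
        n_segments=_n_segments(channel.n, kw["nperseg"], kw["noverlap"]),
    )


def cross_spectral(
    input_ch: TimeSeriesChannel,
    output_ch: TimeSeriesChannel,
    resolution: float = 0.25,
    *,
    gii_floor_ratio: float = 1e-12,
) -> CrossSpectralResult:
    """Transmissibility H = Gio/Gii and coherence with shared Welch settings.

    Bins where the input auto-spectrum falls below
    ``gii_floor_ratio * max(Gii)`` carry no usable input power and are
    flagged undefined instead of reported. Coherence is clipped to [0, 1]
    only against floating-point excursions (≤ 1e-9 by Cauchy–Schwarz).
    """
    if input_ch.rate != output_ch.rate:
        raise ValueError(
            f"rate mismatch: input {input_ch.rate} Hz vs output {output_ch.rate} Hz"
        )
    if input_ch.n != output_ch.n:
        raise ValueError(
            f"length mismatch: input {input_ch.n} vs output {output_ch.n} samples"
        )
    kw = _welch_params(input_ch, resolution, min_segments=2)
    f, gii = signal.welch(input_ch.samples, fs=input_ch.rate, **kw)
    _, goo = signal.welch(output_ch.samples, fs=input_ch.rate, **kw)
    _, gio = signal.csd(input_ch.samples, output_ch.samples, fs=input_ch.rate, **kw)

    defined = gii > gii_floor_ratio * gii.max()
    H = np.full(f.shape, np.nan + 0j, dtype=complex)
    H[defined] = gio[defined] / gii[defined]
    coh = np.full(f.shape, np.nan)
    denom = gii * goo
    ok = defined & (denom > 0)
    coh[ok] = np.abs(gio[ok]) ** 2 / denom[ok]
    excess = np.nanmax(coh[ok] - 1.0, initial=0.0)
    if excess > 1e-9:
        raise FloatingPointError(f"coherence exceeded 1 by {excess:.3e}")
    coh[ok] = np.clip(coh[ok], 0.0, 1.0)
    return CrossSpectralResult(
        frequencies=f,
        Gii=gii,
        Goo=goo,
        Gio=gio,
        H=H,
        coherence=coh,
        defined=ok,
        resolution=input_ch.rate / kw["nperseg"],
        n_segments=_n_segments(input_ch.n, kw["nperseg"], kw["noverlap"]),
    )
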