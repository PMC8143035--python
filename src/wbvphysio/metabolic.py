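"""Indirect-calorimetry summarization.

Breath-metabolic variables (VO2, VCO2, EE, VE, VT) arrive as slow,
mixing-chamber time series on a shared clock. Each episode is reduced to a
pre-vibration baseline mean and a moving-average peak over the vibration
bout: the mean of the best sustained window, which rejects short transients
in favour of a steady plateau estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import EpisodeSummary

METABOLIC_VARIABLES = ("VO2", "VCO2", "EE", "VE", "VT")

#: display units for the metabolic variables (EE unit is configurable metadata)
DEFAULT_UNITS = {
    "VO2": "mL/min",
    "VCO2": "mL/min",
    "EE": "kcal/min",
    "VE": "L/min",
    "VT": "L",
}


@dataclass
class MetabolicSeries:
    """Uniformly sampled metabolic variables sharing one time base."""

    time: np.ndarray
    data: dict
    rate: float
    vibration_onset: float
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        for k, v in self.data.items():
            if v.shape != self.time.shape:
                raise ValueError(f"variable {k} length does not match time base")
        if not (self.time[0] <= self.vibration_onset <= self.time[-1]):
            raise ValueError("vibration_onset falls outside the record")

    @property
    def variables(self) -> tuple:
        return tuple(self.data)

    def get(self, variable: str) -> np.ndarray:
        if variable not in self.data:
            raise KeyError(f"variable {variable!r} missing from series")
        return self.data[variable]


def baseline_mean(series: MetabolicSeries, variable: str, window_s: float = 180.0) -> float:
    """Mean over the final ``window_s`` seconds preceding vibration onset.

    At the default 0.1 Hz rate and 3-minute window this is the mean of
    exactly 18 samples.
    """
    values = series.get(variable)
    mask = (series.time >= series.vibration_onset - window_s) & (
        series.time < series.vibration_onset
    )
    n_needed = int(round(window_s * series.rate))
    if int(mask.sum()) < n_needed:
        raise ValueError(
            f"insufficient pre-onset data for {variable}: need {n_needed} samples "
            f"({window_s} s at {series.rate} Hz), found {int(mask.sum())}"
        )
    return float(values[mask].mean())


def moving_average_peak(
    series: MetabolicSeries,
    variable: str,
    window_s: float = 180.0,
    span_s: float = 600.0,
) -> dict:
    """Peak of the single-sample-stride moving average over the vibration span.

    Windows of ``window_s`` slide one sample at a time within
    ``[onset, onset + span_s)``; only full windows count, and ties go to the
    earliest window. Returns ``{"peak_mean", "window_start"}`` with
    ``window_start`` in seconds from record start.
    """
    values = series.get(variable)
    mask = (series.time >= series.vibration_onset) & (
        series.time < series.vibration_onset + span_s
    )
    seg = values[mask]
    seg_t = series.time[mask]
    w = int(round(window_s * series.rate))
    if seg.size < w or w < 1:
        raise ValueError(
            f"vibration epoch for {variable} shorter than one {window_s}-s window "
            f"({seg.size} samples < {w})"
        )
    # mean of every full window at single-sample stride; per-window sums
    # (not a running cumsum) so exact ties stay exact and resolve earliest
    means = np.lib.stride_tricks.sliding_window_view(seg, w).mean(axis=1)
    k = int(np.argmax(means))  # first maximum: earliest window
    return {"peak_mean": float(means[k]), "window_start": float(seg_t[k])}


def summarize_episode(
    series: MetabolicSeries,
    variables: tuple = METABOLIC_VARIABLES,
    baseline_window_s: float = 180.0,
    peak_window_s: float = 180.0,
    span_s: float = 600.0,
) -> list:
    """Baseline mean and moving-average peak for each metabolic variable."""
    out = []
    for var in variables:
        base = baseline_mean(series, var, window_s=baseline_window_s)
        peak = moving_average_peak(series, var, window_s=peak_window_s, span_s=span_s)
        pct = float("nan") if base == 0 else 100.0 * (peak["peak_mean"] - base) / base
        out.append(
            EpisodeSummary(
                variable=var,
                baseline_mean=base,
                vibration_peak_mean=peak["peak_mean"],
                pct_change=pct,
                peak_window_start=peak["window_start"],
            )
        )
    return out
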