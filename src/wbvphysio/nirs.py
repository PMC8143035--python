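"""Regional tissue-oxygenation (rSO2) summarization.

Near-infrared rSO2 is a slow percentage-valued series per muscle site.
The reduction mirrors the calorimetry stage at different defaults: a
1-minute pre-vibration baseline mean and a 1-minute moving-average peak
over the 10-minute vibration bout, computed independently per site.

Because "increased by x%" is ambiguous for a percent-valued quantity, each
site summary carries BOTH the absolute percentage-point delta and the
relative change as percent of baseline, labelled explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metabolic import MetabolicSeries, baseline_mean, moving_average_peak

NIRS_SITES = ("GL", "RF", "BB")


@dataclass
class OxySeries:
    """rSO2 percent series for several sites on one time base."""

    time: np.ndarray
    data: dict
    rate: float
    vibration_onset: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        for site, v in self.data.items():
            if np.any((v < 0) | (v > 100)):
                raise ValueError(f"rSO2 values for {site} outside [0, 100] %")

    @property
    def sites(self) -> tuple:
        return tuple(self.data)

    def get(self, site: str) -> np.ndarray:
        if site not in self.data:
            raise KeyError(f"site {site!r} missing from series")
        return self.data[site]

    def _as_metabolic(self) -> MetabolicSeries:
        # reuse the shared baseline/moving-average machinery
        return MetabolicSeries(
            time=self.time,
            data=self.data,
            rate=self.rate,
            vibration_onset=self.vibration_onset,
            units={site: "%" for site in self.data},
        )


def nirs_baseline_mean(series: OxySeries, site: str, window_s: float = 60.0) -> float:
    """Mean rSO2 over the final minute before vibration (15 samples at 0.25 Hz)."""
    return baseline_mean(series._as_metabolic(), site, window_s=window_s)


def nirs_peak(
    series: OxySeries, site: str, window_s: float = 60.0, span_s: float = 600.0
) -> dict:
    """Peak 1-minute moving average of rSO2 within the vibration span."""
    return moving_average_peak(series._as_metabolic(), site, window_s=window_s, span_s=span_s)


@dataclass
class OxySummary:
    site: str
    baseline_mean: float
    vibration_peak_mean: float
    delta_points: float       # absolute change, percentage points
    pct_of_baseline: float    # relative change, percent of baseline
    peak_window_start: float


def summarize_oxy(
    series: OxySeries,
    sites: tuple = None,
    baseline_window_s: float = 60.0,
    peak_window_s: float = 60.0,
    span_s: float = 600.0,
) -> list:
    """Per-site baseline, peak, and both flavours of change."""
    out = []
    for site in sites if sites is not None else series.sites:
        base = nirs_baseline_mean(series, site, window_s=baseline_window_s)
        peak = nirs_peak(series, site, window_s=peak_window_s, span_s=span_s)
        delta = peak["peak_mean"] - base
        out.append(
            OxySummary(
                site=site,
                baseline_mean=base,
                vibration_peak_mean=peak["peak_mean"],
                delta_points=float(delta),
                pct_of_baseline=float("nan") if base == 0 else float(100.0 * delta / base),
                peak_window_start=peak["window_start"],
            )
        )
    return out
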