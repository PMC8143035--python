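"""Core in-memory containers shared across the pipeline stages.

All signals are uniformly sampled; time is seconds from record start.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesChannel:
    """A uniformly sampled signal with its sampling rate and provenance labels.

    Parameters
    ----------
    samples : ndarray
        Signal values, one per sample.
    rate : float
        Sampling rate in Hz. Must be positive.
    units : str
        Physical units of the samples (e.g. ``"g"``, ``"uV"``).
    site : str
        Anatomical or actuator site label (e.g. ``"FTSH"``, ``"TA"``).
    axis : str
        Accelerometer axis (``"x"``/``"y"``/``"z"``) or empty for scalar channels.
    condition : str
        ``"baseline"``, ``"vibration"`` or ``"mvic"``.
    """

    samples: np.ndarray
    rate: float
    units: str = ""
    site: str = ""
    axis: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    def rms(self) -> float:
        """Time-domain root-mean-square of the samples."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def replace(self, samples: np.ndarray) -> "TimeSeriesChannel":
        """Copy of this channel with new samples, labels preserved."""
        return TimeSeriesChannel(
            samples=np.asarray(samples, dtype=float),
            rate=self.rate,
            units=self.units,
            site=self.site,
            axis=self.axis,
            condition=self.condition,
        )


@dataclass
class SpectralEstimate:
    """One-sided Welch power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray
    resolution: float
    n_segments: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.frequencies.shape != self.psd.shape:
            raise ValueError("frequencies and psd must have matching shapes")

    def copy(self) -> "SpectralEstimate":
        return SpectralEstimate(
            self.frequencies.copy(), self.psd.copy(), self.resolution, self.n_segments
        )


@dataclass
class CrossSpectralResult:
    """Cross-spectral analysis of an input/output channel pair.

    ``H = Gio / Gii`` is the H1 transmissibility estimator and
    ``coherence = |Gio|^2 / (Gii * Goo)``, both on the shared Welch grid.
    Bins where the input auto-spectrum falls below the configured floor are
    marked undefined in ``defined`` rather than reported.
    """

    frequencies: np.ndarray
    Gii: np.ndarray
    Goo: np.ndarray
    Gio: np.ndarray
    H: np.ndarray
    coherence: np.ndarray
    defined: np.ndarray
    resolution: float
    n_segments: int

    def magnitude_at(self, freq: float) -> float:
        """|H| at the defined bin nearest to ``freq``."""
        idx = np.flatnonzero(self.defined)
        if idx.size == 0:
            raise ValueError("no defined bins in cross-spectral result")
        k = idx[np.argmin(np.abs(self.frequencies[idx] - freq))]
        return float(np.abs(self.H[k]))

    def coherence_at(self, freq: float) -> float:
        idx = np.flatnonzero(self.defined)
        if idx.size == 0:
            raise ValueError("no defined bins in cross-spectral result")
        k = idx[np.argmin(np.abs(self.frequencies[idx] - freq))]
        return float(self.coherence[k])


@dataclass
class ActivationResult:
    """Per-muscle EMG activation summary across the three recording conditions.

    ``bias`` is the baseline ratio of spike-filtered to unfiltered RMS and
    compensates for broadband power removed along with the artifact lines;
    the vibration RMS is divided by it before normalization to MVIC.
    """

    muscle: str
    rms_baseline_filtered: float
    rms_baseline_unfiltered: float
    rms_vibration: float
    rms_mvic: float
    bias: float
    pct_mvic_baseline: float
    pct_mvic_vibration: float


@dataclass
class EpisodeSummary:
    """Baseline mean and vibration-epoch moving-average peak for one variable."""

    variable: str
    baseline_mean: float
    vibration_peak_mean: float
    pct_change: float
    peak_window_start: float


@dataclass
class MultivariateTestResult:
    """One-sample Hotelling T² on condition differences, reported Wilks-style."""

    family: str
    n_complete: int
    p_vars: int
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    variables: list = field(default_factory=list)


@dataclass
class PosthocRow:
    """Paired-t post-hoc for one variable with Bonferroni family correction."""

    variable: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    significant: bool
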