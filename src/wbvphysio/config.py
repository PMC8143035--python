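"""Cohort-level configuration for the synthetic study generator.

Defaults mirror the study protocol: triaxial accelerometry at 512 Hz,
surface EMG at 1 kHz, mixing-chamber calorimetry at 0.1 Hz, NIRS rSO2 at
0.25 Hz, a 5-minute supine baseline and a 10-minute vibration bout.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class CohortConfig:
    n_subjects: int = 19
    seed: int = 0
    accel_rate: float = 512.0
    emg_rate: float = 1000.0
    metabolic_rate: float = 0.1
    nirs_rate: float = 0.25
    vibration_duration: float = 600.0
    baseline_duration: float = 300.0
    # EMG sessions are recorded as trigger-aligned segments around the events
    # the analysis extracts, not over the full protocol timeline.
    emg_pre_onset: float = 5.0
    emg_post_onset: float = 75.0
    mvic_duration: float = 5.0
    # accelerometry record length during the vibration bout
    accel_duration: float = 600.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in ("accel_rate", "emg_rate", "metabolic_rate", "nirs_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "vibration_duration",
            "baseline_duration",
            "emg_pre_onset",
            "emg_post_onset",
            "mvic_duration",
            "accel_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)
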