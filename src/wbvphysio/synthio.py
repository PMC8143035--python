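"""Seeded generator of study-like inputs with recorded ground truth.

The generator emulates a supine multi-frequency whole-body-vibration
session: dual sinusoidal excitation at 25 Hz (feet actuators, 4.2 g_rms)
and 15 Hz (shoulder actuators, 0.7 g_rms) with distance-dependent
attenuation to tissue sites; broadband surface EMG carrying narrowband
motion-artifact lines at the excitation and mains frequencies and their
harmonics; and step-plus-drift metabolic and rSO2 responses with
between-subject variation. Every drawn parameter is recorded in a
``GroundTruth`` block so downstream stages can be tested for recovery.

Reproducibility: one global seed deterministically spawns per-subject,
per-modality substreams (``numpy`` ``SeedSequence`` spawn keys), so adding
a subject never perturbs the records of existing ones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .channels import TimeSeriesChannel
from .config import CohortConfig
from .metabolic import MetabolicSeries
from .nirs import OxySeries

log = logging.getLogger(__name__)

MUSCLES = ("SO", "TA", "GL", "VM", "VL", "RF", "ST", "DM")
ACCEL_SITES = ("FTSH", "SHSH", "TA", "RF", "BC")
SOURCE_SITES = ("FTSH", "SHSH")

#: actuator drive lines: site -> (frequency Hz, RMS amplitude in g)
EXCITATIONS = {"FTSH": (25.0, 4.2), "SHSH": (15.0, 0.7)}

#: vibration-direction axis per site: y along the foot chain, z along the
#: shoulder chain
SITE_AXIS = {"FTSH": "y", "TA": "y", "RF": "y", "SHSH": "z", "BC": "z"}

#: nominal tissue gains (gain at 15 Hz, gain at 25 Hz): transmissibility
#: attenuates with distance from each excitation source
DEFAULT_SITE_ATTENUATIONS = {
    "FTSH": (0.0, 1.0),
    "SHSH": (1.0, 0.0),
    "TA": (0.10, 0.60),
    "RF": (0.15, 0.30),
    "BC": (0.40, 0.08),
}

#: per-muscle resting activation (fraction of MVIC RMS) and vibration
#: multiplier; RF and ST are deliberately left at no effect
DEFAULT_MUSCLE_EFFECTS = {
    "SO": (0.030, 1.04),
    "TA": (0.030, 1.15),
    "GL": (0.030, 1.30),
    "VM": (0.025, 1.45),
    "VL": (0.025, 1.62),
    "RF": (0.025, 1.00),
    "ST": (0.025, 1.00),
    "DM": (0.020, 1.25),
}

#: metabolic step responses: baseline mean, relative plateau effect,
#: rise time constant (s), additive noise SD (series units)
DEFAULT_METABOLIC_RESPONSE = {
    "VO2": {"baseline_mean": 250.0, "plateau_mean": 305.75, "rise_time_constant": 45.0, "noise_sd": 10.0},
    "VCO2": {"baseline_mean": 210.0, "plateau_mean": 252.0, "rise_time_constant": 45.0, "noise_sd": 9.0},
    "EE": {"baseline_mean": 1.25, "plateau_mean": 1.5125, "rise_time_constant": 45.0, "noise_sd": 0.05},
    "VE": {"baseline_mean": 7.0, "plateau_mean": 8.26, "rise_time_constant": 30.0, "noise_sd": 0.35},
    "VT": {"baseline_mean": 0.50, "plateau_mean": 0.515, "rise_time_constant": 30.0, "noise_sd": 0.035},
}

#: rSO2 step responses per site (percent); plateau = baseline + delta
DEFAULT_NIRS_RESPONSE = {
    "GL": {"baseline_mean": 65.0, "plateau_mean": 69.5, "rise_time_constant": 60.0, "noise_sd": 0.8},
    "RF": {"baseline_mean": 63.0, "plateau_mean": 64.4, "rise_time_constant": 60.0, "noise_sd": 0.8},
    "BB": {"baseline_mean": 68.0, "plateau_mean": 70.5, "rise_time_constant": 60.0, "noise_sd": 0.8},
}

_MODALITY_KEY = {"params": 0, "accel": 1, "emg": 2, "metabolic": 3, "nirs": 4}


@dataclass
class GroundTruth:
    """Exact generator parameters, per subject, for recovery testing."""

    accel: dict = field(default_factory=dict)
    emg: dict = field(default_factory=dict)
    metabolic: dict = field(default_factory=dict)
    nirs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**{k: d.get(k, {}) for k in ("accel", "emg", "metabolic", "nirs")})


def subject_ids(n: int) -> list:
    return [f"S{i + 1:02d}" for i in range(n)]


def _rng(seed: int, subject: int, modality: str, channel: int = 0) -> np.random.Generator:
    """Deterministic substream for (subject, modality, channel)."""
    key = (subject, _MODALITY_KEY[modality], channel)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-median multiplicative jitter with coefficient of variation ~cv."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return float(np.exp(rng.normal(0.0, sigma)))


# ---------------------------------------------------------------------------
# accelerometry


def generate_acceleration(
    config: CohortConfig,
    site_attenuations: dict = None,
    *,
    noise_rms: float = 0.01,
    harmonic_fractions: tuple = (0.05, 0.02),
    subject_gain_cv: float = 0.10,
) -> tuple:
    """Per-subject accelerometer channels plus exact per-subject gains.

    Source channels (``FTSH``, ``SHSH``) are sinusoids scaled so their RMS
    equals the configured g_rms drive. Tissue channels are the two source
    sinusoids scaled by the site gains, plus harmonic distortion
    (``harmonic_fractions`` of the at-site fundamental amplitude for the
    2nd, 3rd, ... harmonics) and white measurement noise of RMS
    ``noise_rms`` g. The gains actually used per subject are returned in
    the ground-truth dict.
    """
    atten = dict(DEFAULT_SITE_ATTENUATIONS if site_attenuations is None else site_attenuations)
    for site, gains in atten.items():
        if site not in ACCEL_SITES:
            raise ValueError(f"unknown accelerometer site label: {site!r}")
        g15, g25 = gains
        if not (np.isfinite(g15) and np.isfinite(g25)) or g15 < 0 or g25 < 0:
            raise ValueError(f"gains for site {site!r} must be finite and >= 0")

    n = int(config.accel_rate * config.accel_duration)
    t = np.arange(n) / config.accel_rate

    subjects = []
    gt = {"source_rms": {s: EXCITATIONS[s][1] for s in SOURCE_SITES}, "subjects": {}}
    for i, sid in enumerate(subject_ids(config.n_subjects)):
        rng = _rng(config.seed, i, "accel")
        phase = {s: rng.uniform(0, 2 * np.pi) for s in SOURCE_SITES}
        waves = {}
        for s in SOURCE_SITES:
            f0, grms = EXCITATIONS[s]
            waves[s] = grms * np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t + phase[s])

        channels = {}
        gt_subject = {}
        for site, (g15, g25) in atten.items():
            if site in SOURCE_SITES:
                sg15, sg25 = g15, g25
            else:
                jitter = _lognormal_factor(rng, subject_gain_cv)
                sg15, sg25 = g15 * jitter, g25 * jitter
            x = sg15 * waves["SHSH"] + sg25 * waves["FTSH"]
            if site not in SOURCE_SITES:
                for k, frac in enumerate(harmonic_fractions, start=2):
                    for s, gain in (("SHSH", sg15), ("FTSH", sg25)):
                        f0, grms = EXCITATIONS[s]
                        amp = frac * gain * grms * np.sqrt(2.0)
                        x = x + amp * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
            if noise_rms > 0:
                x = x + noise_rms * rng.standard_normal(n)
            channels[site] = TimeSeriesChannel(
                samples=x,
                rate=config.accel_rate,
                units="g",
                site=site,
                axis=SITE_AXIS.get(site, "y"),
                condition="vibration",
            )
            gt_subject[site] = {"gain_15": float(sg15), "gain_25": float(sg25)}
        subjects.append(channels)
        gt["subjects"][sid] = gt_subject
    return subjects, gt


# ---------------------------------------------------------------------------
# surface EMG


def band_limited_noise(
    n: int,
    rate: float,
    rng: np.random.Generator,
    f_lo: float = 10.0,
    flat_lo: float = 20.0,
    flat_hi: float = 150.0,
    f_hi: float = 400.0,
) -> np.ndarray:
    """Unit-RMS Gaussian noise with a raised-cosine band envelope.

    The amplitude spectrum is flat between ``flat_lo`` and ``flat_hi``,
    rolls off with half-cosine shoulders toward ``f_lo`` and ``f_hi``, and
    is zero outside — a simple, fully characterizable stand-in for a
    surface-EMG power spectrum.
    """
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, 1.0 / rate)
    env = np.zeros_like(f)
    core = (f >= flat_lo) & (f <= flat_hi)
    env[core] = 1.0
    lo = (f >= f_lo) & (f < flat_lo)
    env[lo] = 0.5 * (1 - np.cos(np.pi * (f[lo] - f_lo) / (flat_lo - f_lo)))
    hi = (f > flat_hi) & (f <= f_hi)
    env[hi] = 0.5 * (1 + np.cos(np.pi * (f[hi] - flat_hi) / (f_hi - flat_hi)))
    x = irfft(spec * env, n)
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def _sum_of_sines(lines, rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of sinusoids with random phase per line.

    When every line frequency is a multiple of a common divisor whose
    period spans an integer number of samples, one period is synthesized
    and tiled (exact, and much cheaper for long records).
    """
    freqs = np.array([f for f, _ in lines])
    amps = np.array([a for _, a in lines])
    phases = rng.uniform(0, 2 * np.pi, size=len(lines))
    # common fundamental via integer gcd at mHz precision
    mhz = np.round(freqs * 1000).astype(np.int64)
    if np.all(np.abs(mhz - freqs * 1000) < 1e-6) and np.all(mhz > 0):
        f_gcd = np.gcd.reduce(mhz) / 1000.0
        period = rate / f_gcd
        if abs(period - round(period)) < 1e-9 and 0 < round(period) <= n:
            p = int(round(period))
            t = np.arange(p) / rate
            chunk = np.sum(
                amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]),
                axis=0,
            )
            reps = int(np.ceil(n / p))
            return np.tile(chunk, reps)[:n]
    t = np.arange(n) / rate
    return np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0
    )


def artifact_lines(
    base_frequencies: tuple = (15.0, 25.0, 60.0),
    f_max: float = 400.0,
    total_rms: float = 1.0,
) -> list:
    """Harmonic line set ``[(freq, amplitude), ...]`` with 1/k amplitude decay,
    scaled so the summed sinusoid RMS equals ``total_rms``.

    Coincident harmonics from different bases (e.g. 60 Hz is both the mains
    fundamental and the 4th harmonic of 15 Hz) merge into one line with the
    combined power, so every returned frequency is unique and line powers
    add independently.
    """
    power_at = {}
    for f0 in base_frequencies:
        k = 1
        while k * f0 <= f_max:
            f = round(float(k * f0), 9)
            power_at[f] = power_at.get(f, 0.0) + (1.0 / k) ** 2 / 2.0
            k += 1
    total_power = sum(power_at.values())
    scale = total_rms**2 / total_power if total_power > 0 else 0.0
    return [(f, float(np.sqrt(2.0 * p * scale))) for f, p in sorted(power_at.items())]


def default_muscle_params(mvic_rms: float = 1.0, artifact_ratio: float = 1.5) -> dict:
    """Nominal per-muscle generator parameters in arbitrary EMG units.

    ``artifact_ratio`` sets the total artifact RMS relative to the
    physiological vibration RMS (artifact lines dominate raw vibration
    records, as seen on real vibration EMG).
    """
    params = {}
    for muscle, (base_frac, mult) in DEFAULT_MUSCLE_EFFECTS.items():
        vib = base_frac * mult * mvic_rms
        params[muscle] = {
            "baseline_rms": base_frac * mvic_rms,
            "vibration_rms": vib,
            "mvic_rms": mvic_rms,
            "artifact": artifact_lines(total_rms=artifact_ratio * vib),
        }
    return params


@dataclass
class EmgRecord:
    """One muscle's session: a continuous baseline+vibration channel with a
    known vibration onset, plus MVIC trial channels."""

    muscle: str
    channel: TimeSeriesChannel
    vibration_onset: float
    mvic: list


def generate_emg(
    config: CohortConfig,
    muscle_params: dict = None,
    *,
    subject_cv: float = 0.20,
    condition_cv: float = 0.03,
) -> tuple:
    """Per-subject EMG record sets plus exact per-subject ground truth.

    The physiological component is band-limited noise scaled to the
    requested RMS per condition; vibration epochs additionally carry pure
    sinusoid artifact lines (random phase per line per record) at the
    excitation/mains frequencies and harmonics. ``subject_cv`` applies one
    multiplicative lognormal factor per subject (scaling all of that
    subject's conditions together); ``condition_cv`` adds independent
    lognormal jitter per condition, modelling same-session repeatability.
    Explicit ``muscle_params`` with both CVs at zero are honoured exactly.
    """
    params = default_muscle_params() if muscle_params is None else muscle_params
    for muscle, p in params.items():
        for key in ("baseline_rms", "vibration_rms", "mvic_rms"):
            if p[key] < 0:
                raise ValueError(f"{key} for {muscle!r} must be >= 0, got {p[key]}")

    n_pre = int(config.emg_rate * config.emg_pre_onset)
    n_post = int(config.emg_rate * config.emg_post_onset)
    n_mvic = int(config.emg_rate * config.mvic_duration)
    onset = n_pre / config.emg_rate
    t_post = np.arange(n_post) / config.emg_rate

    subjects = []
    gt = {}
    for i, sid in enumerate(subject_ids(config.n_subjects)):
        prng = _rng(config.seed, i, "params")
        subj_factor = _lognormal_factor(prng, subject_cv)
        records = {}
        gt_subject = {}
        for j, muscle in enumerate(params):
            p = params[muscle]
            art_factor = _lognormal_factor(prng, subject_cv)
            base_rms = p["baseline_rms"] * subj_factor * _lognormal_factor(prng, condition_cv)
            vib_rms = p["vibration_rms"] * subj_factor * _lognormal_factor(prng, condition_cv)
            mvic_rms = p["mvic_rms"] * subj_factor * _lognormal_factor(prng, condition_cv)
            lines = [(f, a * art_factor) for f, a in p.get("artifact", [])]

            rng = _rng(config.seed, i, "emg", j)
            x_pre = base_rms * band_limited_noise(n_pre, config.emg_rate, rng)
            x_post = vib_rms * band_limited_noise(n_post, config.emg_rate, rng)
            if lines:
                x_post = x_post + _sum_of_sines(lines, config.emg_rate, n_post, rng)
            channel = TimeSeriesChannel(
                samples=np.concatenate([x_pre, x_post]),
                rate=config.emg_rate,
                units="au",
                site=muscle,
                condition="vibration",
            )
            mvic = [
                TimeSeriesChannel(
                    samples=mvic_rms * band_limited_noise(n_mvic, config.emg_rate, rng),
                    rate=config.emg_rate,
                    units="au",
                    site=muscle,
                    condition="mvic",
                )
                for _ in range(2)
            ]
            records[muscle] = EmgRecord(
                muscle=muscle, channel=channel, vibration_onset=onset, mvic=mvic
            )
            gt_subject[muscle] = {
                "baseline_rms": float(base_rms),
                "vibration_rms": float(vib_rms),
                "mvic_rms": float(mvic_rms),
                "pct_mvic_baseline": float(100.0 * base_rms / mvic_rms) if mvic_rms else float("nan"),
                "pct_mvic_vibration": float(100.0 * vib_rms / mvic_rms) if mvic_rms else float("nan"),
                "artifact_lines": [[float(f), float(a)] for f, a in lines],
            }
        subjects.append(records)
        gt[sid] = gt_subject
    return subjects, gt


# ---------------------------------------------------------------------------
# metabolic and rSO2 step responses


def _step_response(
    t: np.ndarray,
    onset: float,
    baseline: float,
    plateau: float,
    tau: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if tau <= 0:
        raise ValueError(f"rise_time_constant must be positive, got {tau}")
    x = np.full_like(t, baseline, dtype=float)
    post = t >= onset
    x[post] = baseline + (plateau - baseline) * (1.0 - np.exp(-(t[post] - onset) / tau))
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(t.size)
    return x


def _draw_response(
    nominal: dict, rng: np.random.Generator, subject_cv: float, effect_cv: float
) -> dict:
    base = nominal["baseline_mean"] * _lognormal_factor(rng, subject_cv)
    if nominal["baseline_mean"] != 0:
        rel_effect = (nominal["plateau_mean"] - nominal["baseline_mean"]) / nominal["baseline_mean"]
    else:
        rel_effect = 0.0
    plateau = base * (1.0 + rel_effect * _lognormal_factor(rng, effect_cv))
    return {
        "baseline_mean": float(base),
        "plateau_mean": float(plateau),
        "rise_time_constant": nominal["rise_time_constant"],
        "noise_sd": nominal["noise_sd"],
    }


def generate_metabolic(
    config: CohortConfig,
    response: dict = None,
    *,
    subject_cv: float = 0.15,
    effect_cv: float = 0.20,
) -> tuple:
    """Per-subject metabolic series (saturating-exponential step + noise).

    All five variables share one clock at ``metabolic_rate``; the baseline
    segment is ``baseline_mean`` plus noise and the vibration segment rises
    exponentially toward ``plateau_mean``. Per-subject draws are lognormal
    on the baseline (``subject_cv``) and on the relative effect
    (``effect_cv``); both at zero honour the nominal response exactly.
    """
    nominal = DEFAULT_METABOLIC_RESPONSE if response is None else response
    duration = config.baseline_duration + config.vibration_duration
    n = int(config.metabolic_rate * duration)
    t = np.arange(n) / config.metabolic_rate
    onset = config.baseline_duration

    subjects = []
    gt = {}
    for i, sid in enumerate(subject_ids(config.n_subjects)):
        prng = _rng(config.seed, i, "params", channel=1)
        rng = _rng(config.seed, i, "metabolic")
        data = {}
        gt_subject = {}
        for var in nominal:
            drawn = _draw_response(nominal[var], prng, subject_cv, effect_cv)
            data[var] = _step_response(
                t,
                onset,
                drawn["baseline_mean"],
                drawn["plateau_mean"],
                drawn["rise_time_constant"],
                drawn["noise_sd"],
                rng,
            )
            b, p = drawn["baseline_mean"], drawn["plateau_mean"]
            drawn["pct_change"] = float(100.0 * (p - b) / b) if b else float("nan")
            gt_subject[var] = drawn
        subjects.append(
            MetabolicSeries(time=t, data=data, rate=config.metabolic_rate, vibration_onset=onset)
        )
        gt[sid] = gt_subject
    return subjects, gt


def generate_nirs(
    config: CohortConfig,
    response: dict = None,
    *,
    subject_cv: float = 0.05,
    effect_cv: float = 0.20,
) -> tuple:
    """Per-subject rSO2 series per site, clipped to the [0, 100] % domain.

    Identical contract to :func:`generate_metabolic` at ``nirs_rate`` and
    three sites; requesting values outside [0, 100] clips with a logged
    warning. Effects vary on the absolute percentage-point delta.
    """
    nominal = DEFAULT_NIRS_RESPONSE if response is None else response
    duration = config.baseline_duration + config.vibration_duration
    n = int(config.nirs_rate * duration)
    t = np.arange(n) / config.nirs_rate
    onset = config.baseline_duration

    subjects = []
    gt = {}
    for i, sid in enumerate(subject_ids(config.n_subjects)):
        prng = _rng(config.seed, i, "params", channel=2)
        rng = _rng(config.seed, i, "nirs")
        data = {}
        gt_subject = {}
        for site in nominal:
            nom = nominal[site]
            base = nom["baseline_mean"] * _lognormal_factor(prng, subject_cv)
            delta = (nom["plateau_mean"] - nom["baseline_mean"]) * _lognormal_factor(
                prng, effect_cv
            )
            x = _step_response(
                t, onset, base, base + delta, nom["rise_time_constant"], nom["noise_sd"], rng
            )
            if np.any((x < 0) | (x > 100)):
                log.warning(
                    "rSO2 series for %s/%s clipped to [0, 100] %%", sid, site
                )
                x = np.clip(x, 0.0, 100.0)
            data[site] = x
            gt_subject[site] = {
                "baseline_mean": float(base),
                "plateau_mean": float(base + delta),
                "delta_points": float(delta),
                "rise_time_constant": nom["rise_time_constant"],
                "noise_sd": nom["noise_sd"],
            }
        subjects.append(
            OxySeries(time=t, data=data, rate=config.nirs_rate, vibration_onset=onset)
        )
        gt[sid] = gt_subject
    return subjects, gt


# ---------------------------------------------------------------------------
# cohort assembly and a table-level null


@dataclass
class Cohort:
    """All generated records for one synthetic cohort."""

    config: CohortConfig
    subjects: list
    accel: list
    emg: list
    metabolic: list
    nirs: list
    ground_truth: GroundTruth


def generate_cohort(config: CohortConfig, *, include_accel: bool = True, **kwargs) -> Cohort:
    """Generate every modality for one cohort under one seed.

    Keyword arguments prefixed ``accel_``, ``emg_``, ``metabolic_``,
    ``nirs_`` are forwarded to the per-modality generators.
    """
    def sub(prefix):
        return {
            k[len(prefix):]: v for k, v in kwargs.items() if k.startswith(prefix)
        }

    accel_subj, accel_gt = (
        generate_acceleration(config, **sub("accel_")) if include_accel else ([], {})
    )
    emg_subj, emg_gt = generate_emg(config, **sub("emg_"))
    met_subj, met_gt = generate_metabolic(config, **sub("metabolic_"))
    nirs_subj, nirs_gt = generate_nirs(config, **sub("nirs_"))
    return Cohort(
        config=config,
        subjects=subject_ids(config.n_subjects),
        accel=accel_subj,
        emg=emg_subj,
        metabolic=met_subj,
        nirs=nirs_subj,
        ground_truth=GroundTruth(
            accel=accel_gt, emg=emg_gt, metabolic=met_gt, nirs=nirs_gt
        ),
    )


def null_paired_table(
    n_subjects: int,
    variables: tuple,
    rng: np.random.Generator,
    mean: float = 1.0,
    sd: float = 0.1,
):
    """Paired cohort table with baseline and vibration drawn iid per subject.

    The exact null of the condition test: both conditions come from the same
    distribution, so any detected "effect" is a false positive. Used for
    type-I-error calibration of the inference layer.
    """
    import pandas as pd

    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        for var in variables:
            rows.append(
                {
                    "subject": sid,
                    "variable": var,
                    "baseline": mean + sd * rng.standard_normal(),
                    "vibration": mean + sd * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
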