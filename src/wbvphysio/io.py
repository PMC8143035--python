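"""Readers, writers, manifest handling, and the end-to-end pipeline driver.

Interchange formats are deliberately plain: one CSV per subject per
modality with a ``time_s,<channel labels>`` header, a JSON cohort manifest
listing files, rates, event times and (for synthetic cohorts) the
ground-truth block, and JSON reports. All time is seconds from record
start; vibration onset is an explicit manifest field, never inferred from
the signals.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import accel as accel_mod
from . import emg as emg_mod
from . import metabolic as met_mod
from . import nirs as nirs_mod
from . import stats as stats_mod
from .channels import TimeSeriesChannel
from .config import CohortConfig
from .metabolic import MetabolicSeries
from .nirs import OxySeries
from .synthio import SITE_AXIS, SOURCE_SITES, Cohort, EmgRecord, generate_cohort

log = logging.getLogger(__name__)

RATE_TOLERANCE = 1e-3  # relative tolerance on the inferred sampling rate


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and subject."""


def write_channel_csv(path, time: np.ndarray, channels: dict) -> None:
    """Write ``time_s,<labels>`` CSV with one column per channel."""
    df = pd.DataFrame({"time_s": time})
    for label, values in channels.items():
        df[label] = values
    df.to_csv(path, index=False, float_format="%.8g")


def read_channel_csv(path, expected_rate: float) -> tuple:
    """Load a channel CSV, validating time base and sample integrity.

    Returns ``(time, {label: ndarray})``. The sampling rate is inferred
    from the median time step and must match ``expected_rate`` within
    0.1%; non-monotone time or non-finite samples are rejected with the
    offending row numbers.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 2  # 1-based data row after header
        raise ValueError(f"{path}: non-monotone time at row {bad}")
    rate = 1.0 / float(np.median(dt))
    if abs(rate - expected_rate) > RATE_TOLERANCE * expected_rate:
        raise ValueError(
            f"{path}: inferred rate {rate:.4f} Hz differs from expected "
            f"{expected_rate} Hz by more than 0.1%"
        )
    channels = {}
    for col in df.columns[1:]:
        values = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            rows = (bad[:5] + 2).tolist()
            raise ValueError(f"{path}: non-finite values in column {col!r} at rows {rows}")
        channels[col] = values
    return t, channels


# ---------------------------------------------------------------------------
# cohort writing / loading


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write per-subject CSVs and the JSON manifest; returns manifest path."""
    out = Path(out_dir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    subjects = []
    for i, sid in enumerate(cohort.subjects):
        entry = {"id": sid}
        if cohort.accel:
            ch = cohort.accel[i]
            path = data / f"{sid}_accel.csv"
            t = np.arange(next(iter(ch.values())).n) / cfg.accel_rate
            write_channel_csv(path, t, {site: c.samples for site, c in ch.items()})
            entry["accel"] = str(path.relative_to(out))
        rec = cohort.emg[i]
        first = next(iter(rec.values()))
        t = np.arange(first.channel.n) / cfg.emg_rate
        path = data / f"{sid}_emg.csv"
        write_channel_csv(path, t, {m: r.channel.samples for m, r in rec.items()})
        entry["emg_record"] = str(path.relative_to(out))
        entry["emg_mvic"] = []
        for trial in range(len(first.mvic)):
            path = data / f"{sid}_mvic{trial + 1}.csv"
            t_m = np.arange(first.mvic[trial].n) / cfg.emg_rate
            write_channel_csv(
                path, t_m, {m: r.mvic[trial].samples for m, r in rec.items()}
            )
            entry["emg_mvic"].append(str(path.relative_to(out)))
        met = cohort.metabolic[i]
        path = data / f"{sid}_metabolic.csv"
        write_channel_csv(path, met.time, met.data)
        entry["metabolic"] = str(path.relative_to(out))
        oxy = cohort.nirs[i]
        path = data / f"{sid}_nirs.csv"
        write_channel_csv(path, oxy.time, oxy.data)
        entry["nirs"] = str(path.relative_to(out))
        entry["vibration_onset_s"] = {
            "emg": first.vibration_onset,
            "metabolic": met.vibration_onset,
            "nirs": oxy.vibration_onset,
        }
        subjects.append(entry)

    manifest = {
        "config": cfg.to_dict(),
        "modalities": {
            "accel": {"rate": cfg.accel_rate, "units": "g"},
            "emg": {"rate": cfg.emg_rate, "units": "au"},
            "metabolic": {"rate": cfg.metabolic_rate},
            "nirs": {"rate": cfg.nirs_rate, "units": "%"},
        },
        "subjects": subjects,
        "ground_truth": cohort.ground_truth.to_dict(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path) -> dict:
    """Load a cohort manifest and verify every referenced file exists."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    manifest["_root"] = str(root)
    for entry in manifest["subjects"]:
        for key in ("accel", "emg_record", "metabolic", "nirs"):
            if key in entry and not (root / entry[key]).exists():
                raise FileNotFoundError(
                    f"manifest references missing file {entry[key]} for subject {entry['id']}"
                )
        for p in entry.get("emg_mvic", []):
            if not (root / p).exists():
                raise FileNotFoundError(
                    f"manifest references missing file {p} for subject {entry['id']}"
                )
    for mod in manifest["modalities"].values():
        if mod["rate"] <= 0:
            raise ValueError("manifest modality rates must be positive")
    return manifest


def _entry(manifest: dict, subject_id: str) -> dict:
    for entry in manifest["subjects"]:
        if entry["id"] == subject_id:
            return entry
    raise KeyError(f"subject {subject_id!r} not in manifest")


def load_accel_subject(manifest: dict, subject_id: str) -> dict:
    root = Path(manifest["_root"])
    entry = _entry(manifest, subject_id)
    rate = manifest["modalities"]["accel"]["rate"]
    _, channels = read_channel_csv(root / entry["accel"], rate)
    return {
        site: TimeSeriesChannel(
            samples=v, rate=rate, units="g", site=site,
            axis=SITE_AXIS.get(site, ""), condition="vibration",
        )
        for site, v in channels.items()
    }


def load_emg_subject(manifest: dict, subject_id: str) -> dict:
    root = Path(manifest["_root"])
    entry = _entry(manifest, subject_id)
    rate = manifest["modalities"]["emg"]["rate"]
    onset = entry["vibration_onset_s"]["emg"]
    _, channels = read_channel_csv(root / entry["emg_record"], rate)
    mvic_sets = [read_channel_csv(root / p, rate)[1] for p in entry.get("emg_mvic", [])]
    records = {}
    for muscle, v in channels.items():
        records[muscle] = EmgRecord(
            muscle=muscle,
            channel=TimeSeriesChannel(
                samples=v, rate=rate, units="au", site=muscle, condition="vibration"
            ),
            vibration_onset=onset,
            mvic=[
                TimeSeriesChannel(
                    samples=m[muscle], rate=rate, units="au", site=muscle, condition="mvic"
                )
                for m in mvic_sets
            ],
        )
    return records


def load_metabolic_subject(manifest: dict, subject_id: str) -> MetabolicSeries:
    root = Path(manifest["_root"])
    entry = _entry(manifest, subject_id)
    rate = manifest["modalities"]["metabolic"]["rate"]
    t, channels = read_channel_csv(root / entry["metabolic"], rate)
    return MetabolicSeries(
        time=t, data=channels, rate=rate,
        vibration_onset=entry["vibration_onset_s"]["metabolic"],
    )


def load_nirs_subject(manifest: dict, subject_id: str) -> OxySeries:
    root = Path(manifest["_root"])
    entry = _entry(manifest, subject_id)
    rate = manifest["modalities"]["nirs"]["rate"]
    t, channels = read_channel_csv(root / entry["nirs"], rate)
    return OxySeries(
        time=t, data=channels, rate=rate,
        vibration_onset=entry["vibration_onset_s"]["nirs"],
    )


# ---------------------------------------------------------------------------
# summary tables feeding the inference stage


def metabolic_paired_table(series_list, subject_ids, **kw) -> pd.DataFrame:
    rows = []
    for sid, series in zip(subject_ids, series_list):
        for summary in met_mod.summarize_episode(series, variables=series.variables, **kw):
            rows.append(
                {
                    "subject": sid,
                    "variable": summary.variable,
                    "baseline": summary.baseline_mean,
                    "vibration": summary.vibration_peak_mean,
                }
            )
    return pd.DataFrame(rows)


def metabolic_episode_table(series_list, subject_ids, **kw) -> pd.DataFrame:
    """Every EpisodeSummary field per subject and metabolic variable."""
    rows = []
    for sid, series in zip(subject_ids, series_list):
        for summary in met_mod.summarize_episode(series, variables=series.variables, **kw):
            rows.append({"subject": sid, **dataclasses.asdict(summary)})
    return pd.DataFrame(rows)


def nirs_episode_table(series_list, subject_ids, **kw) -> pd.DataFrame:
    """Every per-site rSO2 summary field (absolute and relative change)."""
    rows = []
    for sid, series in zip(subject_ids, series_list):
        for summary in nirs_mod.summarize_oxy(series, **kw):
            rows.append({"subject": sid, **dataclasses.asdict(summary)})
    return pd.DataFrame(rows)


def nirs_paired_table(series_list, subject_ids, **kw) -> pd.DataFrame:
    rows = []
    for sid, series in zip(subject_ids, series_list):
        for summary in nirs_mod.summarize_oxy(series, **kw):
            rows.append(
                {
                    "subject": sid,
                    "variable": summary.site,
                    "baseline": summary.baseline_mean,
                    "vibration": summary.vibration_peak_mean,
                }
            )
    return pd.DataFrame(rows)


def accel_summary(
    subject_channels, subject_ids, *, resolution=0.25, rms_window_s=4.0, out_dir=None
) -> dict:
    """Per-site cohort RMS plus transmissibility/coherence at both drives.

    Each tissue channel is detrended/low-passed, then cross-spectra are
    taken against the foot drive (read at 25 Hz) and the shoulder drive
    (read at 15 Hz). With ``out_dir`` set, cohort-mean spectral curves
    (Gii, Goo, |Gio|, |H|, coherence vs frequency) are written as one CSV
    per tissue site and source.
    """
    sites = list(next(iter(subject_channels)).keys())
    rms_per_site = {site: [] for site in sites}
    trans = {site: {"H15": [], "H25": [], "coh15": [], "coh25": []} for site in sites}
    curves = {}
    for channels in subject_channels:
        pre = {site: accel_mod.preprocess_accel(ch) for site, ch in channels.items()}
        for site, ch in pre.items():
            rms_per_site[site].append(
                accel_mod.segment_rms(ch, window_s=rms_window_s)["intra_mean"]
            )
            if site in SOURCE_SITES:
                continue
            for src, key_h, key_c, freq in (
                ("SHSH", "H15", "coh15", 15.0),
                ("FTSH", "H25", "coh25", 25.0),
            ):
                if src not in pre:
                    continue
                xs = accel_mod.cross_spectral(pre[src], ch, resolution=resolution)
                trans[site][key_h].append(xs.magnitude_at(freq))
                trans[site][key_c].append(xs.coherence_at(freq))
                acc = curves.setdefault(
                    (site, src),
                    {"frequency_hz": xs.frequencies, "Gii": [], "Goo": [],
                     "Gio_mag": [], "H_mag": [], "coherence": []},
                )
                acc["Gii"].append(xs.Gii)
                acc["Goo"].append(xs.Goo)
                acc["Gio_mag"].append(np.abs(xs.Gio))
                acc["H_mag"].append(np.where(xs.defined, np.abs(xs.H), np.nan))
                acc["coherence"].append(xs.coherence)
    out = {"sites": {}}
    for site in sites:
        entry = {"cohort_rms": accel_mod.cohort_rms(rms_per_site[site])}
        if site not in SOURCE_SITES:
            for key in ("H15", "H25", "coh15", "coh25"):
                vals = trans[site][key]
                entry[key + "_mean"] = float(np.mean(vals)) if vals else None
        out["sites"][site] = entry
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (site, src), acc in curves.items():
            df = pd.DataFrame({"frequency_hz": acc["frequency_hz"]})
            for col in ("Gii", "Goo", "Gio_mag", "H_mag", "coherence"):
                stacked = np.vstack(acc[col])
                counts = np.sum(~np.isnan(stacked), axis=0)
                sums = np.nansum(stacked, axis=0)
                # bins undefined for every subject stay NaN without warnings
                df[col] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            df.to_csv(
                out_dir / f"spectra_{site}_vs_{src}.csv", index=False, float_format="%.8g"
            )
    return out


# ---------------------------------------------------------------------------
# the end-to-end pipeline


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def run_pipeline(
    config: CohortConfig,
    out_dir,
    *,
    alpha: float = 0.05,
    accel_resolution: float = 0.25,
    rms_window_s: float = 4.0,
    include_accel: bool = True,
    **generator_kwargs,
) -> dict:
    """simulate → write → read back → analyse every stage → infer.

    Deterministic given ``config.seed``. Every stage's parameters are
    echoed into ``provenance.json``; any stage failure aborts with the
    stage name and offending subject. Returns the full report dict and
    writes ``inference_report.json``, per-family CSVs and the provenance
    log under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, subject="-"):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineError(f"stage {name!r} failed for subject {subject}: {exc}") from exc

    cohort = stage("simulate", lambda: generate_cohort(
        config, include_accel=include_accel, **generator_kwargs
    ))
    manifest_path = stage("write", lambda: write_cohort(cohort, out))
    manifest = stage("read", lambda: read_manifest(manifest_path))
    sids = [e["id"] for e in manifest["subjects"]]

    accel_report = None
    if include_accel:
        accel_channels = [
            stage("accel-load", lambda s=sid: load_accel_subject(manifest, s), sid)
            for sid in sids
        ]
        accel_report = stage(
            "accel",
            lambda: accel_summary(
                accel_channels, sids, resolution=accel_resolution,
                rms_window_s=rms_window_s, out_dir=out / "spectra",
            ),
        )
        (out / "accel_summary.json").write_text(json.dumps(_to_jsonable(accel_report), indent=1))

    emg_results = []
    for sid in sids:
        records = stage("emg-load", lambda s=sid: load_emg_subject(manifest, s), sid)
        emg_results.extend(
            stage("emg", lambda r=records, s=sid: emg_mod.activation_results([r], [s]), sid)
        )
    emg_table = emg_mod.paired_table_from_results(emg_results)
    emg_table.to_csv(out / "emg_activation.csv", index=False)
    emg_mod.details_table_from_results(emg_results).to_csv(
        out / "emg_activation_details.csv", index=False
    )

    met_series = [
        stage("metabolic-load", lambda s=sid: load_metabolic_subject(manifest, s), sid)
        for sid in sids
    ]
    met_table = stage("metabolic", lambda: metabolic_paired_table(met_series, sids))
    met_table.to_csv(out / "metabolic_summary.csv", index=False)
    stage("metabolic", lambda: metabolic_episode_table(met_series, sids)).to_csv(
        out / "metabolic_episodes.csv", index=False
    )

    nirs_series = [
        stage("nirs-load", lambda s=sid: load_nirs_subject(manifest, s), sid)
        for sid in sids
    ]
    nirs_table = stage("nirs", lambda: nirs_paired_table(nirs_series, sids))
    nirs_table.to_csv(out / "nirs_summary.csv", index=False)
    stage("nirs", lambda: nirs_episode_table(nirs_series, sids)).to_csv(
        out / "nirs_episodes.csv", index=False
    )

    inference = stage(
        "stats", lambda: stats_mod.run_inference(emg_table, met_table, nirs_table, alpha=alpha)
    )
    report = {
        "inference": inference,
        "accel": accel_report,
        "n_subjects": len(sids),
    }
    (out / "inference_report.json").write_text(json.dumps(_to_jsonable(inference), indent=1))
    for name in inference:
        rows = [dataclasses.asdict(r) for r in inference[name]["posthoc"]]
        pd.DataFrame(rows).to_csv(out / f"posthoc_{name}.csv", index=False)

    provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "alpha": alpha,
        "accel_resolution_hz": accel_resolution,
        "rms_window_s": rms_window_s,
        "generator_kwargs": {k: _to_jsonable(v) for k, v in generator_kwargs.items()},
        "stages": ["simulate", "write", "read", "accel", "emg", "metabolic", "nirs", "stats"],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return report
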