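"""Readers and writers for recordings, trial sets, connectivity and results.

Standard EEG formats (BrainVision ``.vhdr`` and EDF) are read through mne.
The package's own on-disk container for arrays is a ``.npz`` file with a
JSON sidecar (``<stem>.json``) carrying sampling rate, channel labels,
events and other metadata; delimited text (TSV) is used for events tables,
cohort tables, adjacency matrices, and efficiency series.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (BinaryNetwork, EfficiencySeries, Recording,
                         TimeVaryingConnectivity, TrialSet, TVMVARModel)

__all__ = [
    "read_raw",
    "read_events_tsv",
    "save_recording", "load_recording",
    "save_trialset", "load_trialset",
    "save_models", "load_models",
    "save_connectivity", "load_connectivity",
    "write_adjacency_tsv", "read_adjacency_tsv",
    "write_ge_series_tsv", "read_ge_series_tsv",
    "write_cohort_tsv", "read_cohort_tsv",
    "write_edf",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# standard EEG formats (via mne)

def read_raw(path: str | Path, events_tsv: str | Path | None = None) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording into μV.

    Events come from the file's annotations/markers, or from an external
    TSV (columns ``onset_sample``, ``label``) when ``events_tsv`` is given.
    """
    import mne  # deferred: mne import is slow and optional for synthetic runs

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format {suffix!r} (need .vhdr or .edf)")
    data_uv = raw.get_data() * 1e6  # mne uses volts internally
    events: list[tuple[int, str]] = []
    if events_tsv is not None:
        events = read_events_tsv(events_tsv)
    else:
        for ann in raw.annotations:
            events.append((int(round(ann["onset"] * raw.info["sfreq"])),
                           str(ann["description"])))
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), events=events)


def read_events_tsv(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"onset_sample", "label"} <= set(df.columns):
        raise ValueError("events TSV needs columns onset_sample, label")
    return [(int(r.onset_sample), str(r.label)) for r in df.itertuples()]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Export a Recording as EDF, if an EDF export backend is installed."""
    import mne

    info = mne.create_info(list(rec.channel_labels), rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    try:
        raw.export(str(path), fmt="edf", overwrite=True, verbose="error")
    except (ImportError, RuntimeError, ValueError) as err:
        raise RuntimeError(
            "EDF export needs the 'edfio' backend for mne, which is not "
            "installed; use save_recording (.npz + JSON sidecar) instead"
        ) from err


# ---------------------------------------------------------------------------
# npz + JSON-sidecar container

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez(path, data=rec.data)
    _write_json(_sidecar(path), {
        "kind": "recording", "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "events": [[int(s), str(l)] for s, l in rec.events],
    })
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        data = z["data"]
    return Recording(data=data, fs=meta["fs"], channel_labels=meta["channel_labels"],
                     events=[(int(s), str(l)) for s, l in meta["events"]])


def save_trialset(ts: TrialSet, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez(path, data=ts.data, times=ts.times, rejected_mask=ts.rejected_mask)
    _write_json(_sidecar(path), {
        "kind": "trialset", "fs": ts.fs,
        "channel_labels": list(ts.channel_labels), "labels": list(ts.labels),
    })
    return path


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        data, times, mask = z["data"], z["times"], z["rejected_mask"]
    return TrialSet(data=data, times=times, labels=meta["labels"], fs=meta["fs"],
                    channel_labels=meta["channel_labels"], rejected_mask=mask)


def save_models(models: list[TVMVARModel], path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez(path,
             coefficients=np.stack([m.coefficients for m in models]),
             innovation_cov=np.stack([m.innovation_cov for m in models]))
    m0 = models[0]
    _write_json(_sidecar(path), {
        "kind": "tvmvar_models", "order": m0.order, "fs": m0.fs,
        "update_coefficient": m0.update_coefficient,
        "channel_labels": list(m0.channel_labels), "n_models": len(models),
    })
    return path


def load_models(path: str | Path) -> list[TVMVARModel]:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        coeffs, covs = z["coefficients"], z["innovation_cov"]
    return [TVMVARModel(order=meta["order"], coefficients=coeffs[i],
                        innovation_cov=covs[i],
                        channel_labels=meta["channel_labels"], fs=meta["fs"],
                        update_coefficient=meta["update_coefficient"])
            for i in range(coeffs.shape[0])]


def save_connectivity(tvc: TimeVaryingConnectivity, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez(path, theta=tvc.theta, times=tvc.times)
    _write_json(_sidecar(path), {
        "kind": "connectivity", "band": list(tvc.band),
        "channel_labels": list(tvc.channel_labels),
    })
    return path


def load_connectivity(path: str | Path) -> TimeVaryingConnectivity:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as z:
        theta, times = z["theta"], z["times"]
    return TimeVaryingConnectivity(theta=theta, band=tuple(meta["band"]),
                                   times=times, channel_labels=meta["channel_labels"])


# ---------------------------------------------------------------------------
# delimited text

def write_adjacency_tsv(net: BinaryNetwork, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(net.adjacency, index=list(net.channel_labels),
                      columns=list(net.channel_labels))
    df.to_csv(path, sep="\t")
    return path


def read_adjacency_tsv(path: str | Path, time: float = 0.0,
                       cost: float = 1.0) -> BinaryNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BinaryNetwork(adjacency=df.to_numpy(), channel_labels=list(df.columns),
                         time=time, cost=cost)


def write_ge_series_tsv(series: list[EfficiencySeries], path: str | Path) -> Path:
    path = Path(path)
    rows = [{"time_s": float(t), "ge": float(g), "subject": s.subject,
             "condition": s.condition}
            for s in series for t, g in zip(s.times, s.ge)]
    pd.DataFrame(rows, columns=["time_s", "ge", "subject", "condition"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    return path


def read_ge_series_tsv(path: str | Path) -> list[EfficiencySeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (subject, condition), grp in df.groupby(["subject", "condition"], sort=True):
        out.append(EfficiencySeries(times=grp["time_s"].to_numpy(),
                                    ge=grp["ge"].to_numpy(),
                                    subject=str(subject), condition=str(condition)))
    return out


def write_cohort_tsv(records, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"subject": r.subject, "group": r.group,
             "fma": "" if r.fma is None else f"{r.fma:.4f}",
             "severity": r.severity or ""} for r in records]
    pd.DataFrame(rows, columns=["subject", "group", "fma", "severity"]).to_csv(
        path, sep="\t", index=False)
    return path


def read_cohort_tsv(path: str | Path):
    from .containers import CohortRecord

    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    records = []
    for r in df.itertuples():
        fma = None if pd.isna(r.fma) or r.fma == "" else float(r.fma)
        sev = getattr(r, "severity", None)
        sev = None if (sev is None or pd.isna(sev) or sev == "") else str(sev)
        records.append(CohortRecord(subject=str(r.subject), group=str(r.group),
                                    fma=fma, severity=sev))
    return records


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
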