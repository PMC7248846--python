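"""Signal and cohort I/O: CSV/EDF signals, JSON truth sidecars, manifests.

Signals travel as two-channel recordings.  The native on-disk form is plain
columnar CSV with a header row naming the channel and a commented first line
carrying the sampling rate (``# fs=200.0 t0=0.0``); EDF recordings are read
through :mod:`mne` when it is installed (``pip install sleepsig[edf]``).
Synthetic cohorts are written one subject per pair of files (``<id>_ecg.csv``,
``<id>_emg.csv``) plus a JSON truth sidecar and a cohort manifest CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroupLabel, GroupProfile, SyntheticRecord
from .tfa import SignalSegment

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "read_edf_channel",
    "load_channel",
    "write_record",
    "read_record",
    "write_cohort",
    "read_cohort",
]


def write_signal_csv(signal: SignalSegment, path: str | Path) -> None:
    """Write a signal as CSV: a ``# fs=... t0=...`` comment line then one column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs} t0={signal.t0}\n")
        fh.write(f"{signal.label or 'signal'}\n")
        np.savetxt(fh, signal.samples, fmt="%.6g")


def read_signal_csv(path: str | Path) -> SignalSegment:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=...' header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        label = fh.readline().strip()
        samples = np.loadtxt(fh)
    return SignalSegment(samples=samples, fs=float(meta["fs"]),
                         t0=float(meta.get("t0", 0.0)), label=label)


def read_edf_channel(path: str | Path, channel: str) -> SignalSegment:
    """Read one channel from an EDF recording (requires the ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires mne: pip install sleepsig[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True,
                              verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(f"channel {channel!r} not found in {path}")
    data = raw.get_data(picks=[channel])[0]
    return SignalSegment(samples=data, fs=float(raw.info["sfreq"]), label=channel)


def load_channel(path: str | Path, channel: str | None = None) -> SignalSegment:
    """Dispatch on extension: ``.edf`` via mne, anything else as signal CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        if channel is None:
            raise ValueError("EDF input requires a channel name")
        return read_edf_channel(path, channel)
    return read_signal_csv(path)


# --------------------------------------------------------------------------
# cohort on disk
# --------------------------------------------------------------------------

def write_record(record: SyntheticRecord, outdir: str | Path) -> dict:
    """Write one subject (two signal CSVs + truth JSON); return its manifest row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    write_signal_csv(record.ecg, outdir / f"{sid}_ecg.csv")
    write_signal_csv(record.emg, outdir / f"{sid}_emg.csv")
    with open(outdir / f"{sid}_truth.json", "w") as fh:
        json.dump(record.truth_json(), fh)
    return {"subject_id": sid, "label": record.label.value,
            "ecg": f"{sid}_ecg.csv", "emg": f"{sid}_emg.csv",
            "truth": f"{sid}_truth.json",
            "duration_s": record.ecg.duration, "fs": record.ecg.fs}


def write_cohort(records: list[SyntheticRecord], outdir: str | Path) -> Path:
    """Write every record plus ``manifest.csv``; returns the manifest path."""
    outdir = Path(outdir)
    rows = [write_record(r, outdir) for r in records]
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_record(outdir: str | Path, subject_id: str, label: str) -> SyntheticRecord:
    outdir = Path(outdir)
    ecg = read_signal_csv(outdir / f"{subject_id}_ecg.csv")
    emg = read_signal_csv(outdir / f"{subject_id}_emg.csv")
    truth_path = outdir / f"{subject_id}_truth.json"
    truth: dict = {}
    profile = GroupProfile()
    if truth_path.exists():
        with open(truth_path) as fh:
            sidecar = json.load(fh)
        truth = {k: np.asarray(v) if isinstance(v, list) and v
                 and not isinstance(v[0], list) else v
                 for k, v in sidecar["truth"].items()}
        profile = GroupProfile(**sidecar["profile"])
    return SyntheticRecord(ecg=ecg, emg=emg, truth=truth,
                           label=GroupLabel(label), subject_id=subject_id,
                           profile=profile)


def read_cohort(outdir: str | Path) -> list[SyntheticRecord]:
    """Load a cohort directory written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    return [read_record(outdir, row.subject_id, row.label)
            for row in manifest.itertuples()]
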