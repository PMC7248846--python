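"""Windowing, artifact rejection and observation assembly.

ECG and EMG are cut into 120 s windows sliding every 60 s (50% overlap).
Within each window the EMG trial is the first 24 s, subdivided into 20 s
sub-windows sliding every 2 s — exactly three sub-windows, giving the
5 (features) x 3 (sub-windows) EMG tensor that accompanies the 10-value ECG
feature vector in one classification observation.  Windows whose R-peak
detection is flagged noisy, or any of whose features are missing or
non-finite, are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (DEParams, ECG_FEATURE_NAMES, EMG_FEATURE_NAMES,
                       ecg_feature_vector, emg_feature_vector)
from .rpeak import RPeakSet, iterative_rpeak_detect
from .synthetic import GroupLabel, SyntheticRecord
from .tfa import SignalSegment

__all__ = [
    "Observation",
    "WindowPair",
    "segment_recording",
    "build_observation",
    "extract_observations",
    "observations_to_frame",
    "frame_to_arrays",
]

WINDOW_S = 120.0
STRIDE_S = 60.0
EMG_TRIAL_S = 24.0
EMG_SUB_S = 20.0
EMG_SUB_STRIDE_S = 2.0

#: EMG sub-window saturation guard: fraction of samples at the recorded
#: extremes above which a sub-window is treated as an amplitude artifact.
SATURATION_FRAC = 0.01


@dataclass
class Observation:
    """One classification unit: ECG vector (10), EMG tensor (5 x 3), label."""

    ecg_features: np.ndarray
    emg_tensor: np.ndarray
    label: GroupLabel
    subject_id: str
    window_start: float

    def __post_init__(self) -> None:
        self.ecg_features = np.asarray(self.ecg_features, dtype=float)
        self.emg_tensor = np.asarray(self.emg_tensor, dtype=float)
        if self.ecg_features.shape != (10,):
            raise ValueError("ecg_features must have shape (10,)")
        if self.emg_tensor.shape != (5, 3):
            raise ValueError("emg_tensor must have shape (5, 3)")
        self.label = GroupLabel(self.label)


@dataclass
class WindowPair:
    """An aligned 120 s ECG window and its three 20 s EMG sub-windows."""

    ecg: SignalSegment
    emg_subwindows: list[SignalSegment]
    window_start: float


def segment_recording(ecg: SignalSegment, emg: SignalSegment) -> list[WindowPair]:
    """Cut an aligned ECG/EMG recording into overlapping window pairs.

    Requires both channels at the same rate and duration.  Emits only full
    windows: a recording of ``D`` seconds yields ``floor((D - 120) / 60) + 1``
    pairs (none if ``D < 120``).
    """
    if ecg.fs != emg.fs:
        raise ValueError("ECG and EMG sampling rates differ")
    if len(ecg) != len(emg):
        raise ValueError("ECG and EMG durations differ")
    fs = ecg.fs
    win = int(round(WINDOW_S * fs))
    stride = int(round(STRIDE_S * fs))
    sub = int(round(EMG_SUB_S * fs))
    sub_stride = int(round(EMG_SUB_STRIDE_S * fs))
    n_sub = int((EMG_TRIAL_S - EMG_SUB_S) / EMG_SUB_STRIDE_S) + 1  # == 3

    pairs = []
    for start in range(0, len(ecg) - win + 1, stride):
        t_start = ecg.t0 + start / fs
        ecg_w = SignalSegment(ecg.samples[start:start + win], fs, t_start, ecg.label)
        subs = []
        for j in range(n_sub):
            s0 = start + j * sub_stride
            subs.append(SignalSegment(emg.samples[s0:s0 + sub], fs,
                                      emg.t0 + s0 / fs, emg.label))
        pairs.append(WindowPair(ecg=ecg_w, emg_subwindows=subs,
                                window_start=t_start))
    return pairs


def _saturated(x: np.ndarray) -> bool:
    rng = x.max() - x.min()
    if rng == 0:
        return True
    at_edge = (x >= x.max() - 1e-12 * rng).sum() + (x <= x.min() + 1e-12 * rng).sum()
    return at_edge / x.size > SATURATION_FRAC


def build_observation(pair: WindowPair, peaks: RPeakSet, label: GroupLabel,
                      subject_id: str, de_params: DEParams = DEParams()
                      ) -> Observation | None:
    """Assemble one observation, or ``None`` when the window is rejected.

    Rejection reasons: noisy peak quality, amplitude-saturated EMG sub-window,
    any missing or non-finite feature value.
    """
    if peaks.quality != "ok" or len(peaks) < 2:
        return None
    try:
        ecg_vec = ecg_feature_vector(peaks, pair.ecg).as_array()
    except ValueError:
        return None
    cols = []
    for sub in pair.emg_subwindows:
        if _saturated(sub.samples):
            return None
        fv = emg_feature_vector(sub, de_params)
        if fv.degenerate:
            return None
        cols.append(fv.as_array())
    emg_tensor = np.stack(cols, axis=1)  # 5 features x 3 sub-windows
    values = np.concatenate([ecg_vec, emg_tensor.ravel()])
    if not np.isfinite(values).all():
        return None
    return Observation(ecg_features=ecg_vec, emg_tensor=emg_tensor,
                       label=label, subject_id=subject_id,
                       window_start=pair.window_start)


def extract_observations(record: SyntheticRecord | tuple,
                         de_params: DEParams = DEParams(),
                         thresholds: np.ndarray | None = None
                         ) -> list[Observation]:
    """Run the full per-subject pipeline: segment, detect R peaks, featurise."""
    obs = []
    for pair in segment_recording(record.ecg, record.emg):
        peaks = iterative_rpeak_detect(pair.ecg, thresholds=thresholds)
        o = build_observation(pair, peaks, record.label, record.subject_id,
                              de_params)
        if o is not None:
            obs.append(o)
    return obs


# --------------------------------------------------------------------------
# tabular export
# --------------------------------------------------------------------------

def _emg_columns() -> list[str]:
    return [f"emg_{name}_w{j}" for name in EMG_FEATURE_NAMES for j in range(3)]


def observations_to_frame(observations: list[Observation]) -> pd.DataFrame:
    """Feature table: 10 ECG + 15 EMG columns + subject id, label, window start."""
    rows = []
    for o in observations:
        row = dict(zip(ECG_FEATURE_NAMES, o.ecg_features))
        row.update(dict(zip(_emg_columns(), o.emg_tensor.ravel())))
        row["subject_id"] = o.subject_id
        row["label"] = o.label.value
        row["window_start"] = o.window_start
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(ecg X (n,10), emg X (n,3,5), labels (n,), subjects (n,)) from a feature table.

    The EMG tensor is returned time-major for the recurrent branch: axis 1 is
    the sub-window (3 steps), axis 2 the five features.
    """
    ecg = df[list(ECG_FEATURE_NAMES)].to_numpy(float)
    emg = df[_emg_columns()].to_numpy(float).reshape(-1, 5, 3).transpose(0, 2, 1)
    labels = df["label"].to_numpy()
    subjects = df["subject_id"].to_numpy()
    return ecg, emg, labels, subjects
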