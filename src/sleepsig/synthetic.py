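"""Synthetic annotated PSG cohort: ECG + leg EMG for four subject groups.

The generator emulates the statistical structure the analysis pipeline relies
on, with exact ground truth:

* **ECG** — beats from an integrate-and-fire model around a mean heart rate,
  each beat a fixed QRS-like kernel whose amplitude is modulated by a
  breathing signal in the 0.05-1 Hz band (respiratory amplitude modulation).
  Obstructive-apnea episodes (Poisson arrivals) suppress the modulation and
  double the beat-timing jitter.  Additive white Gaussian noise.
* **EMG** — band-limited (20-95 Hz) Gaussian noise; restless-leg profiles add
  quasi-periodic raised-cosine burst envelopes of high-amplitude activity.

Groups: HEALTHY (steady breathing, no bursts), OSA (apnea episodes),
RLS (bursts), OSA_RLS (both).  Everything is driven by one seed and the
truth records (R-peak indices, breathing-frequency track, apnea and burst
intervals) are consistent with the waveforms by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from enum import Enum

import numpy as np
from scipy.signal import butter, filtfilt

from .tfa import SignalSegment

__all__ = [
    "GroupLabel",
    "GroupProfile",
    "SyntheticRecord",
    "GROUP_TEMPLATES",
    "qrs_kernel",
    "gen_ecg",
    "gen_emg",
    "gen_record",
    "gen_cohort",
]


class GroupLabel(str, Enum):
    HEALTHY = "HEALTHY"
    OSA = "OSA"
    RLS = "RLS"
    OSA_RLS = "OSA_RLS"


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one subject.

    Units: frequencies in Hz, durations in seconds, rates as stated.
    ``apnea_rate`` is episodes per minute; ``resp_mod_depth`` the fractional
    beat-amplitude swing caused by breathing; ``burst_gain`` the burst
    amplitude relative to the EMG baseline standard deviation ``noise_sd``
    (which also sets the ECG additive-noise level).
    """

    hr_mean: float = 1.0          # Hz (60 bpm)
    hr_sd: float = 0.05           # Hz beat-to-beat jitter
    breath_freq: float = 0.25     # Hz, within [0.05, 1]
    resp_mod_depth: float = 0.2   # fraction in [0, 1)
    apnea_rate: float = 0.0       # episodes / minute
    apnea_dur: float = 20.0       # s
    burst_period: float = 10.0    # s
    burst_dur: float = 2.0        # s
    burst_gain: float = 0.0       # x noise_sd
    noise_sd: float = 0.04        # signal units

    def __post_init__(self) -> None:
        if not 0 <= self.resp_mod_depth < 1:
            raise ValueError("resp_mod_depth must lie in [0, 1)")
        for name in ("hr_mean", "hr_sd", "apnea_rate", "apnea_dur",
                     "burst_period", "burst_dur", "burst_gain", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.05 <= self.breath_freq <= 1.0:
            raise ValueError("breath_freq must lie in [0.05, 1] Hz")


GROUP_TEMPLATES: dict[GroupLabel, GroupProfile] = {
    GroupLabel.HEALTHY: GroupProfile(),
    GroupLabel.OSA: GroupProfile(hr_mean=1.1, resp_mod_depth=0.25,
                                 apnea_rate=0.5, apnea_dur=20.0),
    GroupLabel.RLS: GroupProfile(hr_mean=1.0, burst_gain=4.0),
    GroupLabel.OSA_RLS: GroupProfile(hr_mean=1.1, resp_mod_depth=0.25,
                                     apnea_rate=0.5, apnea_dur=20.0,
                                     burst_gain=4.0),
}


@dataclass
class SyntheticRecord:
    """One generated subject: signals plus exact ground truth."""

    ecg: SignalSegment
    emg: SignalSegment
    truth: dict
    label: GroupLabel
    subject_id: str
    profile: GroupProfile = field(default_factory=GroupProfile)

    def truth_json(self) -> dict:
        """Truth sidecar as JSON-serialisable plain types."""
        t = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.truth.items()}
        return {"subject_id": self.subject_id, "label": self.label.value,
                "profile": asdict(self.profile), "truth": t}


# --------------------------------------------------------------------------
# ECG
# --------------------------------------------------------------------------

def qrs_kernel(fs: float) -> tuple[np.ndarray, int]:
    """A fixed QRS-like kernel (R wave with small Q/S lobes) and its peak offset."""
    tau = np.arange(-0.06, 0.06 + 0.5 / fs, 1.0 / fs)
    k = (np.exp(-0.5 * (tau / 0.010) ** 2)
         - 0.22 * np.exp(-0.5 * ((tau - 0.028) / 0.012) ** 2)
         - 0.12 * np.exp(-0.5 * ((tau + 0.025) / 0.012) ** 2))
    return k, int(np.argmax(k))


def _poisson_intervals(rng: np.random.Generator, duration: float,
                       rate_per_min: float, dur_s: float) -> list[tuple[float, float]]:
    """Non-overlapping episode intervals from Poisson arrivals."""
    if rate_per_min <= 0 or dur_s <= 0:
        return []
    out: list[tuple[float, float]] = []
    t = float(rng.exponential(60.0 / rate_per_min))
    while t < duration:
        end = min(t + dur_s, duration)
        out.append((t, end))
        t = end + float(rng.exponential(60.0 / rate_per_min))
    return out


def _in_intervals(t: np.ndarray | float, intervals: list[tuple[float, float]]):
    t = np.asarray(t, dtype=float)
    hit = np.zeros(t.shape, dtype=bool)
    for a, b in intervals:
        hit |= (t >= a) & (t < b)
    return hit


def gen_ecg(profile: GroupProfile, duration: float, fs: float = 200.0,
            seed: int | np.random.Generator = 0) -> tuple[SignalSegment, dict]:
    """Generate an ECG channel and its ground truth.

    Beat times follow an integrate-and-fire model: the i-th R-R interval is
    ``1 / f_i`` with ``f_i ~ N(hr_mean, hr_sd)`` (jitter doubled inside apnea
    episodes).  Each beat deposits the QRS kernel scaled by
    ``1 + depth(t) * sin(phase(t))`` where the breathing phase integrates a
    slowly drifting frequency track around ``breath_freq`` and ``depth`` drops
    to near zero inside apnea episodes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    apnea = _poisson_intervals(rng, duration, profile.apnea_rate, profile.apnea_dur)

    # breathing frequency track: slow +-2% sinusoidal drift, random phase;
    # disordered breathing resumes at a shifted rate (+-30%) after each apnea
    # episode, so the track is irregular between episodes
    drift_phase = rng.uniform(0, 2 * np.pi)
    base = np.full(n, profile.breath_freq)
    for _, b_end in apnea:
        mult = 1.0 + rng.uniform(-0.3, 0.3)
        base[t >= b_end] = profile.breath_freq * mult
    if apnea:  # smooth rate transitions over ~5 s
        w = int(5.0 * fs)
        kernel = np.ones(w) / w
        base = np.convolve(np.pad(base, (w // 2, w - w // 2 - 1), mode="edge"),
                           kernel, mode="valid")
    f_track = base * (1.0 + 0.02 * np.sin(2 * np.pi * t / 300.0 + drift_phase))
    f_track = np.clip(f_track, 0.05, 1.0)
    breath_phase = 2 * np.pi * np.cumsum(f_track) / fs + rng.uniform(0, 2 * np.pi)

    # beat times
    beats = []
    tb = float(rng.uniform(0.1, 0.6))
    while tb < duration - 0.1:
        beats.append(tb)
        sd = profile.hr_sd * (2.0 if _in_intervals(tb, apnea) else 1.0)
        f = rng.normal(profile.hr_mean, sd)
        f = float(np.clip(f, 0.4, 3.0))
        tb += 1.0 / f
    beat_times = np.asarray(beats)

    kernel, k_peak = qrs_kernel(fs)
    sig = np.zeros(n + kernel.size)
    depth = np.where(_in_intervals(beat_times, apnea),
                     0.02 * profile.resp_mod_depth, profile.resp_mod_depth)
    beat_samples = np.round(beat_times * fs).astype(int)
    amp = 1.0 + depth * np.sin(breath_phase[np.clip(beat_samples, 0, n - 1)])
    for s0, a in zip(beat_samples, amp):
        sig[s0:s0 + kernel.size] += a * kernel
    sig = sig[k_peak:k_peak + n]  # align so each R peak sits at its beat sample
    sig += rng.normal(0.0, profile.noise_sd, n)

    truth = {
        "rpeak_indices": beat_samples,
        "rpeak_times": beat_samples / fs,
        "rpeak_amplitudes": amp,
        "breath_freq_track": f_track,
        "apnea_intervals": [list(iv) for iv in apnea],
    }
    return SignalSegment(samples=sig, fs=fs, label="ECG"), truth


# --------------------------------------------------------------------------
# EMG
# --------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float] = (20.0, 95.0)) -> np.ndarray:
    b, a = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    x = filtfilt(b, a, rng.standard_normal(n))
    return x / x.std()


def gen_emg(profile: GroupProfile, duration: float, fs: float = 200.0,
            seed: int | np.random.Generator = 0) -> tuple[SignalSegment, dict]:
    """Generate a leg-EMG channel and its ground truth.

    Baseline: band-limited Gaussian noise with standard deviation ``noise_sd``.
    When ``burst_gain > 0`` (restless-leg profiles), raised-cosine envelopes of
    length ``burst_dur`` at quasi-periodic spacings ``burst_period`` (+-20%)
    gate additional high-amplitude band-limited activity of amplitude
    ``burst_gain * noise_sd``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    sig = profile.noise_sd * _bandlimited_noise(rng, n, fs)

    bursts: list[tuple[float, float]] = []
    if profile.burst_gain > 0 and profile.burst_dur > 0:
        env = np.zeros(n)
        tb = float(rng.uniform(0.5, profile.burst_period))
        width = int(round(profile.burst_dur * fs))
        window = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / max(width - 1, 1)))
        while tb + profile.burst_dur < duration:
            s0 = int(round(tb * fs))
            env[s0:s0 + width] = np.maximum(env[s0:s0 + width], window)
            bursts.append((tb, tb + profile.burst_dur))
            tb += profile.burst_period * (1.0 + rng.uniform(-0.2, 0.2))
        sig = sig + (profile.burst_gain * profile.noise_sd
                     * env * _bandlimited_noise(rng, n, fs))

    truth = {"burst_intervals": [list(iv) for iv in bursts]}
    return SignalSegment(samples=sig, fs=fs, label="EMG"), truth


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def gen_record(profile: GroupProfile, label: GroupLabel, subject_id: str,
               duration: float, fs: float = 200.0,
               seed: int | np.random.Generator = 0) -> SyntheticRecord:
    """Generate one subject's paired ECG/EMG record with merged truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ecg, ecg_truth = gen_ecg(profile, duration, fs, rng)
    emg, emg_truth = gen_emg(profile, duration, fs, rng)
    return SyntheticRecord(ecg=ecg, emg=emg, truth={**ecg_truth, **emg_truth},
                           label=label, subject_id=subject_id, profile=profile)


def _perturb(rng: np.random.Generator, template: GroupProfile) -> GroupProfile:
    """Per-subject variation around the group template."""
    return replace(
        template,
        hr_mean=template.hr_mean * (1.0 + rng.normal(0, 0.05)),
        hr_sd=template.hr_sd * (1.0 + rng.uniform(-0.2, 0.2)),
        breath_freq=float(np.clip(template.breath_freq + rng.normal(0, 0.02),
                                  0.08, 0.6)),
        resp_mod_depth=float(np.clip(template.resp_mod_depth
                                     * (1.0 + rng.normal(0, 0.1)), 0.05, 0.6)),
        burst_period=template.burst_period * (1.0 + rng.uniform(-0.1, 0.1)),
    )


def gen_cohort(n_per_group: int = 10, duration: float = 1800.0,
               seed: int = 0, fs: float = 200.0,
               templates: dict[GroupLabel, GroupProfile] | None = None
               ) -> list[SyntheticRecord]:
    """Generate a balanced four-group cohort with unique subject ids.

    Defaults mirror the study design this pipeline targets: 10 subjects per
    group.  Per-subject profiles are drawn around the group templates so
    subjects differ within a group (required for meaningful cross-subject
    evaluation).
    """
    templates = templates or GROUP_TEMPLATES
    master = np.random.default_rng(seed)
    records = []
    sid = 0
    for label in GroupLabel:
        template = templates[label]
        for _ in range(n_per_group):
            sid += 1
            profile = _perturb(master, template)
            sub_seed = int(master.integers(0, 2**31 - 1))
            records.append(gen_record(profile, label, f"S{sid:02d}",
                                      duration, fs, np.random.default_rng(sub_seed)))
    return records
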