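"""Synthetic multimodal subject records with condition-dependent structure.

The generator emulates the shape of a wearable-study record — the chest
channel set at 700 Hz, the wrist set at 64/32/4/4 Hz and a 700 Hz label
track following a (condition, duration) schedule exactly — with deliberately
minimal signal realism: periodic pulse templates for ECG/BVP, tonic level
plus exponential-decay phasic events for EDA, a sinusoid for respiration,
variance-coded noise for EMG and ACC, and a slow drift for temperature.
What matters is that the three study conditions differ in their signal
statistics (heart rate, electrodermal tone and event rate, breathing rate,
movement variance) so the full pipeline is exercised end to end and the
classification task is learnable but not single-channel trivial: stress and
amusement are separated on EDA and pulse rate while overlapping on skin
temperature.

Everything is deterministic per (seed, subject_index); per-subject parameter
jitter models inter-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .wesad import (CHEST_RATE, WRIST_RATES, ChannelSeries, SubjectRecord,
                    validate_record)

__all__ = [
    "ConditionParams",
    "SyntheticSpec",
    "DEFAULT_CONDITIONS",
    "generate_subject",
    "generate_dataset",
    "estimate_pulse_bpm",
]


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition signal statistics.

    Units: pulse_bpm beats/min; eda_tonic microsiemens; eda_event_rate
    events/s; resp_bpm breaths/min; temp_base °C with temp_drift °C/min;
    acc_sd and emg_sd in arbitrary sensor units.
    """

    pulse_bpm: float
    eda_tonic: float
    eda_event_rate: float
    resp_bpm: float
    temp_base: float
    temp_drift: float
    acc_sd: float
    emg_sd: float


#: Defaults keyed by condition code (1 baseline, 2 stress, 3 amusement).
#: Chosen for physiological plausibility: stress raises heart rate,
#: electrodermal tone/event rate, breathing rate and muscle tone; amusement
#: sits between, but shares the slightly elevated skin temperature of stress
#: so no single slow channel separates those two conditions.
DEFAULT_CONDITIONS: Dict[int, ConditionParams] = {
    1: ConditionParams(pulse_bpm=65.0, eda_tonic=2.0, eda_event_rate=0.05,
                       resp_bpm=14.0, temp_base=34.0, temp_drift=0.0,
                       acc_sd=0.05, emg_sd=0.10),
    2: ConditionParams(pulse_bpm=90.0, eda_tonic=8.0, eda_event_rate=0.30,
                       resp_bpm=20.0, temp_base=34.4, temp_drift=0.02,
                       acc_sd=0.15, emg_sd=0.30),
    3: ConditionParams(pulse_bpm=75.0, eda_tonic=5.0, eda_event_rate=0.15,
                       resp_bpm=16.0, temp_base=34.4, temp_drift=0.0,
                       acc_sd=0.10, emg_sd=0.15),
}

DEFAULT_NOISE_SD: Dict[str, float] = {
    "ECG": 0.05, "EDA": 0.05, "EMG": 0.0, "RESP": 0.05, "TEMP": 0.01,
    "ACC": 0.0, "BVP": 0.05,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters: schedule, per-condition statistics, noise, seed.

    The default schedule — 60 s each of baseline, stress and amusement per
    subject, 6 subjects — is the scaled-down study condition every end-to-end
    check runs under.
    """

    n_subjects: int = 6
    schedule: Tuple[Tuple[int, float], ...] = ((1, 60.0), (2, 60.0), (3, 60.0))
    conditions: Dict[int, ConditionParams] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS))
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    subject_variability: float = 0.05  # relative sd of per-subject jitter
    beat_jitter: float = 0.02          # relative sd of beat-interval jitter
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.schedule:
            raise ValueError("schedule is empty")
        for cond, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"schedule duration for condition {cond} "
                                 "must be positive")
            if cond not in self.conditions:
                raise ValueError(f"no parameters for condition {cond}")
        for cond, p in self.conditions.items():
            if not (20.0 <= p.pulse_bpm <= 220.0):
                raise ValueError(f"condition {cond}: pulse {p.pulse_bpm} bpm "
                                 "outside the physiological 20-220 range")
            if not (4.0 <= p.resp_bpm <= 60.0):
                raise ValueError(f"condition {cond}: breathing {p.resp_bpm} "
                                 "breaths/min outside the 4-60 range")
        if self.subject_variability < 0 or self.beat_jitter < 0:
            raise ValueError("variability parameters must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.schedule))


# ---------------------------------------------------------------------------
# per-channel signal builders (one condition segment at a time)


def _pulse_train(rng: np.random.Generator, duration: float, rate: float,
                 bpm: float, width_s: float, jitter: float) -> np.ndarray:
    """Sum of Gaussian pulse templates at the given beat rate."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    period = 60.0 / bpm
    beat = period / 2.0  # first beat away from the segment edge
    while beat < duration:
        out += np.exp(-0.5 * ((t - beat) / width_s) ** 2)
        beat += period * (1.0 + jitter * rng.standard_normal())
    return out


def _eda(rng: np.random.Generator, duration: float, rate: float,
         tonic: float, event_rate: float, tau: float = 2.0,
         amp: float = 0.6) -> np.ndarray:
    """Tonic level plus Poisson-arriving exponential-decay phasic events."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    out = np.full(n, tonic)
    n_events = rng.poisson(event_rate * duration)
    for t0 in np.sort(rng.uniform(0.0, duration, size=n_events)):
        mask = t >= t0
        out[mask] += amp * np.exp(-(t[mask] - t0) / tau)
    return out


def _segment(rng: np.random.Generator, name: str, rate: float, duration: float,
             p: ConditionParams, noise_sd: Dict[str, float],
             beat_jitter: float = 0.0) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if name == "ECG":
        sig = _pulse_train(rng, duration, rate, p.pulse_bpm, 0.02, beat_jitter)
    elif name == "BVP":
        sig = _pulse_train(rng, duration, rate, p.pulse_bpm, 0.08, beat_jitter)
    elif name == "EDA":
        sig = _eda(rng, duration, rate, p.eda_tonic, p.eda_event_rate)
    elif name == "RESP":
        sig = np.sin(2.0 * np.pi * (p.resp_bpm / 60.0) * t)
    elif name == "TEMP":
        sig = p.temp_base + (p.temp_drift / 60.0) * t
    elif name == "EMG":
        sig = p.emg_sd * rng.standard_normal(n)
    elif name.startswith("ACC"):
        offset = 1.0 if name == "ACC_Z" else 0.0  # gravity on one axis
        sig = offset + p.acc_sd * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown channel {name!r}")
    key = "ACC" if name.startswith("ACC") else name
    sd = noise_sd.get(key, 0.0)
    if sd > 0:
        sig = sig + sd * rng.standard_normal(n)
    return sig


def _jittered(rng: np.random.Generator, p: ConditionParams,
              rel_sd: float) -> ConditionParams:
    if rel_sd == 0:
        return p
    def j(v, lo=None, hi=None):
        out = v * (1.0 + rel_sd * rng.standard_normal())
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out
    return replace(p,
                   pulse_bpm=j(p.pulse_bpm, 20.0, 220.0),
                   eda_tonic=j(p.eda_tonic, 0.05),
                   eda_event_rate=j(p.eda_event_rate, 0.0),
                   resp_bpm=j(p.resp_bpm, 4.0, 60.0),
                   temp_base=p.temp_base + 0.2 * rel_sd / 0.05 * rng.standard_normal()
                   if rel_sd > 0 else p.temp_base,
                   acc_sd=j(p.acc_sd, 1e-4),
                   emg_sd=j(p.emg_sd, 1e-4))


# ---------------------------------------------------------------------------
# generators


def generate_subject(spec: SyntheticSpec, subject_index: int = 0) -> SubjectRecord:
    """One synthetic subject record, deterministic per (spec.seed, index).

    Per-subject condition parameters are jittered by
    ``spec.subject_variability``; beat intervals additionally carry
    ``spec.beat_jitter``. The label track follows the schedule exactly.
    """
    param_rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, subject_index, 0)))
    params = {cond: _jittered(param_rng, p, spec.subject_variability)
              for cond, p in spec.conditions.items()}

    chest_names = ("ECG", "EDA", "EMG", "RESP", "TEMP",
                   "ACC_X", "ACC_Y", "ACC_Z")
    wrist_names = tuple(sorted(WRIST_RATES))
    chest_parts: Dict[str, List[np.ndarray]] = {n: [] for n in chest_names}
    wrist_parts: Dict[str, List[np.ndarray]] = {n: [] for n in wrist_names}
    label_parts: List[np.ndarray] = []

    # stable per-(site, channel, segment) seed keys — no string hashing, so
    # records are identical across processes
    for seg_idx, (cond, dur) in enumerate(spec.schedule):
        p = params[cond]
        for site_idx, (names, rate_of, parts) in enumerate((
                (chest_names, lambda n: CHEST_RATE, chest_parts),
                (wrist_names, WRIST_RATES.__getitem__, wrist_parts))):
            for ch_idx, name in enumerate(names):
                rng_ch = np.random.default_rng(np.random.SeedSequence(
                    (spec.seed, subject_index, 1 + site_idx, ch_idx, seg_idx)))
                parts[name].append(
                    _segment(rng_ch, name, rate_of(name), dur, p,
                             spec.noise_sd, spec.beat_jitter))
        label_parts.append(np.full(int(round(dur * CHEST_RATE)), cond))

    chest = {name: ChannelSeries(name, CHEST_RATE, np.concatenate(parts))
             for name, parts in chest_parts.items()}
    wrist = {name: ChannelSeries(name, WRIST_RATES[name], np.concatenate(parts))
             for name, parts in wrist_parts.items()}
    labels = ChannelSeries("label", CHEST_RATE, np.concatenate(label_parts))

    record = SubjectRecord(f"SYN{subject_index:02d}", chest, wrist, labels,
                           meta={"synthetic": True, "seed": spec.seed,
                                 "subject_index": subject_index})
    diags = validate_record(record)
    if diags:  # a generator bug, not a user error
        raise AssertionError(f"generated record failed validation: {diags}")
    return record


def generate_dataset(spec: SyntheticSpec) -> List[SubjectRecord]:
    """n_subjects records with per-subject seeds derived from the master seed."""
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


# ---------------------------------------------------------------------------
# parameter-recovery helper


def estimate_pulse_bpm(values: np.ndarray, rate: float) -> float:
    """Recover the beat rate of a pulse-template signal by peak counting."""
    values = np.asarray(values, dtype=float)
    height = values.min() + 0.5 * (values.max() - values.min())
    min_dist = max(1, int(rate * 0.25))  # no physiological rhythm above 240 bpm
    peaks, _ = find_peaks(values, height=height, distance=min_dist)
    duration = len(values) / rate
    return 60.0 * len(peaks) / duration
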