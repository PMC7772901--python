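"""Fixed-duration windowing of multi-rate records, label mapping and splits.

Records are cut into 5 s windows by default, stride equal to the window
(non-overlapping), each channel sliced at its native rate — a 5 s chest
window is 3500 samples per channel, a wrist window is 320 (BVP) / 160 per
ACC axis / 20 (EDA) / 20 (TEMP).  A window is emitted only when its 700 Hz
label slice is pure enough: the modal condition code must be a study
condition and occupy at least ``purity`` of the slice (default 1.0, i.e.
single-condition windows only).

Task mapping: three-class → baseline 0, stress 1, amusement 2; binary →
stress 1, {baseline, amusement} 0.  Splits are window-level by default (the
whole window pool is scrambled before the 7:3 partition), with a stricter
subject-level option; tenfold cross-validation folds are balanced to within
one window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .wesad import LABEL_CODES, STUDY_CONDITIONS, SubjectRecord

__all__ = [
    "Window",
    "WindowSet",
    "segment_record",
    "assign_window_condition",
    "map_task_labels",
    "scramble_split",
    "make_folds",
]

WRIST_ACC_AXES = ("ACC_X", "ACC_Y", "ACC_Z")


@dataclass
class Window:
    """One fixed-duration slice: per-channel vectors at native rates."""

    subject_id: str
    t_start: float
    signals: Dict[str, np.ndarray]
    condition: int


@dataclass
class WindowSet:
    """An ordered window collection, optionally task-mapped.

    ``task`` is ``None`` until :func:`map_task_labels` runs; afterwards
    ``labels[i]`` is the integer task label of ``windows[i]`` and ``meta``
    records the mapping and the number of dropped windows.
    """

    windows: List[Window]
    site: str
    window_s: float
    task: Optional[str] = None
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def channel_names(self) -> Tuple[str, ...]:
        if not self.windows:
            return ()
        return tuple(self.windows[0].signals)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([w.condition for w in self.windows], dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return np.array([w.subject_id for w in self.windows])

    def channel_matrix(self, name: str) -> np.ndarray:
        """Stack one channel across windows → (n_windows, samples)."""
        return np.stack([w.signals[name] for w in self.windows])

    def subset(self, indices: Sequence[int]) -> "WindowSet":
        idx = np.asarray(indices, dtype=int)
        labels = None if self.labels is None else self.labels[idx]
        return WindowSet([self.windows[i] for i in idx], self.site,
                         self.window_s, self.task, labels, dict(self.meta))

    # -- serialization (npz with an embedded JSON manifest) ------------------

    def save(self, path) -> None:
        arrays = {f"ch_{name}": self.channel_matrix(name)
                  for name in self.channel_names}
        manifest = {"site": self.site, "window_s": self.window_s,
                    "task": self.task, "meta": self.meta,
                    "channels": list(self.channel_names)}
        arrays["subjects"] = self.subjects
        arrays["t_start"] = np.array([w.t_start for w in self.windows])
        arrays["conditions"] = self.conditions
        if self.labels is not None:
            arrays["labels"] = self.labels
        arrays["manifest"] = np.array(json.dumps(manifest))
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "WindowSet":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            subjects = z["subjects"]
            t_start = z["t_start"]
            conditions = z["conditions"]
            labels = z["labels"] if "labels" in z else None
            mats = {name: z[f"ch_{name}"] for name in manifest["channels"]}
        windows = [Window(str(subjects[i]), float(t_start[i]),
                          {name: mats[name][i] for name in mats},
                          int(conditions[i]))
                   for i in range(len(subjects))]
        return cls(windows, manifest["site"], manifest["window_s"],
                   manifest["task"], labels, manifest["meta"])


# ---------------------------------------------------------------------------


def assign_window_condition(label_slice: np.ndarray, purity: float = 1.0,
                            accepted: Sequence[int] = STUDY_CONDITIONS) -> Optional[int]:
    """Modal condition of a label slice, or ``None`` if the window is rejected.

    The modal code wins iff it is in ``accepted`` and covers at least
    ``purity`` of the slice.
    """
    codes = np.asarray(label_slice, dtype=int)
    if codes.size == 0:
        raise ValueError("empty label slice")
    counts = np.bincount(codes)
    mode = int(counts.argmax())
    if mode not in accepted:
        return None
    if counts[mode] / codes.size < purity:
        return None
    return mode


def segment_record(record: SubjectRecord, window_s: float = 5.0,
                   stride_s: float = 5.0, site: str = "chest",
                   include_acc: bool = True, purity: float = 1.0,
                   accepted: Sequence[int] = STUDY_CONDITIONS) -> WindowSet:
    """Cut one record into fixed-duration windows with one condition each.

    Windows start at t = 0, stride_s, 2·stride_s, …; a window is emitted only
    if every channel of the chosen site has a full-length slice and the label
    slice passes :func:`assign_window_condition`.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be positive")
    if site not in ("chest", "wrist"):
        raise ValueError(f"unknown site {site!r}")
    channels = record.chest if site == "chest" else record.wrist
    if not include_acc:
        channels = {k: v for k, v in channels.items() if not k.startswith("ACC")}
    if min(ch.rate for ch in channels.values()) * window_s < 1:
        raise ValueError(
            f"window of {window_s} s holds no samples at the slowest rate")

    lab = record.labels
    n_lab_win = int(round(lab.rate * window_s))
    lengths = {name: int(round(ch.rate * window_s))
               for name, ch in channels.items()}

    windows: List[Window] = []
    t = 0.0
    while True:
        lab_start = int(round(lab.rate * t))
        if lab_start + n_lab_win > len(lab.values):
            break
        ok = True
        signals: Dict[str, np.ndarray] = {}
        for name, ch in channels.items():
            start = int(round(ch.rate * t))
            stop = start + lengths[name]
            if stop > len(ch.values):
                ok = False
                break
            signals[name] = ch.values[start:stop]
        if ok:
            cond = assign_window_condition(
                lab.values[lab_start:lab_start + n_lab_win], purity, accepted)
            if cond is not None:
                windows.append(Window(record.subject_id, t, signals, cond))
        t += stride_s
    return WindowSet(windows, site, window_s,
                     meta={"stride_s": stride_s, "purity": purity,
                           "include_acc": include_acc})


def segment_records(records: Sequence[SubjectRecord], **kwargs) -> WindowSet:
    """Segment several records and pool their windows into one set."""
    pooled: Optional[WindowSet] = None
    for rec in records:
        ws = segment_record(rec, **kwargs)
        if pooled is None:
            pooled = ws
        else:
            pooled.windows.extend(ws.windows)
    return pooled if pooled is not None else WindowSet([], "chest", 5.0)


THREE_CLASS_MAP = {1: 0, 2: 1, 3: 2}   # baseline, stress, amusement
BINARY_MAP = {1: 0, 2: 1, 3: 0}        # stress vs non-stress (incl. amusement)


def map_task_labels(ws: WindowSet, task: str) -> WindowSet:
    """Map condition codes to task labels; drop unmappable windows.

    three_class: baseline→0, stress→1, amusement→2.
    binary: stress→1, baseline and amusement→0.
    """
    if ws.task is not None:
        raise ValueError("WindowSet is already task-mapped")
    if task == "three_class":
        mapping = THREE_CLASS_MAP
    elif task == "binary":
        mapping = BINARY_MAP
    else:
        raise ValueError(f"unknown task {task!r}")
    # documented-but-unmodelled codes (transient, meditation, ...) are
    # dropped; anything outside the documented set is an error
    known = set(LABEL_CODES) | set(mapping)
    kept, labels, dropped = [], [], 0
    for w in ws.windows:
        if w.condition in mapping:
            kept.append(w)
            labels.append(mapping[w.condition])
        elif w.condition in known:
            dropped += 1
        else:
            raise ValueError(f"unknown condition code {w.condition}")
    meta = dict(ws.meta)
    meta.update({"mapping": {str(k): v for k, v in mapping.items()},
                 "dropped": dropped})
    return WindowSet(kept, ws.site, ws.window_s, task,
                     np.array(labels, dtype=int), meta)


def scramble_split(ws: WindowSet, train_fraction: float = 0.7,
                   seed: int = 0, level: str = "window") -> Tuple[WindowSet, WindowSet]:
    """Randomly scramble the windows and partition them 7:3 by default.

    ``level='window'`` scrambles the pooled windows (a subject's windows can
    land on both sides); ``level='subject'`` keeps each subject entirely on
    one side, the stricter alternative.
    """
    if ws.task is None:
        raise ValueError("map task labels before splitting")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ws)
    if n < 2:
        raise ValueError("need at least 2 windows to split")
    rng = np.random.default_rng(seed)
    if level == "window":
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        return ws.subset(perm[:n_train]), ws.subset(perm[n_train:])
    if level == "subject":
        subjects = ws.subjects
        order = rng.permutation(np.unique(subjects))
        target = train_fraction * n
        train_subjects, count = [], 0
        for i, s in enumerate(order):
            if count >= target:
                break
            if i == len(order) - 1 and train_subjects:
                break  # always keep at least one subject on the test side
            train_subjects.append(s)
            count += int(np.sum(subjects == s))
        mask = np.isin(subjects, train_subjects)
        if mask.all() or not mask.any():
            raise ValueError("subject-level split needs at least 2 subjects")
        return ws.subset(np.flatnonzero(mask)), ws.subset(np.flatnonzero(~mask))
    raise ValueError(f"unknown split level {level!r}")


def make_folds(ws: WindowSet, k: int = 10,
               seed: int = 0) -> List[Tuple[WindowSet, WindowSet]]:
    """k scrambled cross-validation folds; test folds partition the set.

    Fold sizes differ by at most one window; deterministic per seed.
    """
    n = len(ws)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} windows")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = []
    for test_idx in np.array_split(perm, k):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        folds.append((ws.subset(np.flatnonzero(mask)), ws.subset(test_idx)))
    return folds
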