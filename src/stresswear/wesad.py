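"""Reading, validating and round-tripping multi-rate subject records.

A subject record bundles the chest-worn channel set (ECG, EDA, EMG,
respiration, skin temperature and the three accelerometer axes, all sampled
at 700 Hz), the wrist-worn set (BVP at 64 Hz, three ACC axes at 32 Hz, EDA
and skin temperature at 4 Hz) and a 700 Hz condition-label track.  Two
on-disk layouts are supported:

* the WESAD dataset's native per-subject pickle (a dict with ``signal``,
  ``label`` and ``subject`` keys, chest signals as ``(N, 1)`` / ``(N, 3)``
  arrays) — ``read_wesad_subject``;
* a self-describing columnar text fixture used by the tests and the synthetic
  generator — ``write_subject_fixture`` / ``read_subject_fixture``.

Label codes follow the dataset documentation: 0 undefined/transient,
1 baseline, 2 stress, 3 amusement, 4 meditation, 5–7 unused. Only {1, 2, 3}
are study conditions; everything else is excluded from modelling by default.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np

__all__ = [
    "ChannelSeries",
    "SubjectRecord",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "LABEL_CODES",
    "STUDY_CONDITIONS",
    "CHEST_RATE",
    "WRIST_RATES",
    "read_wesad_subject",
    "write_wesad_native",
    "write_subject_fixture",
    "read_subject_fixture",
    "validate_record",
]

CHEST_RATE = 700.0
WRIST_RATES = {"BVP": 64.0, "ACC_X": 32.0, "ACC_Y": 32.0, "ACC_Z": 32.0,
               "EDA": 4.0, "TEMP": 4.0}
CHEST_CHANNELS = ("ECG", "EDA", "EMG", "RESP", "TEMP", "ACC_X", "ACC_Y", "ACC_Z")
WRIST_CHANNELS = ("BVP", "ACC_X", "ACC_Y", "ACC_Z", "EDA", "TEMP")

#: condition codes documented for the dataset
LABEL_CODES = frozenset(range(8))
#: baseline / stress / amusement — the conditions the models are trained on
STUDY_CONDITIONS = (1, 2, 3)
CONDITION_NAMES = {1: "baseline", 2: "stress", 3: "amusement"}


class SchemaError(KeyError):
    """A required channel or key is absent from a record file."""


class ValidationError(ValueError):
    """A record violates a structural invariant (lengths, rates, codes)."""


class ParseError(ValueError):
    """A fixture file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class ChannelSeries:
    """One channel: a name, a sampling rate in Hz, and its ordered samples."""

    name: str
    rate: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValidationError(f"channel {self.name}: rate must be > 0")

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def __eq__(self, other) -> bool:
        return (isinstance(other, ChannelSeries)
                and self.name == other.name
                and self.rate == other.rate
                and self.values.shape == other.values.shape
                and bool(np.array_equal(self.values, other.values)))


@dataclass
class SubjectRecord:
    """One participant's chest + wrist channels and 700 Hz label track."""

    subject_id: str
    chest: Dict[str, ChannelSeries]
    wrist: Dict[str, ChannelSeries]
    labels: ChannelSeries
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        """Record duration in seconds, derived from the label track."""
        return self.labels.duration

    def __eq__(self, other) -> bool:
        return (isinstance(other, SubjectRecord)
                and self.subject_id == other.subject_id
                and self.chest == other.chest
                and self.wrist == other.wrist
                and self.labels == other.labels)


# ---------------------------------------------------------------------------
# validation


def validate_record(record: SubjectRecord) -> List[str]:
    """Check every structural invariant; return a diagnostic per violation.

    An empty list means the record is internally consistent: all chest
    channels share one rate and one length equal to the label track, wrist
    channel lengths match rate × duration within one sample, all values are
    finite and all label codes belong to the documented code set.
    """
    diags: List[str] = []
    labels = record.labels
    n_lab = len(labels.values)
    duration = labels.duration

    codes = np.unique(labels.values.astype(int))
    bad = [int(c) for c in codes if int(c) not in LABEL_CODES]
    if bad:
        diags.append(f"labels: unknown condition code(s) {bad}")
    if not np.array_equal(labels.values, labels.values.astype(int)):
        diags.append("labels: non-integer label values")

    missing = [c for c in CHEST_CHANNELS if c not in record.chest]
    if missing:
        diags.append(f"chest: missing channel(s) {missing}")
    rates = {ch.rate for ch in record.chest.values()}
    if len(rates) > 1:
        diags.append(f"chest: channels disagree on rate {sorted(rates)}")
    for name, ch in record.chest.items():
        if not np.all(np.isfinite(ch.values)):
            diags.append(f"chest/{name}: non-finite samples")
        if len(ch.values) != n_lab:
            diags.append(
                f"chest/{name}: length {len(ch.values)} != label track {n_lab}")

    missing = [c for c in WRIST_CHANNELS if c not in record.wrist]
    if missing:
        diags.append(f"wrist: missing channel(s) {missing}")
    for name, ch in record.wrist.items():
        if not np.all(np.isfinite(ch.values)):
            diags.append(f"wrist/{name}: non-finite samples")
        expected = ch.rate * duration
        if abs(len(ch.values) - expected) > 1.0:
            diags.append(
                f"wrist/{name}: length {len(ch.values)} inconsistent with "
                f"rate {ch.rate} Hz x duration {duration:.6g} s "
                f"(expected {expected:.6g} +/- 1)")
    return diags


def _validated(record: SubjectRecord) -> SubjectRecord:
    diags = validate_record(record)
    if diags:
        raise ValidationError("; ".join(diags))
    return record


# ---------------------------------------------------------------------------
# WESAD native pickle layout


def _split_acc(values: np.ndarray, where: str) -> Dict[str, np.ndarray]:
    """Normalize nested (N, 3) or flat (3N,) ACC encodings to per-axis arrays."""
    arr = np.asarray(values)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return {"ACC_X": arr[:, 0], "ACC_Y": arr[:, 1], "ACC_Z": arr[:, 2]}
    if arr.ndim == 1 and arr.size % 3 == 0:
        arr = arr.reshape(-1, 3)
        return {"ACC_X": arr[:, 0], "ACC_Y": arr[:, 1], "ACC_Z": arr[:, 2]}
    raise ValidationError(f"{where}/ACC: cannot interpret shape {arr.shape}")


def read_wesad_subject(path) -> SubjectRecord:
    """Read one subject's record in the dataset's native pickled layout.

    Channel names are normalized (``Temp``→``TEMP``, ``Resp``→``RESP``) and the
    3-axis accelerometer is split into three separate axis channels.  The
    returned record always passes :func:`validate_record`, or this raises.
    """
    path = Path(path)
    with open(path, "rb") as fh:  # FileNotFoundError propagates as the I/O error
        raw = pickle.load(fh, encoding="latin1")
    try:
        signal = raw["signal"]
        label = np.asarray(raw["label"]).ravel()
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: missing top-level key {exc}") from exc
    subject_id = str(raw.get("subject", path.stem))

    name_map_chest = {"ECG": "ECG", "EDA": "EDA", "EMG": "EMG",
                      "Resp": "RESP", "Temp": "TEMP"}
    chest_raw = signal.get("chest")
    wrist_raw = signal.get("wrist")
    if chest_raw is None:
        raise SchemaError(f"{path}: missing 'chest' signal group")
    if wrist_raw is None:
        raise SchemaError(f"{path}: missing 'wrist' signal group")

    chest: Dict[str, ChannelSeries] = {}
    for native, norm in name_map_chest.items():
        if native not in chest_raw:
            raise SchemaError(f"{path}: missing chest channel {native!r}")
        chest[norm] = ChannelSeries(norm, CHEST_RATE, chest_raw[native])
    if "ACC" not in chest_raw:
        raise SchemaError(f"{path}: missing chest channel 'ACC'")
    for axis, vals in _split_acc(chest_raw["ACC"], "chest").items():
        chest[axis] = ChannelSeries(axis, CHEST_RATE, vals)

    wrist: Dict[str, ChannelSeries] = {}
    for native in ("BVP", "EDA", "TEMP"):
        if native not in wrist_raw:
            raise SchemaError(f"{path}: missing wrist channel {native!r}")
        wrist[native] = ChannelSeries(native, WRIST_RATES[native], wrist_raw[native])
    if "ACC" not in wrist_raw:
        raise SchemaError(f"{path}: missing wrist channel 'ACC'")
    for axis, vals in _split_acc(wrist_raw["ACC"], "wrist").items():
        wrist[axis] = ChannelSeries(axis, WRIST_RATES[axis], vals)

    labels = ChannelSeries("label", CHEST_RATE, label)
    return _validated(SubjectRecord(subject_id, chest, wrist, labels))


def write_wesad_native(record: SubjectRecord, path) -> None:
    """Serialize a record back into the dataset's native pickled layout."""
    chest = {
        "ECG": record.chest["ECG"].values[:, None],
        "EDA": record.chest["EDA"].values[:, None],
        "EMG": record.chest["EMG"].values[:, None],
        "Resp": record.chest["RESP"].values[:, None],
        "Temp": record.chest["TEMP"].values[:, None],
        "ACC": np.column_stack([record.chest[a].values
                                for a in ("ACC_X", "ACC_Y", "ACC_Z")]),
    }
    wrist = {
        "BVP": record.wrist["BVP"].values[:, None],
        "EDA": record.wrist["EDA"].values[:, None],
        "TEMP": record.wrist["TEMP"].values[:, None],
        "ACC": np.column_stack([record.wrist[a].values
                                for a in ("ACC_X", "ACC_Y", "ACC_Z")]),
    }
    blob = {"subject": record.subject_id,
            "signal": {"chest": chest, "wrist": wrist},
            "label": record.labels.values.astype(int)}
    with open(path, "wb") as fh:
        pickle.dump(blob, fh)


# ---------------------------------------------------------------------------
# columnar text fixture format
#
#   #stresswear-fixture v1
#   #subject S1
#   #channel chest/ECG 700 1400
#   #channel label 700 1400
#   #data
#   <one row per sample index; one column per declared channel; cells past a
#    channel's length are the pad marker '.'>

_PAD = "."


def _fmt(v: float) -> str:
    # repr of a Python float is the shortest exact round-trip representation
    return repr(float(v))


def write_subject_fixture(record: SubjectRecord, path) -> None:
    """Write a record as self-describing columnar text (lossless round trip)."""
    cols: List[np.ndarray] = []
    header = ["#stresswear-fixture v1", f"#subject {record.subject_id}"]
    for site, chans in (("chest", record.chest), ("wrist", record.wrist)):
        for name in sorted(chans):
            ch = chans[name]
            header.append(f"#channel {site}/{name} {ch.rate:g} {len(ch.values)}")
            cols.append(ch.values)
    header.append(f"#channel label {record.labels.rate:g} {len(record.labels.values)}")
    cols.append(record.labels.values)
    header.append("#data")

    n_rows = max(len(c) for c in cols)
    label_idx = len(cols) - 1
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(n_rows):
            cells = []
            for j, c in enumerate(cols):
                if i < len(c):
                    cells.append(str(int(c[i])) if j == label_idx else _fmt(c[i]))
                else:
                    cells.append(_PAD)
            fh.write("\t".join(cells) + "\n")


def read_subject_fixture(path) -> SubjectRecord:
    """Parse a columnar text fixture back into a validated record."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#stresswear-fixture"):
        raise ParseError("missing '#stresswear-fixture' magic header", 1)

    subject_id = "unknown"
    decls: List[tuple] = []  # (site, name, rate, n)
    data_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("#subject "):
            subject_id = line.split(maxsplit=1)[1]
        elif line.startswith("#channel "):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"malformed channel declaration {line!r}", ln)
            ident = parts[1]
            try:
                rate, n = float(parts[2]), int(parts[3])
            except ValueError:
                raise ParseError(f"bad rate/count in {line!r}", ln) from None
            if ident == "label":
                site, name = "label", "label"
            elif "/" in ident:
                site, name = ident.split("/", 1)
            else:
                raise ParseError(f"channel identifier {ident!r} lacks site", ln)
            decls.append((site, name, rate, n))
        elif line.strip() == "#data":
            data_start = ln
            break
        else:
            raise ParseError(f"unexpected header line {line!r}", ln)
    if data_start is None:
        raise ParseError("missing '#data' separator", len(lines))
    if not any(d[0] == "label" for d in decls):
        raise SchemaError(f"{path}: fixture declares no label channel")

    n_cols = len(decls)
    columns: List[List[str]] = [[] for _ in decls]
    for ln, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"expected {n_cols} columns, found {len(cells)}", ln)
        for col, cell in zip(columns, cells):
            if cell != _PAD:
                col.append(cell)

    chest: Dict[str, ChannelSeries] = {}
    wrist: Dict[str, ChannelSeries] = {}
    labels = None
    for (site, name, rate, n), col in zip(decls, columns):
        if len(col) != n:
            raise ParseError(
                f"channel {site}/{name}: declared {n} samples, found {len(col)}",
                data_start)
        try:
            vals = np.array([float(v) for v in col])
        except ValueError as exc:
            raise ParseError(f"channel {site}/{name}: {exc}", data_start) from None
        series = ChannelSeries(name, rate, vals)
        if site == "chest":
            chest[name] = series
        elif site == "wrist":
            wrist[name] = series
        elif site == "label":
            labels = ChannelSeries("label", rate, vals)
        else:
            raise ParseError(f"unknown site {site!r}", data_start)

    return _validated(SubjectRecord(subject_id, chest, wrist, labels))
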