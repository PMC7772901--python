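"""Training protocol, metrics, and the end-to-end synthetic benchmark.

The protocol mirrors the study design: the pooled window set is randomly
scrambled and split 7:3 into training and testing portions; tenfold
cross-validation on the training portion provides model-selection telemetry;
the network is then refit on the full training portion and the reported
metrics come from the 30% hold-out.  Training uses Adam (learning rate
0.001), binary or categorical cross-entropy bound to the task, 100 epochs
and batch size 40 by default.

Metrics: accuracy = (TP + TN) / total; precision = TP / (TP + FP); recall =
TP / (TP + FN); F1 = 2·precision·recall / (precision + recall).  Multi-class
reports use per-class one-vs-rest scores with macro (plus micro and
weighted) aggregates; undefined ratios are 0 by convention.

Per-channel z-scoring (statistics from the training split only) is applied
by default: raw channels differ in scale by orders of magnitude, and a
scalar mean/sd per channel preserves the between-window differences the
classifier needs.  ``normalize=False`` trains on raw values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .models import ModelGraph, instantiate
from .windowing import WRIST_ACC_AXES, WindowSet, make_folds, scramble_split

__all__ = [
    "TrainConfig",
    "EvalReport",
    "FittedModel",
    "ProtocolResult",
    "train_model",
    "evaluate_model",
    "metrics_from_confusion",
    "run_protocol",
    "branch_inputs",
    "synthetic_benchmark",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (defaults follow the study protocol)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 40
    loss: Optional[str] = None  # bound to the task when None
    seed: int = 0
    cv_folds: int = 10          # 0 disables the CV telemetry in run_protocol
    train_fraction: float = 0.7
    normalize: bool = True
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in (None, "binary_cross_entropy",
                             "categorical_cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def loss_for_task(self, task: str) -> str:
        bound = ("binary_cross_entropy" if task == "binary"
                 else "categorical_cross_entropy")
        if self.loss is not None and self.loss != bound:
            raise ValueError(f"loss {self.loss!r} does not match task {task!r}")
        return bound

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    """Confusion matrix plus accuracy / precision / recall / F1.

    ``confusion[i, j]`` counts true class i predicted as j.  For binary
    tasks the scalar precision/recall/F1 treat class 1 (stress) as positive;
    for multi-class they are the macro averages, with micro and weighted
    variants alongside.
    """

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: Dict[str, List[float]]
    macro: Dict[str, float]
    micro: Dict[str, float]
    weighted: Dict[str, float]
    n_test: int

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "per_class": self.per_class, "macro": self.macro,
                "micro": self.micro, "weighted": self.weighted,
                "n_test": self.n_test}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def metrics_from_confusion(confusion: np.ndarray) -> EvalReport:
    """Compute the full metric set from a square confusion matrix.

    Zero-denominator conventions: a per-class precision or recall with an
    empty denominator is 0, and F1 is 0 when precision + recall = 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {C.shape}")
    if (C < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = C.sum()
    accuracy = float(np.trace(C) / total) if total else 0.0

    k = C.shape[0]
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    support = C.sum(axis=1)
    for i in range(k):
        tp = C[i, i]
        fp = C[:, i].sum() - tp
        fn = C[i, :].sum() - tp
        prec[i] = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec[i] = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1[i] = (2.0 * prec[i] * rec[i] / (prec[i] + rec[i])
                 if prec[i] + rec[i] > 0 else 0.0)

    macro = {"precision": float(prec.mean()), "recall": float(rec.mean()),
             "f1": float(f1.mean())}
    # micro-averaged one-vs-rest precision and recall both reduce to accuracy
    micro = {"precision": accuracy, "recall": accuracy, "f1": accuracy}
    w = support / total if total else np.zeros(k)
    weighted = {"precision": float(prec @ w), "recall": float(rec @ w),
                "f1": float(f1 @ w)}

    if k == 2:  # positive class = 1: the four binary formulas verbatim
        top_p, top_r, top_f = float(prec[1]), float(rec[1]), float(f1[1])
    else:
        top_p, top_r, top_f = macro["precision"], macro["recall"], macro["f1"]

    return EvalReport(C.astype(int), accuracy, top_p, top_r, top_f,
                      {"precision": prec.tolist(), "recall": rec.tolist(),
                       "f1": f1.tolist()},
                      macro, micro, weighted, int(total))


# ---------------------------------------------------------------------------
# assembling branch inputs from a WindowSet


def branch_inputs(ws: WindowSet, graph: ModelGraph,
                  stats: Optional[Dict[str, Tuple[float, float]]] = None
                  ) -> Dict[str, np.ndarray]:
    """Per-branch input arrays for a window set, optionally z-scored.

    Conv branches receive ``(n, L, 1)``; the wrist ACC branch receives the
    three axes flattened axis-major into one vector; dense/passthrough
    branches receive ``(n, d)``.  ``stats`` maps channel name → (mean, sd)
    computed on the training split.
    """
    def channel(name: str) -> np.ndarray:
        try:
            x = ws.channel_matrix(name)
        except KeyError:
            raise KeyError(f"window set lacks channel {name!r} needed by "
                           f"branch {name!r}") from None
        if stats is not None:
            mean, sd = stats[name]
            x = (x - mean) / sd
        return x

    inputs: Dict[str, np.ndarray] = {}
    for br in graph.branches:
        if br.kind == "conv_block":
            x = channel(br.name)
            if x.shape[1] != br.input_len:
                raise ValueError(
                    f"branch {br.name!r}: window length {x.shape[1]} != "
                    f"graph input length {br.input_len}")
            inputs[br.name] = x[:, :, None]
        elif br.name == "ACC":
            x = np.hstack([channel(a) for a in WRIST_ACC_AXES])
            if x.shape[1] != br.input_len:
                raise ValueError(
                    f"branch ACC: flattened length {x.shape[1]} != "
                    f"graph input length {br.input_len}")
            inputs["ACC"] = x
        else:
            x = channel(br.name)
            if x.shape[1] != br.input_len:
                raise ValueError(
                    f"branch {br.name!r}: window length {x.shape[1]} != "
                    f"graph input length {br.input_len}")
            inputs[br.name] = x
    return inputs


def _channel_stats(ws: WindowSet, graph: ModelGraph) -> Dict[str, Tuple[float, float]]:
    needed = set()
    for br in graph.branches:
        if br.name == "ACC" and br.kind == "mlp":
            needed.update(WRIST_ACC_AXES)
        else:
            needed.add(br.name)
    stats = {}
    for name in needed:
        x = ws.channel_matrix(name)
        sd = float(x.std())
        stats[name] = (float(x.mean()), sd if sd > 0 else 1.0)
    return stats


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """A trained network plus everything needed to reuse it."""

    graph: ModelGraph
    network: nn.Network
    config: TrainConfig
    stats: Optional[Dict[str, Tuple[float, float]]]
    history: Dict[str, List[float]]

    def predict(self, ws: WindowSet) -> np.ndarray:
        return self.network.predict(branch_inputs(ws, self.graph, self.stats))

    def predict_proba(self, ws: WindowSet) -> np.ndarray:
        return self.network.predict_proba(
            branch_inputs(ws, self.graph, self.stats))

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "graph.json").write_text(self.graph.to_json())
        np.savez(d / "weights.npz",
                 **{f"p{i}": p for i, p in enumerate(self.network.parameters())})
        meta = {"config": json.loads(json.dumps(self.config.__dict__)),
                "stats": self.stats, "history": self.history}
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "FittedModel":
        from pathlib import Path
        d = Path(directory)
        graph = ModelGraph.from_json((d / "graph.json").read_text())
        meta = json.loads((d / "model.json").read_text())
        cfg = TrainConfig(**meta["config"])
        net = instantiate(graph, cfg.seed)
        with np.load(d / "weights.npz") as z:
            for i, p in enumerate(net.parameters()):
                p[...] = z[f"p{i}"]
        stats = meta["stats"]
        if stats is not None:
            stats = {k: tuple(v) for k, v in stats.items()}
        return cls(graph, net, cfg, stats, meta["history"])


def train_model(graph: ModelGraph, train: WindowSet,
                cfg: TrainConfig = TrainConfig()) -> FittedModel:
    """Fit a graph on a task-mapped window set under the training protocol.

    Mini-batch Adam on the task-bound cross-entropy; per-epoch mean loss and
    training accuracy are recorded in ``history``.  Fully seeded: weight
    init and batch order derive from ``cfg.seed``.  A NaN loss aborts with a
    diagnostic rather than training on.
    """
    if train.task != graph.task:
        raise ValueError(
            f"graph task {graph.task!r} != window set task {train.task!r}")
    if len(train) == 0:
        raise ValueError("empty training set")

    stats = _channel_stats(train, graph) if cfg.normalize else None
    inputs = branch_inputs(train, graph, stats)
    y = train.labels
    loss_kind = cfg.loss_for_task(graph.task)

    net = instantiate(graph, cfg.seed)
    opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))

    n = len(train)
    history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    order = np.arange(n)
    for epoch in range(cfg.epochs):
        if cfg.shuffle_each_epoch:
            order = shuffle_rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = {k: v[idx] for k, v in inputs.items()}
            logits = net.forward(batch)
            loss, g = nn.loss_and_grad(logits, y[idx], loss_kind)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}; "
                    "try a smaller learning rate or normalize=True")
            net.backward(g)
            opt.step(net.gradients())
            losses.append(loss * len(idx))
            if graph.task == "binary":
                pred = (nn.sigmoid(logits[:, 0]) > 0.5).astype(int)
            else:
                pred = logits.argmax(axis=1)
            correct += int((pred == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)

    return FittedModel(graph, net, cfg, stats, history)


def evaluate_model(model: FittedModel, test: WindowSet) -> EvalReport:
    """Score a fitted model on a test window set.

    Decoding: argmax over softmax outputs for 3-class, threshold 0.5 on the
    sigmoid output for binary.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    if test.task != model.graph.task:
        raise ValueError(
            f"model task {model.graph.task!r} != test task {test.task!r}")
    pred = model.predict(test)
    k = 2 if model.graph.task == "binary" else 3
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(test.labels, pred):
        confusion[t, p] += 1
    return metrics_from_confusion(confusion)


# ---------------------------------------------------------------------------
# full protocol


@dataclass
class ProtocolResult:
    """Hold-out report, per-fold telemetry and a reproducibility manifest."""

    holdout: EvalReport
    fold_reports: List[EvalReport]
    manifest: dict

    @property
    def cv_mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports])) \
            if self.fold_reports else float("nan")

    @property
    def cv_best_accuracy(self) -> float:
        return float(np.max([r.accuracy for r in self.fold_reports])) \
            if self.fold_reports else float("nan")

    def to_dict(self) -> dict:
        return {"holdout": self.holdout.to_dict(),
                "folds": [r.to_dict() for r in self.fold_reports],
                "cv_mean_accuracy": self.cv_mean_accuracy,
                "cv_best_accuracy": self.cv_best_accuracy,
                "manifest": self.manifest}


def run_protocol(dataset: WindowSet,
                 graph_builder: Callable[[str], ModelGraph],
                 cfg: TrainConfig = TrainConfig(),
                 task: Optional[str] = None) -> ProtocolResult:
    """Scrambled 7:3 split, k-fold CV on the training portion, final fit.

    The fold reports are model-selection telemetry; the headline metrics are
    the hold-out EvalReport.  The manifest records all seeds, the config
    hash, and the three accuracy readings (hold-out, CV mean, best fold).
    """
    if dataset.task is None:
        raise ValueError("map task labels before running the protocol")
    graph = graph_builder(dataset.task) if task is None else graph_builder(task)
    train_ws, test_ws = scramble_split(dataset, cfg.train_fraction, cfg.seed)

    fold_reports: List[EvalReport] = []
    if cfg.cv_folds >= 2:
        if len(train_ws) < cfg.cv_folds:
            raise ValueError(
                f"{len(train_ws)} training windows < {cfg.cv_folds} folds")
        for i, (ftr, fte) in enumerate(make_folds(train_ws, cfg.cv_folds,
                                                  cfg.seed)):
            fold_cfg = replace(cfg, seed=cfg.seed + 1 + i)
            fold_reports.append(evaluate_model(
                train_model(graph, ftr, fold_cfg), fte))

    model = train_model(graph, train_ws, cfg)
    holdout = evaluate_model(model, test_ws)

    manifest = {
        "config": {**cfg.__dict__}, "config_hash": cfg.digest(),
        "task": dataset.task, "site": dataset.site,
        "n_windows": len(dataset), "n_train": len(train_ws),
        "n_test": len(test_ws), "cv_folds": cfg.cv_folds,
        "seed": cfg.seed,
        "accuracy_holdout": holdout.accuracy,
        "accuracy_cv_mean": (float(np.mean([r.accuracy for r in fold_reports]))
                             if fold_reports else None),
        "accuracy_cv_best": (float(np.max([r.accuracy for r in fold_reports]))
                             if fold_reports else None),
    }
    result = ProtocolResult(holdout, fold_reports, manifest)
    result.model = model  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# scaled-down end-to-end benchmark


def synthetic_benchmark(site: str = "chest", task: str = "three_class",
                        seed: int = 0, epochs: int = 20,
                        n_subjects: int = 6, condition_s: float = 60.0,
                        include_acc: bool = True,
                        permute_labels: bool = False,
                        batch_size: int = 40) -> Tuple[EvalReport, FittedModel]:
    """Generate, window, split 7:3, train and score one model end to end.

    The scaled-down study condition: ``n_subjects`` synthetic subjects with
    ``condition_s`` seconds per condition, 5 s windows, 20 training epochs.
    ``permute_labels=True`` shuffles the task labels once before the split —
    the chance-level control.
    """
    from .models import (CHEST_BLOCK_DEFAULT, build_chest_cnn, build_wrist_mlp,
                         chest_channels)
    from .synthetic import SyntheticSpec, generate_dataset
    from .windowing import map_task_labels, segment_records

    spec = SyntheticSpec(n_subjects=n_subjects,
                         schedule=((1, condition_s), (2, condition_s),
                                   (3, condition_s)),
                         seed=seed)
    records = generate_dataset(spec)
    ws = segment_records(records, site=site, include_acc=include_acc)
    ws = map_task_labels(ws, task)
    if permute_labels:
        perm_rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
        ws.labels = perm_rng.permutation(ws.labels)

    if site == "chest":
        graph = build_chest_cnn(CHEST_BLOCK_DEFAULT,
                                chest_channels(include_acc), task)
    else:
        graph = build_wrist_mlp(task=task, include_acc=include_acc)

    cfg = TrainConfig(epochs=epochs, batch_size=batch_size, seed=seed,
                      cv_folds=0)
    train_ws, test_ws = scramble_split(ws, cfg.train_fraction, cfg.seed)
    model = train_model(graph, train_ws, cfg)
    return evaluate_model(model, test_ws), model
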