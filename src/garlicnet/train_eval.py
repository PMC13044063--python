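"""Training loop and evaluation stack.

Training is plain minibatch SGD on softmax cross-entropy with the
hyperparameters used for the garlic task (224 x 224 inputs, batch 8, base
learning rate 0.01, 30 epochs); the checkpoint with the best validation
accuracy is returned.  Evaluation builds a K x K confusion matrix (rows =
actual class, columns = predicted class) and derives accuracy plus one-vs-
rest precision, recall and F1 per class with unweighted macro averages.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .datapipe import Dataset
from .nn import SGD, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "MetricsReport",
    "confusion",
    "metrics",
    "dataset_to_arrays",
    "train",
    "evaluate",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol."""

    input_size: int = 224
    batch_size: int = 8
    lr: float = 0.01
    epochs: int = 30
    momentum: float = 0.9
    weight_decay: float = 0.0
    #: update rate of the batch-norm running statistics; the default is
    #: raised above the usual 0.1 so eval-mode statistics track the batch
    #: statistics within a handful of epochs (short-schedule friendly).
    bn_momentum: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size and epochs must be positive")


@dataclass
class TrainHistory:
    """Per-epoch curves; all lists have length ``epochs``."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    best_epoch: int = -1


def confusion(preds, truths, K: int) -> np.ndarray:
    """K x K count matrix with ``counts[actual, predicted]`` semantics."""
    preds = np.asarray(preds, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    cm = np.zeros((K, K), dtype=int)
    np.add.at(cm, (truths, preds), 1)
    return cm


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro-averaged P/R/F1 (and mean loss)."""

    acc: float
    per_class: dict          # class index -> {"P": .., "R": .., "F1": ..}
    macro_P: float
    macro_R: float
    macro_F1: float
    loss: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "macro_P": self.macro_P,
            "macro_R": self.macro_R,
            "macro_F1": self.macro_F1,
            "loss": self.loss,
            "per_class": self.per_class,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; defining it as 0")
        return 0.0
    return num / den


def metrics(cm: np.ndarray, loss: float = float("nan")) -> MetricsReport:
    """Derive Acc and one-vs-rest P/R/F1 per class from a confusion matrix.

    For class k, TP is the diagonal entry, FN the rest of its row, FP the
    rest of its column and TN everything else; precision with no predicted
    positives is defined as 0 (with a warning), and macro scores are
    unweighted class means.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    acc = np.trace(cm) / total
    per_class = {}
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k, :].sum() - tp
        fp = cm[:, k].sum() - tp
        p = _safe_div(tp, tp + fp, f"precision of class {k}")
        r = _safe_div(tp, tp + fn, f"recall of class {k}")
        f1 = _safe_div(2.0 * p * r, p + r, f"F1 of class {k}")
        per_class[k] = {"P": p, "R": r, "F1": f1}
    macro = {m: float(np.mean([per_class[k][m] for k in per_class]))
             for m in ("P", "R", "F1")}
    return MetricsReport(acc=float(acc), per_class=per_class,
                         macro_P=macro["P"], macro_R=macro["R"],
                         macro_F1=macro["F1"], loss=loss)


def dataset_to_arrays(dataset: Dataset, input_size: int):
    """Resize samples to the network input and stack as (N, 3, S, S) floats."""
    xs = []
    for s in dataset.samples:
        img = s.image
        if img.shape[0] != input_size or img.shape[1] != input_size:
            img = sktransform.resize(img, (input_size, input_size),
                                     preserve_range=True, anti_aliasing=True)
        xs.append(np.transpose(img, (2, 0, 1)))
    return np.stack(xs), dataset.label_indices()


def _all_modules(module):
    yield module
    for sub in module.submodules():
        yield from _all_modules(sub)


def _forward_in_batches(net, x, batch_size=16):
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(net.forward(x[i:i + batch_size]))
    return np.concatenate(outs, axis=0)


def train(net, train_set: Dataset, val_set: Dataset, cfg: TrainConfig):
    """SGD training; returns ``(net, TrainHistory)``.

    The network is left holding the weights of the epoch with the highest
    validation accuracy.  Aborts on a non-finite loss.
    """
    counts = train_set.class_counts()
    if any(n == 0 for n in counts.values()):
        raise ValueError(f"every class needs >= 1 training sample: {counts}")
    x_tr, y_tr = dataset_to_arrays(train_set, cfg.input_size)
    x_va, y_va = dataset_to_arrays(val_set, cfg.input_size)
    rng = np.random.default_rng(cfg.seed)
    from .nn import BatchNorm2d

    for mod in _all_modules(net):
        if isinstance(mod, BatchNorm2d):
            mod.momentum = cfg.bn_momentum
    opt = SGD(net.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_acc = -1.0
    best_state = None
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = net.forward(x_tr[idx])
            loss, glogits = cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}"
                )
            opt.zero_grad()
            net.backward(glogits)
            opt.step()
            losses.append(loss)
        net.eval()
        logits_va = _forward_in_batches(net, x_va)
        val_loss, _ = cross_entropy(logits_va, y_va)
        val_acc = float((logits_va.argmax(axis=1) == y_va).mean())
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val_loss))
        history.val_acc.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(net.state_dict())
            history.best_epoch = epoch
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return net, history


def evaluate(net, test_set: Dataset, input_size: int | None = None):
    """Eval-mode argmax prediction: ``(ConfusionMatrix, MetricsReport)``."""
    if len(test_set) == 0:
        raise ValueError("cannot evaluate an empty dataset")
    if len(test_set.class_names) != net.spec.num_classes:
        raise ValueError("network and dataset class counts disagree")
    size = input_size or test_set.samples[0].image.shape[0]
    x, y = dataset_to_arrays(test_set, size)
    net.eval()
    logits = _forward_in_batches(net, x)
    loss, _ = cross_entropy(logits, y)
    preds = logits.argmax(axis=1)
    cm = confusion(preds, y, K=net.spec.num_classes)
    return cm, metrics(cm, loss=float(loss))
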