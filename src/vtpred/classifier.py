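"""One-hidden-layer backpropagation perceptron and evaluation machinery.

The network is deliberately minimal: z-scored inputs, a single tanh
hidden layer, a linear output unit, +-1 targets, full-batch gradient
descent on the mean squared error with an optional classical momentum
term, and early stopping when the MSE falls below 1e-5.

Evaluation produces the confusion matrix at threshold 0 (ties go to the
control class), five scalar metrics, the ROC curve from sweeping all
score thresholds, and the trapezoidal AUC.  :func:`auc_brute` is an
independent pairwise (Mann-Whitney) AUC used as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "TrainConfig",
    "MLPModel",
    "EvalReport",
    "split_stratified",
    "train_mlp",
    "predict",
    "evaluate",
    "auc_brute",
    "select_hidden_size",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for :func:`train_mlp`."""

    lr: float = 0.05
    max_epochs: int = 5000
    mse_target: float = 1e-5
    seed: int = 0
    momentum: float = 0.9


@dataclass
class MLPModel:
    """Weights, normalization statistics and training metadata."""

    w1: np.ndarray          # (n_inputs, n_hidden)
    b1: np.ndarray          # (n_hidden,)
    w2: np.ndarray          # (n_hidden,)
    b2: float
    norm_mean: np.ndarray   # per-feature training mean
    norm_std: np.ndarray    # per-feature training SD (zeros replaced by 1)
    epochs_run: int = 0
    final_mse: float = float("nan")
    converged: bool = False
    seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "norm_mean": self.norm_mean.tolist(), "norm_std": self.norm_std.tolist(),
            "epochs_run": self.epochs_run, "final_mse": self.final_mse,
            "converged": self.converged, "seed": self.seed,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(
            w1=np.asarray(doc["w1"], dtype=float),
            b1=np.asarray(doc["b1"], dtype=float),
            w2=np.asarray(doc["w2"], dtype=float),
            b2=float(doc["b2"]),
            norm_mean=np.asarray(doc["norm_mean"], dtype=float),
            norm_std=np.asarray(doc["norm_std"], dtype=float),
            epochs_run=int(doc["epochs_run"]),
            final_mse=float(doc["final_mse"]),
            converged=bool(doc["converged"]),
            seed=int(doc["seed"]),
        )


@dataclass
class EvalReport:
    """Confusion counts, scalar metrics, ROC points and AUC."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None

    def __post_init__(self) -> None:
        tp, fn, tn, fp = self.tp, self.fn, self.tn, self.fp
        self.sensitivity = tp / (tp + fn) if tp + fn else float("nan")
        self.specificity = tn / (tn + fp) if tn + fp else float("nan")
        self.accuracy = (tp + tn) / (tp + tn + fp + fn)
        self.ppv = tp / (tp + fp) if tp + fp else float("nan")
        self.npv = tn / (tn + fn) if tn + fn else float("nan")

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "EvalReport":
        return cls(tp=tp, fn=fn, tn=tn, fp=fp)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["roc"] is not None:
            d["roc"] = [list(p) for p in d["roc"]]
        return d


def split_stratified(labels: np.ndarray, train_fraction: float = 2 / 3,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test split; returns index arrays.

    Per class, round(train_fraction * n) items go to training (so a
    52 + 52 cohort at 2/3 yields 35 + 35 train and 17 + 17 test), with
    the remainder in the test set.  Reproducible from ``seed``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            raise ValueError(f"class {c} has fewer than 3 members")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        if n_train >= len(idx):
            raise ValueError("train fraction leaves an empty test set")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _forward(model: MLPModel, xz: np.ndarray) -> np.ndarray:
    hidden = np.tanh(xz @ model.w1 + model.b1)
    return hidden @ model.w2 + model.b2


def train_mlp(x: np.ndarray, y: np.ndarray, n_hidden: int,
              cfg: TrainConfig | None = None) -> MLPModel:
    """Train the perceptron on features ``x`` (n, d) and targets ``y`` (+-1).

    Inputs are z-scored by training statistics; optimization is
    full-batch gradient descent on the MSE with classical momentum;
    training stops when MSE < ``cfg.mse_target`` or at
    ``cfg.max_epochs``.  Fully deterministic given data, config and seed.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("x must be (n, d) with matching y")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite features or targets")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if np.all(y > 0) or np.all(y < 0):
        raise ValueError("both classes must be present in training data")

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    xz = (x - mean) / std
    n, d = xz.shape

    rng = np.random.default_rng(cfg.seed)
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
    b2 = 0.0
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0

    mse = float("inf")
    epoch = 0
    converged = False
    for epoch in range(1, cfg.max_epochs + 1):
        hidden = np.tanh(xz @ w1 + b1)
        scores = hidden @ w2 + b2
        err = scores - y
        mse = float(np.mean(err**2))
        if mse < cfg.mse_target:
            converged = True
            break
        # backprop (MSE gradient, full batch)
        g_scores = 2.0 * err / n
        g_w2 = hidden.T @ g_scores
        g_b2 = float(np.sum(g_scores))
        g_hidden = np.outer(g_scores, w2) * (1.0 - hidden**2)
        g_w1 = xz.T @ g_hidden
        g_b1 = g_hidden.sum(axis=0)

        v_w1 = cfg.momentum * v_w1 - cfg.lr * g_w1
        v_b1 = cfg.momentum * v_b1 - cfg.lr * g_b1
        v_w2 = cfg.momentum * v_w2 - cfg.lr * g_w2
        v_b2 = cfg.momentum * v_b2 - cfg.lr * g_b2
        w1 += v_w1
        b1 += v_b1
        w2 += v_w2
        b2 += v_b2

    return MLPModel(w1=w1, b1=b1, w2=w2, b2=b2, norm_mean=mean, norm_std=std,
                    epochs_run=epoch, final_mse=mse, converged=converged,
                    seed=cfg.seed)


def predict(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Continuous score(s) for feature row(s); class = sign, 0 -> control."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} features, got {x.shape[1]}")
    xz = (x - model.norm_mean) / model.norm_std
    scores = _forward(model, xz)
    return float(scores[0]) if single else scores


def classify(scores: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Map scores to +-1 labels; scores exactly at threshold go to -1."""
    return np.where(np.asarray(scores) > threshold, 1, -1)


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC by sweeping all distinct score thresholds; trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores) != 0), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.0) -> EvalReport:
    """Confusion metrics at ``threshold`` plus the full ROC curve and AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = classify(scores, threshold)
    pos, neg = labels > 0, labels < 0
    tp = int(np.sum(pos & (pred > 0)))
    fn = int(np.sum(pos & (pred < 0)))
    tn = int(np.sum(neg & (pred < 0)))
    fp = int(np.sum(neg & (pred > 0)))
    roc, auc = _roc_curve(scores, labels)
    report = EvalReport.from_counts(tp=tp, fn=fn, tn=tn, fp=fp)
    report.roc = roc
    report.auc = auc
    return report


def auc_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise Mann-Whitney AUC: P(score_pos > score_neg), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def select_hidden_size(x: np.ndarray, y: np.ndarray,
                       candidates: range = range(1, 21),
                       val_fraction: float = 1 / 3, seed: int = 0,
                       cfg: TrainConfig | None = None) -> int:
    """Grid-search the hidden-layer size on a held-out validation split.

    Returns the candidate with the highest validation accuracy (ties go
    to the smaller network).
    """
    cfg = cfg or TrainConfig(max_epochs=1000)
    train_idx, val_idx = split_stratified(y, 1 - val_fraction, seed=seed)
    best_h, best_acc = candidates[0], -1.0
    for h in candidates:
        model = train_mlp(x[train_idx], y[train_idx], h,
                          TrainConfig(lr=cfg.lr, max_epochs=cfg.max_epochs,
                                      mse_target=cfg.mse_target, seed=seed,
                                      momentum=cfg.momentum))
        acc = float(np.mean(classify(predict(model, x[val_idx])) == y[val_idx]))
        if acc > best_acc:
            best_h, best_acc = h, acc
    return best_h
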