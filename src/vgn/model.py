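"""The vascular graph classifier and its training/evaluation protocol.

The classifier is a four-layer hybrid message-passing network alternating
MLP-based (GIN) and attention-based (GAT) aggregation over complete
weighted vascular graphs, trained with class-balanced focal cross-entropy
using Adam and a multistep learning-rate decay.  Specimens are split
15:3:2 into train/validation/test with specimen-level stratification, and
the protocol is repeated over independent splits to measure stability.

:class:`VGNClassifier` follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``predict_proba``, ``get_params``), so it
composes with sklearn pipelines together with
:class:`~vgn.graph_builder.GraphFeatureScaler`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score, confusion_matrix, roc_curve

from .nn.autodiff import Tensor
from .nn.layers import VGNNetwork, batch_graphs
from .nn.optim import Adam, MultiStepLR
from .types import N_CLASSES, VascularGraph

SPLIT_RATIOS = (15, 3, 2)
PROB_FLOOR = 1e-12


# --------------------------------------------------------------------- config
@dataclass
class VGNConfig:
    """Hyperparameters of the classifier and its training protocol."""

    n_layers: int = 4
    hidden_dim: int = 64
    n_heads: int = 4
    n_classes: int = N_CLASSES
    focal_gamma: float = 2.0
    class_weights: Optional[np.ndarray] = None  # None -> inverse frequency
    lr: float = 1e-2
    epochs: int = 200
    milestones: Tuple[int, ...] = (100, 150)
    lr_decay: float = 0.1
    batch_size: int = 32
    seed: int = 0


# ----------------------------------------------------------------- focal loss
def focal_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    gamma: float = 2.0,
    class_weights: Optional[np.ndarray] = None,
) -> float:
    """Batch-averaged focal cross-entropy.

    ``loss_i = -w_y * (1 - p_y)^gamma * log(p_y)`` with the true-class
    probability clamped at 1e-12 before the log.  With ``gamma = 0`` and
    unit weights this is exactly the standard cross-entropy.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    n_classes = scores.shape[1]
    if class_weights is None:
        class_weights = np.ones(n_classes)
    class_weights = np.asarray(class_weights, dtype=float)
    if np.any(class_weights <= 0):
        raise ValueError("class weights must be positive")
    p = np.clip(scores[np.arange(labels.size), labels], PROB_FLOOR, None)
    modulation = (1.0 - p) ** gamma if gamma > 0 else 1.0
    return float(np.mean(-class_weights[labels] * modulation * np.log(p)))


def _focal_loss_tensor(
    probs: Tensor, labels: np.ndarray, gamma: float, class_weights: np.ndarray
) -> Tensor:
    """Differentiable focal loss on a (batch, n_classes) probability tensor."""
    n = labels.size
    onehot = np.zeros(probs.shape)
    onehot[np.arange(n), labels] = 1.0
    p = (probs * onehot).sum(axis=1)
    log_p = p.clip_min(PROB_FLOOR).log()
    w = class_weights[labels]
    if gamma > 0:
        modulation = (1.0 - p).clip_min(PROB_FLOOR).pow(gamma)
        per_item = modulation * log_p * (-w)
    else:
        per_item = log_p * (-w)
    return per_item.mean()


def inverse_frequency_weights(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse class-frequency weights normalized to mean 1 over present classes."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    w = np.ones(n_classes)
    w[present] = 1.0 / counts[present]
    w[present] *= present.sum() / w[present].sum()
    return w


# --------------------------------------------------------------------- splits
@dataclass
class SplitSpec:
    """One stratified specimen-level train/validation/test partition."""

    train: List[str]
    val: List[str]
    test: List[str]
    repeat: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"specimens appear in two splits: {sorted(overlap)}")


def _apportion(n: int, ratios: Tuple[int, ...] = SPLIT_RATIOS) -> List[int]:
    """Largest-remainder apportionment of n specimens to the split ratios.

    Remainder ties go to the split with fewer allocated specimens.  When
    n >= 3 every split receives at least one specimen.
    """
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    order = sorted(range(len(ratios)), key=lambda i: (-remainders[i], counts[i]))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    if n >= len(ratios):
        for i in range(len(counts)):
            while counts[i] == 0:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[i] += 1
    return counts


def make_splits(
    specimen_labels: Dict[str, int],
    n_repeats: int = 100,
    seed: int = 0,
) -> List[SplitSpec]:
    """Independent stratified 15:3:2 specimen-level splits.

    Per class, the specimen ids are permuted by a seeded generator and
    partitioned by largest-remainder rounding of the ratios.  A class with
    a single specimen goes to training with a warning.  Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[str]] = {}
    for sid in sorted(specimen_labels):
        by_class.setdefault(specimen_labels[sid], []).append(sid)

    splits = []
    for rep in range(n_repeats):
        train: List[str] = []
        val: List[str] = []
        test: List[str] = []
        for cls in sorted(by_class):
            ids = by_class[cls]
            if len(ids) == 1:
                warnings.warn(
                    f"class {cls} has a single specimen; assigned to training",
                    RuntimeWarning,
                )
                train.extend(ids)
                rng.permutation(1)  # keep the stream aligned across classes
                continue
            perm = rng.permutation(len(ids))
            shuffled = [ids[i] for i in perm]
            n_tr, n_va, n_te = _apportion(len(ids))
            train.extend(shuffled[:n_tr])
            val.extend(shuffled[n_tr:n_tr + n_va])
            test.extend(shuffled[n_tr + n_va:])
        splits.append(SplitSpec(train=train, val=val, test=test, repeat=rep))
    return splits


# ----------------------------------------------------------------- classifier
class VGNClassifier(BaseEstimator, ClassifierMixin):
    """Hybrid GIN/GAT graph classifier for five-class lesion diagnosis.

    Parameters mirror :class:`VGNConfig`.  ``fit`` expects a sequence of
    standardized :class:`~vgn.types.VascularGraph` of equal node count and
    integer labels; ``predict_proba`` returns rows on the 5-class simplex
    in the canonical class order.
    """

    def __init__(
        self,
        n_layers: int = 4,
        hidden_dim: int = 64,
        n_heads: int = 4,
        n_classes: int = N_CLASSES,
        focal_gamma: float = 2.0,
        class_weights: Optional[np.ndarray] = None,
        lr: float = 1e-2,
        epochs: int = 200,
        milestones: Tuple[int, ...] = (100, 150),
        lr_decay: float = 0.1,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.n_classes = n_classes
        self.focal_gamma = focal_gamma
        self.class_weights = class_weights
        self.lr = lr
        self.epochs = epochs
        self.milestones = milestones
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.seed = seed

    # -- sklearn plumbing -------------------------------------------------
    def _build_network(self) -> VGNNetwork:
        return VGNNetwork(
            in_dim=7,
            hidden_dim=self.hidden_dim,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            n_classes=self.n_classes,
            seed=self.seed,
        )

    def fit(
        self,
        X: Sequence[VascularGraph],
        y: Optional[Sequence[int]] = None,
        validation_data: Optional[Tuple[Sequence[VascularGraph], Sequence[int]]] = None,
    ) -> "VGNClassifier":
        if len(X) == 0:
            raise ValueError("training set is empty")
        if y is None:
            y = [g.label for g in X]
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")

        batch = batch_graphs(X)
        x_all, adj_all = batch["x"], batch["adj"]
        weights = (
            inverse_frequency_weights(y, self.n_classes)
            if self.class_weights is None
            else np.asarray(self.class_weights, dtype=float)
        )
        self.class_weights_ = weights
        self.classes_ = np.arange(self.n_classes)

        net = self._build_network()
        optimizer = Adam(net.parameters(), lr=self.lr)
        scheduler = MultiStepLR(optimizer, self.milestones, self.lr_decay)
        shuffle_rng = np.random.default_rng(self.seed + 1)

        history: Dict[str, list] = {"epoch": [], "loss": [], "lr": [], "val_balanced_accuracy": []}
        best_val, best_state = (-np.inf, -np.inf), None
        n = len(X)
        batch_size = min(self.batch_size, n)

        val_batch = val_y = None
        if validation_data is not None and len(validation_data[0]) > 0:
            vb = batch_graphs(validation_data[0])
            val_batch, val_y = vb, np.asarray(validation_data[1], dtype=int)

        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                x = Tensor(x_all[idx])
                adj = Tensor(adj_all[idx])
                probs = net(x, adj)
                loss = _focal_loss_tensor(probs, y[idx], self.focal_gamma, weights)
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            lr_used = optimizer.lr
            scheduler.step()

            val_bacc = np.nan
            if val_batch is not None:
                val_scores = net(Tensor(val_batch["x"]), Tensor(val_batch["adj"])).data
                val_bacc = balanced_accuracy_score(val_y, val_scores.argmax(axis=1))
                val_loss = focal_loss(val_scores, val_y, self.focal_gamma, weights)
                # ties on balanced accuracy go to the epoch with lower loss
                if (val_bacc, -val_loss) > best_val:
                    best_val, best_state = (val_bacc, -val_loss), net.state()

            history["epoch"].append(epoch)
            history["loss"].append(float(np.mean(losses)))
            history["lr"].append(lr_used)
            history["val_balanced_accuracy"].append(val_bacc)

        if best_state is not None:
            net.load_state(best_state)
        self.network_ = net
        self.history_ = history
        self.best_val_score_ = best_val[0] if best_state is not None else None
        return self

    def predict_proba(self, X: Sequence[VascularGraph]) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        out = []
        for start in range(0, len(X), 64):
            chunk = list(X[start:start + 64])
            batch = batch_graphs(chunk)
            out.append(self.network_(Tensor(batch["x"]), Tensor(batch["adj"])).data)
        return np.concatenate(out)

    def predict(self, X: Sequence[VascularGraph]) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def vgn_forward(graph: VascularGraph, clf: VGNClassifier) -> np.ndarray:
    """Score one graph: a 5-vector of class probabilities summing to 1."""
    return clf.predict_proba([graph])[0]


def train(
    graphs: Sequence[VascularGraph],
    split: SplitSpec,
    config: Optional[VGNConfig] = None,
) -> Tuple[VGNClassifier, "object", Dict[str, list]]:
    """Standardize on the training split, fit the classifier, return history.

    Returns ``(classifier, scaler, history)``; the scaler carries the
    training-split feature statistics needed at inference time.
    """
    from .graph_builder import GraphFeatureScaler

    config = config or VGNConfig()
    by_split = {s: [g for g in graphs if g.specimen_id in set(ids)]
                for s, ids in (("train", split.train), ("val", split.val))}
    if not by_split["train"]:
        raise ValueError("empty training split")
    scaler = GraphFeatureScaler().fit(by_split["train"])
    train_graphs = scaler.transform(by_split["train"])
    val_graphs = scaler.transform(by_split["val"])
    clf = VGNClassifier(
        n_layers=config.n_layers,
        hidden_dim=config.hidden_dim,
        n_heads=config.n_heads,
        n_classes=config.n_classes,
        focal_gamma=config.focal_gamma,
        class_weights=config.class_weights,
        lr=config.lr,
        epochs=config.epochs,
        milestones=config.milestones,
        lr_decay=config.lr_decay,
        batch_size=config.batch_size,
        seed=config.seed,
    )
    clf.fit(
        train_graphs,
        [g.label for g in train_graphs],
        validation_data=(val_graphs, [g.label for g in val_graphs]),
    )
    return clf, scaler, clf.history_


# ----------------------------------------------------------------- evaluation
def evaluate(
    clf: VGNClassifier,
    graphs: Sequence[VascularGraph],
    y: Optional[Sequence[int]] = None,
    n_classes: int = N_CLASSES,
) -> Dict[str, object]:
    """Confusion matrix, per-class sensitivity, and one-vs-rest ROC/AUC.

    The confusion matrix is row-normalized to sensitivities; accuracy is
    the mean of the defined diagonal entries.  Classes absent from the
    test set have NaN rows/AUCs and are excluded from averages.
    """
    if len(graphs) == 0:
        raise ValueError("test split is empty")
    if y is None:
        y = [g.label for g in graphs]
    y = np.asarray(y, dtype=int)
    scores = clf.predict_proba(graphs)
    pred = scores.argmax(axis=1)

    cm = confusion_matrix(y, pred, labels=np.arange(n_classes)).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_norm = np.where(row_sums > 0, cm / row_sums, np.nan)
    sensitivity = np.diag(cm_norm)

    aucs = np.full(n_classes, np.nan)
    rocs = {}
    for k in range(n_classes):
        mask_pos = y == k
        if mask_pos.any() and (~mask_pos).any():
            fpr, tpr, _ = roc_curve(mask_pos.astype(int), scores[:, k])
            rocs[k] = (fpr, tpr)
            aucs[k] = float(np.trapezoid(tpr, fpr))
    return {
        "confusion": cm_norm,
        "sensitivity": sensitivity,
        "accuracy": float(np.nanmean(sensitivity)),
        "auc": aucs,
        "roc": rocs,
        "scores": scores,
        "labels": y,
    }


def aggregate_metrics(values: Sequence[float]) -> Dict[str, float]:
    """Mean, sd, and percentile 95% CI across protocol repeats."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan}
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "ci_low": float(np.percentile(arr, 2.5)),
        "ci_high": float(np.percentile(arr, 97.5)),
    }


def run_protocol(
    graphs: Sequence[VascularGraph],
    specimen_labels: Dict[str, int],
    n_repeats: int = 100,
    config: Optional[VGNConfig] = None,
    seed: int = 0,
) -> Dict[str, object]:
    """Repeat the stratified split/train/test protocol and aggregate metrics.

    For each repeat: draw an independent 15:3:2 split, standardize on the
    training split, train with validation-based model selection, and
    evaluate graph-level metrics plus specimen-level majority votes on the
    held-out test specimens.
    """
    from .inference import majority_vote

    config = config or VGNConfig()
    splits = make_splits(specimen_labels, n_repeats=n_repeats, seed=seed)
    repeats = []
    last_model = None
    for split in splits:
        cfg_seed = VGNConfig(**{**config.__dict__, "seed": config.seed + split.repeat})
        clf, scaler, history = train(graphs, split, cfg_seed)
        last_model = (clf, scaler)
        test_ids = set(split.test)
        test_graphs = scaler.transform([g for g in graphs if g.specimen_id in test_ids])
        if not test_graphs:
            warnings.warn(
                f"repeat {split.repeat}: no test graphs (cohort too small); "
                "metrics undefined",
                RuntimeWarning,
            )
            repeats.append({
                "repeat": split.repeat,
                "graph_accuracy": np.nan,
                "sensitivity": np.full(config.n_classes, np.nan),
                "auc": np.full(config.n_classes, np.nan),
                "confusion": np.full((config.n_classes, config.n_classes), np.nan),
                "vote_accuracy": np.nan,
            })
            continue
        res = evaluate(clf, test_graphs, n_classes=config.n_classes)

        votes_correct, votes_total = 0, 0
        for sid in sorted(test_ids):
            sg = [g for g in test_graphs if g.specimen_id == sid]
            if not sg:
                continue
            vote = majority_vote(clf.predict_proba(sg))
            votes_correct += int(vote == specimen_labels[sid])
            votes_total += 1
        repeats.append(
            {
                "repeat": split.repeat,
                "graph_accuracy": res["accuracy"],
                "sensitivity": res["sensitivity"],
                "auc": res["auc"],
                "confusion": res["confusion"],
                "vote_accuracy": votes_correct / max(votes_total, 1),
            }
        )
    return {
        "repeats": repeats,
        "graph_accuracy": aggregate_metrics([r["graph_accuracy"] for r in repeats]),
        "vote_accuracy": aggregate_metrics([r["vote_accuracy"] for r in repeats]),
        "auc_per_class": [
            aggregate_metrics([r["auc"][k] for r in repeats])
            for k in range(config.n_classes)
        ],
        "final_model": last_model,
    }
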