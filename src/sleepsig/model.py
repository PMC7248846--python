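"""Multimodal classifier: recurrent EMG branch + feed-forward ECG branch.

The network ingests one observation as two tensors: a 3-step sequence of the
five EMG features (one step per 20 s sub-window) and the 10-value ECG feature
vector.  The EMG sequence passes through two stacked tanh recurrent layers of
five units; the final-step hidden state is concatenated with a 20-unit ReLU
projection of the ECG vector into a 25-wide merged representation, which a
dropout layer and a small ReLU stack (25 -> 15 -> 15 -> 10 -> 4) map to
four-class softmax probabilities.  Training minimises the negative
log-likelihood with Adam; a checkpoint rule stops training when the loss has
not dropped by more than 1e-3 over the last 100 epochs.

Everything is implemented in numpy with explicit gradients; the network is
small enough that full-batch CPU training takes milliseconds per epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             precision_score, recall_score)

from .synthetic import GroupLabel

__all__ = [
    "ModelConfig",
    "MultimodalNet",
    "TrainedModel",
    "EvalReport",
    "build_model",
    "train",
    "tune",
    "cross_subject_cv",
    "CLASS_ORDER",
]

CLASS_ORDER = tuple(g.value for g in GroupLabel)
N_CLASSES = 4


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``fc_stack`` lists the hidden widths after the merge (the final 4-way
    linear layer is implicit).  ``dropout`` is the drop probability applied to
    the merged representation during training.
    """

    rnn_layers: int = 2
    rnn_units: int = 5
    fc1_units: int = 20
    dropout: float = 0.4
    fc_stack: tuple[int, ...] = (15, 15, 10)
    lr: float = 0.01
    epochs: int = 2000
    seed: int = 0
    check_every: int = 100
    min_loss_drop: float = 1e-3

    @property
    def merge_width(self) -> int:
        return self.rnn_units + self.fc1_units

    def to_json(self) -> str:
        d = asdict(self)
        d["fc_stack"] = list(self.fc_stack)
        return json.dumps(d, indent=2)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MultimodalNet:
    """The network parameters plus forward/backward passes."""

    def __init__(self, cfg: ModelConfig, n_emg_feat: int = 5, n_ecg_feat: int = 10):
        self.cfg = cfg
        self.n_emg_feat = n_emg_feat
        self.n_ecg_feat = n_ecg_feat
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}

        def init(name: str, shape: tuple[int, ...]) -> None:
            fan_in = shape[0]
            self.params[name] = rng.uniform(-1, 1, shape) / np.sqrt(fan_in)

        u = cfg.rnn_units
        in_dim = n_emg_feat
        for layer in range(cfg.rnn_layers):
            init(f"Wx{layer}", (in_dim, u))
            init(f"Wh{layer}", (u, u))
            self.params[f"bh{layer}"] = np.zeros(u)
            in_dim = u
        init("We", (n_ecg_feat, cfg.fc1_units))
        self.params["be"] = np.zeros(cfg.fc1_units)
        widths = [cfg.merge_width, *cfg.fc_stack, N_CLASSES]
        for i in range(len(widths) - 1):
            init(f"Wf{i}", (widths[i], widths[i + 1]))
            self.params[f"bf{i}"] = np.zeros(widths[i + 1])
        self._n_fc = len(widths) - 1

    # -- forward ----------------------------------------------------------

    def forward(self, ecg: np.ndarray, emg: np.ndarray,
                dropout_rng: np.random.Generator | None = None) -> dict:
        """Forward pass; ``emg`` is (n, steps, features), ``ecg`` is (n, 10).

        Passing ``dropout_rng`` enables (inverted) dropout on the merged layer.
        Returns a cache with ``probs`` and every intermediate needed by
        ``backward``.
        """
        cfg = self.cfg
        n, steps, _ = emg.shape
        cache: dict = {"ecg": ecg, "emg": emg, "h": []}
        x = emg
        for layer in range(cfg.rnn_layers):
            h = np.zeros((n, cfg.rnn_units))
            hs = []
            for t in range(steps):
                h = np.tanh(x[:, t] @ self.params[f"Wx{layer}"]
                            + h @ self.params[f"Wh{layer}"]
                            + self.params[f"bh{layer}"])
                hs.append(h)
            hs = np.stack(hs, axis=1)  # (n, steps, units)
            cache["h"].append(hs)
            x = hs
        e_pre = ecg @ self.params["We"] + self.params["be"]
        e = _relu(e_pre)
        cache["e"] = e
        z = np.concatenate([x[:, -1], e], axis=1)
        if dropout_rng is not None and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = (dropout_rng.random(z.shape) < keep) / keep
        else:
            mask = np.ones_like(z)
        cache["mask"] = mask
        a = z * mask
        cache["z"] = z
        cache["a"] = [a]
        for i in range(self._n_fc):
            pre = a @ self.params[f"Wf{i}"] + self.params[f"bf{i}"]
            a = _relu(pre) if i < self._n_fc - 1 else pre
            cache["a"].append(a)
        cache["probs"] = _softmax(a)
        return cache

    def predict_proba(self, ecg: np.ndarray, emg: np.ndarray) -> np.ndarray:
        return self.forward(ecg, emg)["probs"]

    # -- backward ---------------------------------------------------------

    def loss_and_grads(self, cache: dict, y: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean NLL loss and gradients for every parameter."""
        cfg = self.cfg
        probs = cache["probs"]
        n = probs.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        d /= n
        for i in range(self._n_fc - 1, -1, -1):
            a_in = cache["a"][i]
            grads[f"Wf{i}"] = a_in.T @ d
            grads[f"bf{i}"] = d.sum(axis=0)
            d = d @ self.params[f"Wf{i}"].T
            if i > 0:
                d *= cache["a"][i] > 0
        d *= cache["mask"]
        u = cfg.rnn_units
        d_hlast, d_e = d[:, :u], d[:, u:]

        d_e_pre = d_e * (cache["e"] > 0)
        grads["We"] = cache["ecg"].T @ d_e_pre
        grads["be"] = d_e_pre.sum(axis=0)

        steps = cache["emg"].shape[1]
        # gradient w.r.t. each layer's hidden outputs, accumulated top-down
        d_out = [np.zeros((n, steps, u)) for _ in range(cfg.rnn_layers)]
        d_out[-1][:, -1] = d_hlast
        for layer in range(cfg.rnn_layers - 1, -1, -1):
            hs = cache["h"][layer]
            x_in = cache["emg"] if layer == 0 else cache["h"][layer - 1]
            dh = np.zeros((n, u))
            for t in range(steps - 1, -1, -1):
                dh = dh + d_out[layer][:, t]
                dpre = dh * (1.0 - hs[:, t] ** 2)
                grads[f"Wx{layer}"] += x_in[:, t].T @ dpre
                grads[f"bh{layer}"] += dpre.sum(axis=0)
                if t > 0:
                    grads[f"Wh{layer}"] += hs[:, t - 1].T @ dpre
                dh = dpre @ self.params[f"Wh{layer}"].T
                if layer > 0:
                    d_out[layer - 1][:, t] = dpre @ self.params[f"Wx{layer}"].T
        return loss, grads


@dataclass
class TrainedModel:
    """A trained network plus the feature standardiser fitted on training data."""

    net: MultimodalNet
    config: ModelConfig
    loss_trace: np.ndarray
    ecg_scale: tuple[np.ndarray, np.ndarray]
    emg_scale: tuple[np.ndarray, np.ndarray]
    stopped_epoch: int = 0
    checkpoint_losses: np.ndarray = field(default_factory=lambda: np.empty(0))

    def _standardise(self, ecg: np.ndarray, emg: np.ndarray):
        mu_e, sd_e = self.ecg_scale
        mu_m, sd_m = self.emg_scale
        return (ecg - mu_e) / sd_e, (emg - mu_m) / sd_m

    def predict_proba(self, ecg: np.ndarray, emg: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(*self._standardise(ecg, emg))

    def predict(self, ecg: np.ndarray, emg: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(ecg, emg).argmax(axis=1)
        return np.array([CLASS_ORDER[i] for i in idx])


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics."""

    accuracy: np.ndarray
    f1_weighted: np.ndarray
    precision_weighted: np.ndarray
    recall_weighted: np.ndarray
    confusion: np.ndarray
    fold_subjects: list[list[str]] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("accuracy", "f1_weighted", "precision_weighted",
                     "recall_weighted"):
            v = getattr(self, name)
            out[f"{name}_mean"] = float(np.mean(v))
            out[f"{name}_sd"] = float(np.std(v))
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "fold": np.arange(len(self.accuracy)),
            "accuracy": self.accuracy,
            "f1_weighted": self.f1_weighted,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
        })


def build_model(cfg: ModelConfig) -> MultimodalNet:
    """Untrained network with seeded initialisation."""
    return MultimodalNet(cfg)


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    lut = {name: i for i, name in enumerate(CLASS_ORDER)}
    return np.array([lut[str(l)] for l in labels])


def train(ecg: np.ndarray, emg: np.ndarray, labels: np.ndarray,
          cfg: ModelConfig | None = None) -> TrainedModel:
    """Train the multimodal network with Adam on the full batch.

    Features are z-scored with statistics of the training data (stored in the
    returned model).  Every ``cfg.check_every`` epochs the loss is compared
    with the previous checkpoint; if it has not dropped by more than
    ``cfg.min_loss_drop`` training stops (the early-termination rule).
    A non-finite loss aborts with diagnostics.
    """
    cfg = cfg or ModelConfig()
    y = _encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    mu_e, sd_e = ecg.mean(axis=0), ecg.std(axis=0)
    mu_m, sd_m = emg.mean(axis=(0, 1)), emg.std(axis=(0, 1))
    sd_e = np.where(sd_e > 0, sd_e, 1.0)
    sd_m = np.where(sd_m > 0, sd_m, 1.0)
    X_e = (ecg - mu_e) / sd_e
    X_m = (emg - mu_m) / sd_m

    net = MultimodalNet(cfg, n_emg_feat=emg.shape[2], n_ecg_feat=ecg.shape[1])
    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    def eval_loss() -> float:
        cache = net.forward(X_e, X_m)  # no dropout: stable checkpoint metric
        probs = cache["probs"]
        return float(-np.mean(np.log(probs[np.arange(y.size), y] + 1e-300)))

    trace = []
    checkpoints = [eval_loss()]  # baseline before any update
    stopped = cfg.epochs
    for epoch in range(1, cfg.epochs + 1):
        cache = net.forward(X_e, X_m, dropout_rng=rng)
        loss, grads = net.loss_and_grads(cache, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {loss!r}; "
                f"lr={cfg.lr}, trace tail={trace[-5:]}")
        trace.append(loss)
        for k in net.params:
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1 ** epoch)
            vhat = v[k] / (1 - b2 ** epoch)
            net.params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
        if epoch % cfg.check_every == 0:
            current = eval_loss()
            if checkpoints[-1] - current <= cfg.min_loss_drop:
                checkpoints.append(current)
                stopped = epoch
                break
            checkpoints.append(current)
    return TrainedModel(net=net, config=cfg, loss_trace=np.array(trace),
                        checkpoint_losses=np.array(checkpoints),
                        ecg_scale=(mu_e, sd_e), emg_scale=(mu_m, sd_m),
                        stopped_epoch=stopped)


# --------------------------------------------------------------------------
# hyperparameter search (tree-structured Parzen estimator)
# --------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE = {
    "fc1_units": ("int", 8, 32),
    "dropout": ("float", 0.1, 0.6),
    "lr": ("logfloat", 1e-3, 1e-1),
}


def _sample_uniform(rng, kind, lo, hi):
    if kind == "int":
        return int(rng.integers(lo, hi + 1))
    if kind == "float":
        return float(rng.uniform(lo, hi))
    if kind == "logfloat":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    raise ValueError(kind)


def _to_internal(kind, v):
    return np.log(v) if kind == "logfloat" else float(v)


def _from_internal(kind, v, lo, hi):
    if kind == "int":
        return int(np.clip(round(v), lo, hi))
    if kind == "logfloat":
        return float(np.clip(np.exp(v), lo, hi))
    return float(np.clip(v, lo, hi))


def tune(train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
         val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
         search_space: dict | None = None, n_trials: int = 16,
         seed: int = 0, base_cfg: ModelConfig | None = None,
         gamma: float = 0.25, n_candidates: int = 24) -> ModelConfig:
    """Tree-structured Parzen estimator search over hyperparameters.

    Past trials are split at the ``gamma`` quantile of validation accuracy
    into good and bad sets; one-dimensional Parzen (Gaussian-kernel) densities
    ``l(x)`` and ``g(x)`` are fitted per hyperparameter, and the next trial
    maximises ``l(x)/g(x)`` over candidates drawn from ``l``.  Trials train
    with the usual 100-epoch pruning rule.  Fully seeded.
    """
    space = search_space or DEFAULT_SEARCH_SPACE
    base = base_cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    names = list(space)
    n_startup = max(4, n_trials // 4)

    history: list[tuple[dict, float]] = []
    for trial in range(n_trials):
        if trial < n_startup or len(history) < 4:
            point = {k: _sample_uniform(rng, *space[k]) for k in names}
        else:
            scores = np.array([s for _, s in history])
            cut = np.quantile(scores, 1 - gamma)
            good = [p for p, s in history if s >= cut]
            bad = [p for p, s in history if s < cut] or good
            point = {}
            for k in names:
                kind, lo, hi = space[k]
                gv = np.array([_to_internal(kind, p[k]) for p in good])
                bv = np.array([_to_internal(kind, p[k]) for p in bad])
                cand = rng.choice(gv, n_candidates) + rng.normal(
                    0, max(gv.std(), 1e-3) + 1e-3, n_candidates)
                def dens(vals, at):
                    if vals.size < 2 or vals.std() == 0:
                        return np.exp(-0.5 * ((at - vals.mean()) / 0.5) ** 2)
                    return gaussian_kde(vals)(at)
                ratio = dens(gv, cand) / (dens(bv, cand) + 1e-12)
                point[k] = _from_internal(kind, cand[np.argmax(ratio)], lo, hi)
        cfg = ModelConfig(**{**asdict(base), **point,
                             "fc_stack": base.fc_stack,
                             "seed": int(rng.integers(0, 2**31 - 1))})
        model = train(*train_data, cfg)
        pred = model.predict(val_data[0], val_data[1])
        acc = float(np.mean(pred == np.asarray(val_data[2], dtype=object).astype(str)))
        history.append((point, acc))

    best_point, _ = max(history, key=lambda t: t[1])
    return ModelConfig(**{**asdict(base), **best_point,
                          "fc_stack": base.fc_stack})


# --------------------------------------------------------------------------
# cross-subject cross-validation
# --------------------------------------------------------------------------

def _subject_folds(labels: np.ndarray, subjects: np.ndarray, k: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Partition subjects into k folds, stratified by group."""
    subj_label = {}
    for s, l in zip(subjects, labels):
        subj_label[s] = str(l)
    groups: dict[str, list[str]] = {}
    for s, l in subj_label.items():
        groups.setdefault(l, []).append(s)
    folds: list[list[str]] = [[] for _ in range(k)]
    for l in sorted(groups):
        subs = sorted(groups[l])
        rng.shuffle(subs)
        for i, s in enumerate(subs):
            folds[i % k].append(s)
    return [np.array(f) for f in folds]


def cross_subject_cv(ecg: np.ndarray, emg: np.ndarray, labels: np.ndarray,
                     subjects: np.ndarray, k: int = 10,
                     cfg: ModelConfig | None = None) -> EvalReport:
    """k-fold cross-validation whose folds partition *subjects*, never windows.

    With 40 subjects in 4 balanced groups and ``k=10``, each fold holds out
    exactly one subject per group.  Train/test subject disjointness is
    asserted on every fold.  Metrics: accuracy and support-weighted F1,
    precision and recall per fold, plus a pooled confusion matrix.
    """
    cfg = cfg or ModelConfig()
    labels = np.asarray(labels).astype(str)
    subjects = np.asarray(subjects).astype(str)
    if np.unique(subjects).size < k:
        raise ValueError("need at least k subjects for k folds")
    rng = np.random.default_rng(cfg.seed)
    folds = _subject_folds(labels, subjects, k, rng)

    accs, f1s, precs, recs = [], [], [], []
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for fold_id, held_out in enumerate(folds):
        test_mask = np.isin(subjects, held_out)
        train_mask = ~test_mask
        assert not (set(subjects[train_mask]) & set(subjects[test_mask])), \
            "subject leakage between train and test"
        fold_cfg = ModelConfig(**{**asdict(cfg), "seed": cfg.seed + fold_id,
                                  "fc_stack": cfg.fc_stack})
        model = train(ecg[train_mask], emg[train_mask], labels[train_mask],
                      fold_cfg)
        pred = model.predict(ecg[test_mask], emg[test_mask])
        truth = labels[test_mask]
        accs.append(accuracy_score(truth, pred))
        f1s.append(f1_score(truth, pred, labels=list(CLASS_ORDER),
                            average="weighted", zero_division=0))
        precs.append(precision_score(truth, pred, labels=list(CLASS_ORDER),
                                     average="weighted", zero_division=0))
        recs.append(recall_score(truth, pred, labels=list(CLASS_ORDER),
                                 average="weighted", zero_division=0))
        conf += confusion_matrix(truth, pred, labels=list(CLASS_ORDER))
    return EvalReport(accuracy=np.array(accs), f1_weighted=np.array(f1s),
                      precision_weighted=np.array(precs),
                      recall_weighted=np.array(recs), confusion=conf,
                      fold_subjects=[list(f) for f in folds])
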