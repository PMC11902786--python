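"""Training protocol, cross-validation, ablation runner, baselines.

Protocol: Adam (initial learning rate 1e-3) with a stepped exponential
decay — ``lr(e) = lr0 * decay_rate ** floor(e / decay_step)`` with step
10 and rate 0.9 — mean cross-entropy loss, batch size 2048, 1000 epochs
at full scale (desk-scale runs reduce epochs/batch through TrainConfig).

Evaluation: stratified k-fold cross-validation (k=10), reporting the
fold-averaged OA/AA/kappa as the headline numbers plus the pooled
confusion matrix. The ablation runner re-uses identical folds and seeds
across the four network variants so comparisons are paired; the baseline
runner applies the same harness to standard classifiers (KNN, SVM, RF,
GBM, LDA, MLP from scikit-learn; compact 1D-CNN and Transformer
classifiers trained with the package's own autodiff engine).

Any per-band standardization is fitted on training folds only and then
applied to the corresponding test fold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autodiff import Adam, Parameter, Tensor, cross_entropy, softmax
from .data import SpectralDataset
from .mbnet import MBNet, VARIANTS
from .metrics import MetricsReport, evaluate

__all__ = ["TrainConfig", "CVResult", "lr_schedule", "train", "crossvalidate",
           "run_ablation", "run_baselines", "BASELINES", "MBNetClassifier",
           "save_checkpoint", "load_checkpoint", "fold_indices", "fold_hash"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol parameters (full-scale defaults)."""

    lr0: float = 1e-3
    decay_step: int = 10
    decay_rate: float = 0.9
    batch_size: int = 2048
    epochs: int = 1000
    seed: int = 0
    variant: str = "bidirectional"
    device: str = "cpu"          # execution target; this build is CPU-only
    standardize: bool = True     # per-band z-scoring, fitted on training data
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    model: dict = field(default_factory=dict)  # MBNet hyperparameter overrides

    def sub_seed(self, tag: str) -> int:
        """Named deterministic sub-seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{tag}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Stepped exponential decay: lr0 * rate ** floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.decay_rate ** (epoch // cfg.decay_step)


# --------------------------------------------------------------------------
# generic minibatch trainer for autodiff models
# --------------------------------------------------------------------------

def _fit_loop(forward, params: list[Parameter], X: np.ndarray, y: np.ndarray,
              cfg: TrainConfig, min_batch: int = 2) -> dict:
    """Shared Adam loop. `forward(xb, training)` returns logits."""
    rng = np.random.default_rng(cfg.sub_seed("shuffle"))
    opt = Adam(params, lr=cfg.lr0, betas=cfg.adam_betas, eps=cfg.adam_eps)
    n = X.shape[0]
    history = {"loss": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        perm = rng.permutation(n)
        starts = list(range(0, n, cfg.batch_size))
        # avoid a trailing undersized batch that BatchNorm cannot normalize
        if len(starts) > 1 and n - starts[-1] < min_batch:
            starts.pop()
        losses = []
        for s in starts:
            idx = perm[s:s + cfg.batch_size]
            logits = forward(X[idx], True)
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {epoch} "
                    f"(lr={lr:g}); inspect input scaling or lower lr0")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
    return history


# --------------------------------------------------------------------------
# estimators (all expose fit(X, y) / predict(X))
# --------------------------------------------------------------------------

class MBNetClassifier:
    """Estimator wrapper training an :class:`~burnspec.mbnet.MBNet`."""

    def __init__(self, cfg: TrainConfig, n_classes: int | None = None):
        self.cfg = cfg
        self.n_classes = n_classes
        self.model: MBNet | None = None
        self.history: dict | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MBNetClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training requires at least two classes present")
        n_classes = self.n_classes or int(y.max()) + 1
        kwargs = dict(self.cfg.model)
        kwargs.setdefault("seed", self.cfg.sub_seed("init"))
        self.model = MBNet(n_bands=X.shape[1], n_classes=n_classes, **kwargs)
        variant = self.cfg.variant
        fwd = lambda xb, training: self.model.forward(xb, variant=variant,
                                                      training=training)
        self.history = _fit_loop(fwd, self.model.parameters(), X, y, self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=np.float32),
                                  variant=self.cfg.variant)

    def training_accuracy(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _relu(t: Tensor) -> Tensor:
    return t.leaky_relu(0.0)


class Conv1DClassifier:
    """Compact 1-D CNN over the band axis: two valid convolutions with
    stride-2 subsampling, global average pooling, linear head."""

    def __init__(self, cfg: TrainConfig, channels=(16, 32), kernels=(7, 5),
                 n_classes: int | None = None):
        self.cfg = cfg
        self.channels = channels
        self.kernels = kernels
        self.n_classes = n_classes
        self.params: list[Parameter] = []

    def _conv(self, x: Tensor, W: Parameter, b: Parameter, k: int) -> Tensor:
        L = x.shape[1]
        out = None
        for j in range(k):
            term = x[:, j:L - k + 1 + j, :] @ W[j]
            out = term if out is None else out + term
        return out + b

    def _build(self, n_bands: int, n_classes: int, rng) -> None:
        c1, c2 = self.channels
        k1, k2 = self.kernels
        u = lambda shape, fan: Parameter(
            rng.uniform(-1 / np.sqrt(fan), 1 / np.sqrt(fan), shape).astype(np.float32))
        self.W1, self.b1 = u((k1, 1, c1), k1), u((c1,), k1)
        self.W2, self.b2 = u((k2, c1, c2), k2 * c1), u((c2,), k2 * c1)
        self.Wh, self.bh = u((c2, n_classes), c2), u((n_classes,), c2)
        self.params = [self.W1, self.b1, self.W2, self.b2, self.Wh, self.bh]

    def _forward(self, xb: np.ndarray, training: bool) -> Tensor:
        x = Tensor(xb.astype(np.float32)).reshape(xb.shape[0], xb.shape[1], 1)
        x = _relu(self._conv(x, self.W1, self.b1, self.kernels[0]))[:, ::2, :]
        x = _relu(self._conv(x, self.W2, self.b2, self.kernels[1]))
        return x.mean(axis=1) @ self.Wh + self.bh

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y)
        rng = np.random.default_rng(self.cfg.sub_seed("cnn1d"))
        self._build(X.shape[1], self.n_classes or int(y.max()) + 1, rng)
        self.history = _fit_loop(self._forward, self.params, X, y, self.cfg,
                                 min_batch=1)
        return self

    def predict(self, X):
        return np.argmax(self._forward(np.asarray(X), False).data, axis=1)


class TransformerClassifier:
    """Single-block Transformer encoder over the band sequence:
    sinusoidal positions, one self-attention head, a 2x feed-forward,
    layer norm and residuals, mean pooling, linear head."""

    def __init__(self, cfg: TrainConfig, model_dim: int = 16,
                 n_classes: int | None = None):
        self.cfg = cfg
        self.m = model_dim
        self.n_classes = n_classes

    @staticmethod
    def _positions(L: int, m: int) -> np.ndarray:
        pos = np.arange(L)[:, None]
        i = np.arange(m)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / m)
        enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        return enc.astype(np.float32)

    def _layernorm(self, x: Tensor, g: Parameter, b: Parameter) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + 1e-5).sqrt() * g + b

    def _build(self, n_bands, n_classes, rng):
        m = self.m
        u = lambda shape, fan: Parameter(
            rng.uniform(-1 / np.sqrt(fan), 1 / np.sqrt(fan), shape).astype(np.float32))
        ones = lambda: Parameter(np.ones(m, dtype=np.float32))
        zeros = lambda: Parameter(np.zeros(m, dtype=np.float32))
        self.We, self.be = u((1, m), 1), zeros()
        self.Wq, self.Wk, self.Wv, self.Wo = (u((m, m), m) for _ in range(4))
        self.g1, self.bn1 = ones(), zeros()
        self.W_ff1, self.b_ff1 = u((m, 2 * m), m), u((2 * m,), m)
        self.W_ff2, self.b_ff2 = u((2 * m, m), 2 * m), u((m,), 2 * m)
        self.g2, self.bn2 = ones(), zeros()
        self.Wh, self.bh = u((m, n_classes), m), u((n_classes,), m)
        self.pos = self._positions(n_bands, m)
        self.params = [self.We, self.be, self.Wq, self.Wk, self.Wv, self.Wo,
                       self.g1, self.bn1, self.W_ff1, self.b_ff1,
                       self.W_ff2, self.b_ff2, self.g2, self.bn2,
                       self.Wh, self.bh]

    def _forward(self, xb: np.ndarray, training: bool) -> Tensor:
        B, L = xb.shape
        x = Tensor(xb.astype(np.float32)).reshape(B, L, 1) @ self.We + self.be
        x = x + self.pos
        h = self._layernorm(x, self.g1, self.bn1)
        q, k, v = h @ self.Wq, h @ self.Wk, h @ self.Wv
        att = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.m)), axis=-1)
        x = x + (att @ v) @ self.Wo
        h = self._layernorm(x, self.g2, self.bn2)
        x = x + _relu(h @ self.W_ff1 + self.b_ff1) @ self.W_ff2 + self.b_ff2
        return x.mean(axis=1) @ self.Wh + self.bh

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y)
        rng = np.random.default_rng(self.cfg.sub_seed("transformer"))
        self._build(X.shape[1], self.n_classes or int(y.max()) + 1, rng)
        self.history = _fit_loop(self._forward, self.params, X, y, self.cfg,
                                 min_batch=1)
        return self

    def predict(self, X):
        return np.argmax(self._forward(np.asarray(X), False).data, axis=1)


class _Pipeline:
    """Optional per-band standardization (train-fold statistics only)
    in front of any estimator."""

    def __init__(self, estimator, standardize: bool):
        self.estimator = estimator
        self.scaler = StandardScaler() if standardize else None

    def fit(self, X, y):
        if self.scaler is not None:
            X = self.scaler.fit_transform(X)
        self.estimator.fit(X, y)
        return self

    def predict(self, X):
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.estimator.predict(X)


BASELINES = ("knn", "svm", "rf", "gbm", "lda", "mlp", "cnn1d", "transformer")


def make_estimator(name: str, cfg: TrainConfig):
    """Baseline registry. Hyperparameters follow common practice for
    spectral tables; all are overridable by constructing the estimator
    directly."""
    seed = cfg.sub_seed(name)
    registry = {
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "svm": lambda: SVC(kernel="rbf", C=10.0, gamma="scale",
                           random_state=seed),
        "rf": lambda: RandomForestClassifier(n_estimators=200,
                                             random_state=seed),
        "gbm": lambda: HistGradientBoostingClassifier(random_state=seed),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "mlp": lambda: MLPClassifier(hidden_layer_sizes=(100,), max_iter=400,
                                     random_state=seed),
        "cnn1d": lambda: Conv1DClassifier(cfg),
        "transformer": lambda: TransformerClassifier(cfg),
        "mbnet": lambda: MBNetClassifier(cfg),
    }
    if name not in registry:
        raise KeyError(f"unknown estimator {name!r}; known: {sorted(registry)}")
    return registry[name]()


# --------------------------------------------------------------------------
# training entry point
# --------------------------------------------------------------------------

def train(dataset: SpectralDataset, cfg: TrainConfig
          ) -> tuple["_Pipeline", dict]:
    """Train the network on the full dataset; returns the fitted pipeline
    (standardizer + MBNetClassifier, whose ``.estimator.model`` is the
    MBNet) and the per-epoch loss / learning-rate history."""
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")
    pipe = _Pipeline(MBNetClassifier(cfg, n_classes=dataset.n_classes),
                     cfg.standardize)
    pipe.fit(dataset.spectra, dataset.labels)
    return pipe, pipe.estimator.history


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def fold_indices(labels: np.ndarray, k: int, seed: int
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; every class must have >= k samples."""
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    small = np.flatnonzero(counts < k)
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than k={k} samples; "
            f"reduce k or generate more samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def fold_hash(folds: list[tuple[np.ndarray, np.ndarray]]) -> str:
    h = hashlib.sha256()
    for _, te in folds:
        h.update(np.sort(te).astype(np.int64).tobytes())
    return h.hexdigest()


@dataclass
class CVResult:
    per_fold: list[MetricsReport]
    mean_report: MetricsReport
    pooled_confusion: np.ndarray
    folds_hash: str
    history: list[dict] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_report.to_dict(),
            "per_fold": [r.to_dict() for r in self.per_fold],
            "pooled_confusion": self.pooled_confusion.tolist(),
            "folds_hash": self.folds_hash,
        }


def _mean_report(reports: list[MetricsReport], pooled: np.ndarray) -> MetricsReport:
    per_class = np.nanmean([r.per_class_accuracy for r in reports], axis=0)
    return MetricsReport(
        OA=float(np.mean([r.OA for r in reports])),
        AA=float(np.mean([r.AA for r in reports])),
        Kappa=float(np.mean([r.Kappa for r in reports])),
        per_class_accuracy=per_class,
        Po=float(np.mean([r.Po for r in reports])),
        Pe=float(np.mean([r.Pe for r in reports])),
        confusion=pooled)


def crossvalidate(dataset: SpectralDataset, cfg: TrainConfig, k: int = 10,
                  model: str = "mbnet",
                  folds: list[tuple[np.ndarray, np.ndarray]] | None = None
                  ) -> CVResult:
    """Stratified k-fold cross-validation of one estimator.

    Headline numbers are the fold-averaged OA/AA/kappa; the pooled
    (summed) confusion matrix is reported alongside. Standardization,
    when enabled, is fitted inside each training fold.
    """
    if folds is None:
        folds = fold_indices(dataset.labels, k, cfg.sub_seed("splits"))
    reports, histories = [], []
    pooled = np.zeros((dataset.n_classes, dataset.n_classes), dtype=np.int64)
    for tr, te in folds:
        est = _Pipeline(make_estimator(model, cfg), cfg.standardize)
        est.fit(dataset.spectra[tr], dataset.labels[tr])
        pred = est.predict(dataset.spectra[te])
        rep = evaluate(dataset.labels[te], pred, dataset.n_classes)
        reports.append(rep)
        pooled += rep.confusion
        hist = getattr(est.estimator, "history", None)
        if isinstance(hist, dict):
            histories.append(hist)
    return CVResult(per_fold=reports,
                    mean_report=_mean_report(reports, pooled),
                    pooled_confusion=pooled,
                    folds_hash=fold_hash(folds),
                    history=histories)


# --------------------------------------------------------------------------
# ablation + baselines
# --------------------------------------------------------------------------

def run_ablation(dataset: SpectralDataset, cfg: TrainConfig, k: int = 10
                 ) -> dict[str, CVResult]:
    """Cross-validate all four network variants on identical folds with
    identical seeds (paired comparison)."""
    folds = fold_indices(dataset.labels, k, cfg.sub_seed("splits"))
    out = {}
    for variant in VARIANTS:
        vcfg = replace(cfg, variant=variant)
        out[variant] = crossvalidate(dataset, vcfg, k=k, model="mbnet",
                                     folds=folds)
    hashes = {r.folds_hash for r in out.values()}
    assert len(hashes) == 1, "ablation variants must share folds"
    return out


def ablation_table(results: dict[str, CVResult]):
    """Metric-by-variant table (OA/AA in %, kappa as a coefficient)."""
    import pandas as pd
    cols = {}
    for variant, res in results.items():
        m = res.mean_report
        cols[variant] = [100 * m.OA, 100 * m.AA, m.Kappa]
    return pd.DataFrame(cols, index=["OA (%)", "AA (%)", "Kappa"])


def run_baselines(dataset: SpectralDataset, cfg: TrainConfig, k: int = 10,
                  names: tuple[str, ...] = BASELINES + ("mbnet",)
                  ) -> dict[str, CVResult | str]:
    """Cross-validate every requested estimator on identical folds. An
    estimator that raises is recorded as an error string, not fatal."""
    folds = fold_indices(dataset.labels, k, cfg.sub_seed("splits"))
    out: dict[str, CVResult | str] = {}
    for name in names:
        try:
            out[name] = crossvalidate(dataset, cfg, k=k, model=name,
                                      folds=folds)
        except Exception as exc:  # report, continue with the rest
            out[name] = f"failed: {type(exc).__name__}: {exc}"
    hashes = {r.folds_hash for r in out.values() if isinstance(r, CVResult)}
    assert len(hashes) <= 1, "baselines must share folds"
    return out


def baseline_table(results: dict[str, CVResult | str],
                   class_names: list[str]):
    """Per-class accuracy + OA/AA/kappa, one column per method."""
    import pandas as pd
    cols = {}
    for name, res in results.items():
        if isinstance(res, str):
            cols[name] = [np.nan] * (len(class_names) + 3)
            continue
        m = res.mean_report
        cols[name] = ([100 * a for a in m.per_class_accuracy]
                      + [100 * m.OA, 100 * m.AA, m.Kappa])
    idx = list(class_names) + ["OA (%)", "AA (%)", "Kappa"]
    return pd.DataFrame(cols, index=idx)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(clf: MBNetClassifier, path, scaler: StandardScaler | None = None
                    ) -> Path:
    """Single-archive checkpoint: all parameter arrays + the config that
    produced them (JSON), + optional standardizer statistics."""
    path = Path(path)
    arrays = clf.model.state_arrays()
    meta = {"model": clf.model.config, "train": {
        "lr0": clf.cfg.lr0, "decay_step": clf.cfg.decay_step,
        "decay_rate": clf.cfg.decay_rate, "batch_size": clf.cfg.batch_size,
        "epochs": clf.cfg.epochs, "seed": clf.cfg.seed,
        "variant": clf.cfg.variant, "standardize": clf.cfg.standardize,
    }}
    if scaler is not None:
        arrays["scaler_mean"] = scaler.mean_
        arrays["scaler_scale"] = scaler.scale_
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path, expect_bands: int | None = None,
                    expect_classes: int | None = None) -> MBNetClassifier:
    """Rebuild a trained classifier; fails loudly if the checkpoint's band
    or class count does not match what the caller expects."""
    with np.load(Path(path)) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    mc = meta["model"]
    if expect_bands is not None and mc["n_bands"] != expect_bands:
        raise ValueError(f"checkpoint was trained on {mc['n_bands']} bands, "
                         f"dataset has {expect_bands}")
    if expect_classes is not None and mc["n_classes"] != expect_classes:
        raise ValueError(f"checkpoint predicts {mc['n_classes']} classes, "
                         f"dataset has {expect_classes}")
    cfg = TrainConfig(**{k: v for k, v in meta["train"].items()
                         if k in TrainConfig.__dataclass_fields__})
    clf = MBNetClassifier(cfg, n_classes=mc["n_classes"])
    clf.model = MBNet(**mc)
    scaler = None
    if "scaler_mean" in arrays:
        scaler = StandardScaler()
        scaler.mean_ = arrays.pop("scaler_mean")
        scaler.scale_ = arrays.pop("scaler_scale")
        scaler.var_ = scaler.scale_ ** 2
    clf.model.load_state_arrays(arrays)
    clf.scaler = scaler
    return clf
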