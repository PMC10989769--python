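"""Species-level identification of single cells from Raman fingerprints.

The classifier is an 18-layer one-dimensional residual network — a
wide-kernel stem convolution, eight residual blocks of two convolutions
each (17 convolutional layers in total), and one fully connected softmax
head.  Large-kernel convolutions are used throughout and no global average
pooling, so the exact wavenumber positions of fingerprint peaks are
preserved up to the classification head.  Inputs are preprocessed spectra
resampled to a fixed-length grid over the fingerprint region
(600-1800 cm^-1 by default).

Random-forest and support-vector-machine baselines share the same feature
extraction and prediction interface.  Community-level utilities estimate
class proportions among (live) cells of a sample and test their
consistency against expected proportions with a chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from . import nn
from .errors import RamavitError
from .spectra import Band, Ramanome, Spectrum, resample

__all__ = [
    "LabeledRamanome",
    "ClassifierConfig",
    "ClassifierModel",
    "EvalReport",
    "ProportionEstimate",
    "ChiSquareResult",
    "CHI2_DEFAULT_THRESHOLD",
    "train_cnn",
    "train_baselines",
    "predict",
    "evaluate",
    "estimate_proportions",
    "chi_square_consistency",
]

#: The conventional consistency cutoff: the upper-5% point of the
#: chi-square distribution with 5 degrees of freedom, to three decimals.
CHI2_DEFAULT_THRESHOLD = round(float(stats.chi2.isf(0.05, 5)), 3)


@dataclass
class LabeledRamanome:
    """A ramanome whose every cell carries a species label."""

    ramanome: Ramanome
    classes: list[str] = field(default_factory=list)

    def __post_init__(self):
        labels = [s.meta.species_label for s in self.ramanome]
        if any(l is None or l == "" for l in labels):
            raise RamavitError("every cell must carry a species_label")
        if not self.classes:
            self.classes = sorted(set(labels))
        unknown = set(labels) - set(self.classes)
        if unknown:
            raise RamavitError(f"labels outside the class list: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [s.meta.species_label for s in self.ramanome]

    def __len__(self):
        return len(self.ramanome)


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training settings for the residual CNN.

    The layer plan is fixed at one stem convolution (kernel
    ``kernel_stem``) plus ``n_blocks`` residual blocks of two convolutions
    (kernel ``kernel_block``) plus one fully connected layer; channel
    width doubles every two blocks, and every second block halves the
    sequence length with stride 2.  With the default ``n_blocks=8`` this
    gives 17 convolutional layers and 18 weighted layers in total.
    """

    input_region: Band = field(default_factory=lambda: Band("fingerprint", 600.0, 1800.0))
    input_length: int = 300
    n_classes: int = 2
    base_channels: int = 4
    kernel_stem: int = 21
    kernel_block: int = 11
    n_blocks: int = 8
    epochs: int = 12
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    standardize: bool = True

    @property
    def n_conv_layers(self) -> int:
        return 1 + 2 * self.n_blocks

    @property
    def n_weighted_layers(self) -> int:
        return self.n_conv_layers + 1

    def __post_init__(self):
        if self.n_classes < 2:
            raise RamavitError("need at least 2 classes")
        if self.input_length < 16:
            raise RamavitError("input_length too short")

    def grid(self) -> np.ndarray:
        return np.linspace(
            self.input_region.lo_cm1, self.input_region.hi_cm1, self.input_length
        )


class SpectralResNet:
    """The 17-conv + 1-FC residual network on (N, 1, L) spectral input."""

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.stem = nn.Sequential(
            nn.Conv1d(1, c, cfg.kernel_stem, rng=rng),
            nn.BatchNorm(c),
            nn.ReLU(),
        )
        self.blocks: list[nn.ResidualBlock1d] = []
        cin, length = c, cfg.input_length
        for b in range(cfg.n_blocks):
            stride = 2 if (b % 2 == 0 and b > 0) else 1
            cout = cin * 2 if stride == 2 else cin
            self.blocks.append(
                nn.ResidualBlock1d(cin, cout, cfg.kernel_block, stride, rng)
            )
            if stride == 2:
                length = -(-length // 2)
            cin = cout
        self.flat = nn.Flatten()
        self.fc = nn.Dense(cin * length, cfg.n_classes, rng=rng)
        self.cfg = cfg

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out + self.fc.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.stem.forward(x, train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.fc.forward(self.flat.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.flat.backward(self.fc.backward(dlogits))
        for b in reversed(self.blocks):
            d = b.backward(d)
        self.stem.backward(d)

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> list[float]:
        cfg = self.cfg
        opt = nn.Adam(self.params(), lr=cfg.lr)
        n = X.shape[0]
        losses = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = X[idx][:, None, :]
                opt.zero_grad()
                logits = self.forward(xb, train=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
                self.backward(dlogits)
                opt.step()
                ep_loss += loss * idx.size
            losses.append(ep_loss / n)
        return losses

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for start in range(0, X.shape[0], batch):
            logits = self.forward(X[start : start + batch][:, None, :], train=False)
            out.append(nn.softmax(logits))
        return np.vstack(out) if out else np.empty((0, self.cfg.n_classes))


@dataclass
class ClassifierModel:
    """A trained classifier plus everything needed to apply it."""

    kind: str  # "cnn" | "rf" | "svm"
    estimator: object
    classes: list[str]
    grid: np.ndarray
    config: ClassifierConfig

    def transform(self, r: Ramanome) -> np.ndarray:
        X = np.empty((len(r), self.grid.size))
        for i, s in enumerate(r):
            X[i] = resample(s, self.grid).intensities
        if self.config.standardize and X.size:
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
        return X

    def predict_proba(self, r: Ramanome) -> np.ndarray:
        X = self.transform(r)
        if not X.size:
            return np.empty((0, len(self.classes)))
        if self.kind == "cnn":
            return self.estimator.predict_proba(X)
        proba = self.estimator.predict_proba(X)
        # sklearn orders columns by its own classes_; re-order to ours
        order = [list(self.estimator.classes_).index(c) for c in self.classes]
        return proba[:, order]


@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray  # row-normalised fractions
    per_class_acc: np.ndarray
    mean_acc: float
    sd_acc: float
    n_splits: int
    split_accs: tuple[float, ...] = ()


@dataclass(frozen=True)
class ProportionEstimate:
    proportions: dict[str, float]
    n_cells: int
    live_only: bool

    def __post_init__(self):
        tot = sum(self.proportions.values())
        if abs(tot - 1.0) > 1e-6:
            raise RamavitError("proportions must sum to 1")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    threshold: float
    consistent: bool


# ---------------------------------------------------------------------------
# training

def _check_training_set(train: LabeledRamanome) -> None:
    if len(train.classes) < 2:
        raise RamavitError("training needs at least 2 classes")
    counts: dict[str, int] = {}
    for l in train.labels:
        counts[l] = counts.get(l, 0) + 1
    thin = [c for c in train.classes if counts.get(c, 0) < 2]
    if thin:
        raise RamavitError(f"classes with fewer than 2 training spectra: {thin}")


def train_cnn(train: LabeledRamanome, cfg: ClassifierConfig | None = None) -> ClassifierModel:
    """Train the residual CNN; deterministic under ``cfg.seed``."""
    _check_training_set(train)
    cfg = cfg or ClassifierConfig()
    if cfg.n_classes != len(train.classes):
        cfg = replace(cfg, n_classes=len(train.classes))
    rng = np.random.default_rng(cfg.seed)
    net = SpectralResNet(cfg, rng)
    model = ClassifierModel(
        kind="cnn", estimator=net, classes=list(train.classes), grid=cfg.grid(), config=cfg
    )
    X = model.transform(train.ramanome)
    y = np.array([train.classes.index(l) for l in train.labels])
    net.fit(X, y, rng)
    return model


def train_baselines(
    train: LabeledRamanome, kind: str, cfg: ClassifierConfig | None = None
) -> ClassifierModel:
    """Random-forest or SVM baseline over the same resampled features."""
    _check_training_set(train)
    cfg = cfg or ClassifierConfig()
    if cfg.n_classes != len(train.classes):
        cfg = replace(cfg, n_classes=len(train.classes))
    if kind == "rf":
        est = RandomForestClassifier(n_estimators=200, random_state=cfg.seed % (2**31))
    elif kind == "svm":
        est = SVC(kernel="rbf", probability=True, random_state=cfg.seed % (2**31))
    else:
        raise RamavitError(f"unknown baseline kind {kind!r} (use 'rf' or 'svm')")
    model = ClassifierModel(
        kind=kind, estimator=est, classes=list(train.classes), grid=cfg.grid(), config=cfg
    )
    X = model.transform(train.ramanome)
    y = np.array(train.labels)
    est.fit(X, y)
    return model


def predict(model: ClassifierModel, r: Ramanome) -> tuple[list[str], np.ndarray]:
    """Per-cell predicted class and full probability vector.

    The predicted class is the argmax of the probability vector; exact
    ties resolve to the lowest class index.
    """
    proba = model.predict_proba(r)
    labels = [model.classes[int(np.argmax(p))] for p in proba]
    return labels, proba


# ---------------------------------------------------------------------------
# evaluation

def evaluate(
    model_factory: Callable[[LabeledRamanome], ClassifierModel],
    data: LabeledRamanome,
    n_splits: int = 3,
    test_size: float = 0.3,
    seed: int = 0,
) -> EvalReport:
    """Stratified random-split evaluation: accuracy mean +/- SD across
    splits and a pooled row-normalised confusion matrix."""
    if n_splits < 2:
        raise RamavitError("n_splits must be >= 2")
    labels = np.array(data.labels)
    classes = data.classes
    k = len(classes)
    pooled = np.zeros((k, k))
    accs = []
    for split in range(n_splits):
        test_idx = None
        for attempt in range(10):
            sss = StratifiedShuffleSplit(
                n_splits=1,
                test_size=test_size,
                random_state=(seed * 1000 + split * 10 + attempt) % (2**31),
            )
            tr, te = next(sss.split(np.zeros(len(labels)), labels))
            if set(labels[te]) == set(classes):
                test_idx = (tr, te)
                break
        if test_idx is None:
            raise RamavitError("could not draw a split containing every class")
        tr, te = test_idx
        sub_train = LabeledRamanome(
            Ramanome([data.ramanome.spectra[i] for i in tr]), classes=list(classes)
        )
        sub_test = Ramanome([data.ramanome.spectra[i] for i in te])
        model = model_factory(sub_train)
        pred, _ = predict(model, sub_test)
        truth = labels[te]
        accs.append(float(np.mean(np.array(pred) == truth)))
        pooled += _sk_confusion(truth, pred, labels=classes)
    rows = pooled.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    conf = pooled / rows
    accs_arr = np.array(accs)
    return EvalReport(
        confusion=conf,
        per_class_acc=np.diag(conf),
        mean_acc=float(accs_arr.mean()),
        sd_acc=float(accs_arr.std(ddof=1)),
        n_splits=n_splits,
        split_accs=tuple(accs),
    )


# ---------------------------------------------------------------------------
# community composition

def estimate_proportions(
    predictions: Sequence[str],
    live_flags: Sequence[bool] | None = None,
    classes: Sequence[str] | None = None,
) -> ProportionEstimate:
    """Class frequencies among (optionally live-only) predicted cells."""
    preds = list(predictions)
    if live_flags is not None:
        if len(live_flags) != len(preds):
            raise RamavitError("live_flags must match predictions in length")
        preds = [p for p, alive in zip(preds, live_flags) if alive]
    if not preds:
        raise RamavitError("no cells left after live-only filtering")
    keys = list(classes) if classes is not None else sorted(set(preds))
    counts = {c: 0 for c in keys}
    for p in preds:
        if p not in counts:
            raise RamavitError(f"prediction {p!r} outside the class list")
        counts[p] += 1
    n = len(preds)
    return ProportionEstimate(
        proportions={c: counts[c] / n for c in keys},
        n_cells=n,
        live_only=live_flags is not None,
    )


def chi_square_consistency(
    observed_counts: Mapping[str, float],
    expected_props: Mapping[str, float],
    threshold: float | None = None,
    df_mode: bool = False,
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of observed counts against expected
    proportions.

    ``statistic = sum (O_i - E_i)^2 / E_i`` with ``E_i = n * p_i``.  By
    default the consistency cutoff is the conventional 11.070 (upper-5%
    chi-square point at 5 df); ``df_mode=True`` derives the cutoff from
    the actual ``k - 1`` degrees of freedom instead.
    """
    if set(observed_counts) != set(expected_props):
        raise RamavitError("observed and expected must share the same keys")
    ps = np.array([expected_props[c] for c in observed_counts])
    if abs(ps.sum() - 1.0) > 1e-6:
        raise RamavitError("expected proportions must sum to 1")
    obs = np.array([observed_counts[c] for c in observed_counts], dtype=float)
    n = obs.sum()
    exp = n * ps
    if np.any((exp == 0) & (obs > 0)):
        raise RamavitError("zero expected proportion with nonzero observed count")
    nz = exp > 0
    stat = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    if threshold is None:
        threshold = (
            round(float(stats.chi2.isf(alpha, len(obs) - 1)), 3)
            if df_mode
            else CHI2_DEFAULT_THRESHOLD
        )
    return ChiSquareResult(statistic=stat, threshold=threshold, consistent=stat <= threshold)
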