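"""Subject classification from gait features.

Supports the classifiers used for two-group (disease vs. control)
separation on a small pattern matrix of per-subject features:

* single-feature threshold rules with a full ROC / accuracy sweep,
* a two-layer sigmoidal feed-forward network (default architecture
  2-4-2, i.e. 2 features, 4 hidden units, 2 one-hot outputs),
* a radial-basis-function network with k-means centres and Gaussian
  units of fixed spread,
* a hard-limit perceptron,

together with confusion-matrix metrics (sensitivity, specificity,
accuracy) and stratified K-fold / leave-one-out cross-validation.

Convention: the disease group is the *positive* class and sits low on
both stride length and gait velocity, so threshold rules default to
``lower_is_positive``.  Feature matrices are (n_subjects, n_features);
the column-per-subject pattern matrix of the classical notation is
available via :class:`PatternMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

log = logging.getLogger(__name__)

LOWER = "lower_is_positive"
HIGHER = "higher_is_positive"


# -- confusion counts and metrics ---------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts for binary predictions against binary truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tp=int(np.sum(pred & truth)),
    )


@dataclass(frozen=True)
class ClassifierMetrics:
    """Rates in [0, 1]: TPR (sensitivity), FNR, TNR (specificity), FPR, ACCU."""

    tpr: float
    fnr: float
    tnr: float
    fpr: float
    accuracy: float

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return self.tnr

    @property
    def misclassification(self) -> float:
        return 1.0 - self.accuracy

    def as_percent(self) -> dict:
        return {
            "SE_pct": 100 * self.tpr,
            "SP_pct": 100 * self.tnr,
            "FPR_pct": 100 * self.fpr,
            "FNR_pct": 100 * self.fnr,
            "ACCU_pct": 100 * self.accuracy,
            "misclassified_pct": 100 * self.misclassification,
        }


def metrics(c: ConfusionCounts) -> ClassifierMetrics:
    """Sensitivity, specificity, and accuracy from confusion counts."""
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    return ClassifierMetrics(
        tpr=c.tp / n_pos,
        fnr=c.fn / n_pos,
        tnr=c.tn / n_neg,
        fpr=c.fp / n_neg,
        accuracy=(c.tp + c.tn) / c.total,
    )


# -- pattern matrix ------------------------------------------------------


@dataclass
class PatternMatrix:
    """Feature matrix P (R features x Q subjects) with binary labels.

    Labels code the positive (disease) class as 1 and the reference
    class as 0; :attr:`targets` exposes the one-hot (2 x Q) target matrix
    used by the two-output network.
    """

    features: np.ndarray  # (R, Q)
    labels: np.ndarray  # (Q,) in {0, 1}
    subject_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (R, Q)")
        if self.features.shape[1] != len(self.labels):
            raise ValueError("labels must align with feature columns")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("pattern matrix contains non-finite values")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be binary")

    @property
    def X(self) -> np.ndarray:
        """(Q, R) sample-per-row view."""
        return self.features.T

    @property
    def targets(self) -> np.ndarray:
        """One-hot target matrix (2, Q): row 0 reference, row 1 positive."""
        return np.vstack([1 - self.labels, self.labels]).astype(float)

    @classmethod
    def from_feature_table(
        cls,
        table,
        feature_columns=("sl_m", "gv_mps"),
        positive: str = "PD",
        negative: str = "NORM",
    ) -> "PatternMatrix":
        sub = table[table.group.isin([positive, negative])]
        if sub.empty or sub.group.nunique() < 2:
            raise ValueError("need subjects from both groups")
        return cls(
            features=sub[list(feature_columns)].to_numpy().T,
            labels=(sub.group == positive).to_numpy().astype(int),
            subject_ids=list(sub.subject_id),
            feature_names=list(feature_columns),
        )


# -- threshold sweep / ROC ----------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tp: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    accuracy: np.ndarray
    direction: str
    optimal_threshold: float
    optimal_counts: ConfusionCounts
    optimal_metrics: ClassifierMetrics

    def counts_at(self, i: int) -> ConfusionCounts:
        return ConfusionCounts(
            tn=int(self.tn[i]), fp=int(self.fp[i]),
            fn=int(self.fn[i]), tp=int(self.tp[i]),
        )


def roc_sweep(values, truth, direction: str = LOWER) -> ROCResult:
    """Exhaustive threshold sweep with ROC points and the optimal threshold.

    Candidate thresholds are the midpoints between consecutive sorted
    unique feature values plus -inf and +inf.  With
    ``direction="lower_is_positive"`` a subject is predicted positive when
    its value is below the threshold.  The optimal threshold maximises
    accuracy; ties break toward the larger sensitivity+specificity, then
    toward the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if values.shape != truth.shape or values.ndim != 1:
        raise ValueError("values and truth must be equal-length 1-D arrays")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one subject per class")
    if direction not in (LOWER, HIGHER):
        raise ValueError(f"unknown direction {direction!r}")

    u = np.unique(values)
    if len(u) == 1:
        warnings.warn("constant feature: degenerate ROC", stacklevel=2)
        thresholds = np.array([-np.inf, np.inf])
    else:
        thresholds = np.concatenate(
            [[-np.inf], 0.5 * (u[:-1] + u[1:]), [np.inf]]
        )

    pos = np.sort(values[truth])
    neg = np.sort(values[~truth])
    # number of class members strictly below each threshold
    pos_below = np.searchsorted(pos, thresholds, side="left")
    neg_below = np.searchsorted(neg, thresholds, side="left")
    if direction == LOWER:
        tp, fp = pos_below, neg_below
    else:
        tp, fp = n_pos - pos_below, n_neg - neg_below
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    accuracy = (tp + tn) / (n_pos + n_neg)

    balance = tpr + (tn / n_neg)
    # lexsort: last key is primary; prefer high accuracy, then high SE+SP,
    # then small threshold
    order = np.lexsort((thresholds, -balance, -accuracy))
    best = order[0]
    counts = ConfusionCounts(
        tn=int(tn[best]), fp=int(fp[best]), fn=int(fn[best]), tp=int(tp[best])
    )
    return ROCResult(
        thresholds=thresholds,
        tn=tn, fp=fp, fn=fn, tp=tp,
        fpr=fpr, tpr=tpr, accuracy=accuracy,
        direction=direction,
        optimal_threshold=float(thresholds[best]),
        optimal_counts=counts,
        optimal_metrics=metrics(counts),
    )


# -- classifiers ---------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    p = x >= 0
    out[p] = 1.0 / (1.0 + np.exp(-x[p]))
    e = np.exp(x[~p])
    out[~p] = e / (1.0 + e)
    return out


def _stratified_split(y: np.ndarray, fractions, rng: np.random.Generator):
    """Per-class shuffled index split into train/val/test."""
    f_train, f_val, _ = fractions
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(round(f_val * n))
        n_test = int(round((1.0 - f_train - f_val) * n))
        n_train = n - n_val - n_test
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train:n_train + n_val])
        parts[2].extend(idx[n_train + n_val:])
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


@dataclass
class MLPModel:
    """Two-layer sigmoidal network with one-hot outputs.

    Activations A1 = F(W1 x + b1), A2 = F(W2 A1 + b2) with the logistic
    sigmoid F; the decision is the argmax over the two output rows
    (row 0 reference, row 1 positive).  Inputs are standardised with the
    training-split statistics stored on the model.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    seed: int
    splits: tuple
    n_epochs: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def activations(self, X) -> tuple[np.ndarray, np.ndarray]:
        Xs = ((np.asarray(X, dtype=float) - self.mu) / self.sd).T  # (R, Q)
        A1 = _sigmoid(self.W1 @ Xs + self.b1)
        A2 = _sigmoid(self.W2 @ A1 + self.b2)
        return A1, A2

    def predict(self, X) -> np.ndarray:
        _, A2 = self.activations(X)
        return np.argmax(A2, axis=0)


def train_mlp(
    X,
    y,
    hidden: int = 4,
    seed: int = 0,
    splits: tuple = (0.6, 0.2, 0.2),
    lr: float = 0.5,
    momentum: float = 0.9,
    max_epochs: int = 800,
    patience: int = 80,
) -> MLPModel:
    """Train the two-layer sigmoidal network by full-batch gradient descent.

    The squared error between the output activations and the one-hot
    targets is minimised on the training split; the validation split
    provides early stopping (best-weights restore).  Deterministic for a
    given (data, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    rng = np.random.default_rng(seed)
    tr, va, te = _stratified_split(y, splits, rng)
    if len(tr) == 0:
        raise ValueError("empty training split")

    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd[sd == 0] = 1.0
    T = np.vstack([1 - y, y]).astype(float)  # (2, Q)
    Xs = ((X - mu) / sd).T  # (R, Q)

    R, S1, S2 = X.shape[1], hidden, 2
    W1 = rng.uniform(-0.5, 0.5, size=(S1, R)) / np.sqrt(R)
    b1 = np.zeros((S1, 1))
    W2 = rng.uniform(-0.5, 0.5, size=(S2, S1)) / np.sqrt(S1)
    b2 = np.zeros((S2, 1))
    vel = [np.zeros_like(w) for w in (W1, b1, W2, b2)]

    Xtr, Ttr = Xs[:, tr], T[:, tr]
    Xva, Tva = (Xs[:, va], T[:, va]) if len(va) else (Xtr, Ttr)
    best = (np.inf, None, 0)
    n = Xtr.shape[1]
    for epoch in range(1, max_epochs + 1):
        A1 = _sigmoid(W1 @ Xtr + b1)
        A2 = _sigmoid(W2 @ A1 + b2)
        d2 = (A2 - Ttr) * A2 * (1 - A2)  # (S2, n)
        d1 = (W2.T @ d2) * A1 * (1 - A1)
        grads = (
            d1 @ Xtr.T / n,
            d1.mean(axis=1, keepdims=True),
            d2 @ A1.T / n,
            d2.mean(axis=1, keepdims=True),
        )
        params = [W1, b1, W2, b2]
        for i, (p, g) in enumerate(zip(params, grads)):
            vel[i] = momentum * vel[i] - lr * g
            p += vel[i]

        A1v = _sigmoid(W1 @ Xva + b1)
        A2v = _sigmoid(W2 @ A1v + b2)
        val_mse = float(np.mean((A2v - Tva) ** 2))
        if val_mse < best[0] - 1e-12:
            best = (val_mse, [w.copy() for w in params], epoch)
        elif epoch - best[2] >= patience:
            break
    if best[1] is not None:
        W1, b1, W2, b2 = best[1]
    return MLPModel(
        W1=W1, b1=b1, W2=W2, b2=b2, mu=mu, sd=sd, seed=seed,
        splits=tuple(splits), n_epochs=best[2], train_idx=tr,
        val_idx=va, test_idx=te,
    )


@dataclass
class RBFNModel:
    """Gaussian RBF network: k-means centres, least-squares output weights."""

    centres: np.ndarray  # (C, R)
    spread: float
    weights: np.ndarray  # (C + 1,) with trailing bias
    threshold: float = 0.5

    def hidden(self, X) -> np.ndarray:
        d2 = cdist(np.asarray(X, dtype=float), self.centres, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.spread**2))

    def scores(self, X) -> np.ndarray:
        H = self.hidden(X)
        return H @ self.weights[:-1] + self.weights[-1]

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= self.threshold).astype(int)


def train_rbfn(
    X, y, n_centres: int = 18, spread: float = 0.1, seed: int = 0
) -> RBFNModel:
    """Fit the RBF network: seeded k-means centres, then linear least squares."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    if spread <= 0:
        raise ValueError("spread must be positive")
    if n_centres > len(X):
        raise ValueError("more centres than training points")
    n_unique = len(np.unique(X, axis=0))
    if n_unique < n_centres:
        warnings.warn(
            f"only {n_unique} distinct points; reducing centres", stacklevel=2
        )
        n_centres = n_unique
    km = KMeans(n_clusters=n_centres, n_init=10, random_state=seed).fit(X)
    centres = km.cluster_centers_
    d2 = cdist(X, centres, "sqeuclidean")
    H = np.exp(-d2 / (2.0 * spread**2))
    Hb = np.hstack([H, np.ones((len(X), 1))])
    w, *_ = np.linalg.lstsq(Hb, y, rcond=None)
    return RBFNModel(centres=centres, spread=float(spread), weights=w)


@dataclass
class PerceptronModel:
    """Hard-limit single-layer perceptron."""

    w: np.ndarray
    b: float
    converged: bool
    n_epochs: int

    def predict(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) @ self.w + self.b >= 0).astype(int)


def train_perceptron(
    X, y, seed: int = 0, lr: float = 1.0, max_epochs: int = 200
) -> PerceptronModel:
    """Perceptron learning rule with an epoch cap; best-so-far weights kept.

    Correctly classified samples leave the weights unchanged; on separable
    data the rule converges and training stops early.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    w = np.zeros(X.shape[1])
    b = 0.0
    best_err = np.inf
    best = (w.copy(), b)
    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(Xs))
        updates = 0
        for i in order:
            pred = 1 if Xs[i] @ w + b >= 0 else 0
            err = y[i] - pred
            if err:
                w += lr * err * Xs[i]
                b += lr * err
                updates += 1
        n_err = int(np.sum((Xs @ w + b >= 0).astype(int) != y))
        if n_err < best_err:
            best_err, best = n_err, (w.copy(), b)
        if updates == 0:
            converged = True
            break
    w, b = best
    # fold standardisation into the raw-feature weights
    w_raw = w / sd
    b_raw = b - float(np.sum(w * mu / sd))
    return PerceptronModel(w=w_raw, b=b_raw, converged=converged, n_epochs=epoch)


# -- uniform fit/predict wrappers and cross-validation -------------------


class ThresholdClassifier:
    """Single-feature optimal-threshold rule (fits via the ROC sweep)."""

    def __init__(self, feature: int = 0, direction: str = LOWER):
        self.feature = feature
        self.direction = direction
        self.threshold_: float | None = None

    def fit(self, X, y):
        sweep = roc_sweep(
            np.asarray(X, dtype=float)[:, self.feature], y, self.direction
        )
        self.threshold_ = sweep.optimal_threshold
        return self

    def predict(self, X):
        v = np.asarray(X, dtype=float)[:, self.feature]
        if self.direction == LOWER:
            return (v < self.threshold_).astype(int)
        return (v > self.threshold_).astype(int)


class SigmoidMLP:
    """fit/predict wrapper around :func:`train_mlp`."""

    def __init__(self, **kwargs):
        self.kwargs = kwargs
        self.model_: MLPModel | None = None

    def fit(self, X, y):
        self.model_ = train_mlp(X, y, **self.kwargs)
        return self

    def predict(self, X):
        return self.model_.predict(X)


class RBFNetwork:
    def __init__(self, **kwargs):
        self.kwargs = kwargs
        self.model_: RBFNModel | None = None

    def fit(self, X, y):
        kw = dict(self.kwargs)
        kw["n_centres"] = min(kw.get("n_centres", 18), len(np.asarray(X)))
        self.model_ = train_rbfn(X, y, **kw)
        return self

    def predict(self, X):
        return self.model_.predict(X)


class HardlimPerceptron:
    def __init__(self, **kwargs):
        self.kwargs = kwargs
        self.model_: PerceptronModel | None = None

    def fit(self, X, y):
        self.model_ = train_perceptron(X, y, **self.kwargs)
        return self

    def predict(self, X):
        return self.model_.predict(X)


@dataclass(frozen=True)
class CVResult:
    n_misclassified: int
    n: int

    @property
    def error_fraction(self) -> float:
        return self.n_misclassified / self.n


def cross_validate(factory, X, y, k: int, seed: int = 0) -> CVResult:
    """Stratified K-fold cross-validation; ``k == n`` is leave-one-out.

    ``factory()`` must return a fresh object with ``fit(X, y)`` and
    ``predict(X)``.  Returns the misclassified count and fraction over all
    held-out subjects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects {n}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k == n:
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = 0
    for train, test in splitter.split(X, y):
        model = factory()
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]))
        errors += int(np.sum(pred != y[test]))
    return CVResult(n_misclassified=errors, n=n)
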