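"""Pattern-recognition arm: feature assembly, class-imbalance handling, a
five-layer perceptron (with one-layer and logistic-regression comparators),
and the iterated random-holdout evaluation protocol.

The discriminative task is control vs asthma from tabular FOT measurements.
The asthma class outnumbers controls roughly 5:1, so training combines
minority oversampling (exact duplication or SMOTE interpolation, or majority
undersampling) with inverse-frequency class weights in the loss.

The five-layer network is fully connected with hidden widths 128-64-32-16,
batch normalisation after every hidden linear map, LeakyReLU (slope 0.2)
activations and a single sigmoid output; it is trained by Adam on weighted
binary cross-entropy, batch size 32, with the last 5% of the (shuffled)
training rows held out for validation history.  The model, batch norm and
backpropagation are implemented directly on numpy arrays, which keeps the
whole pipeline dependency-light and bit-reproducible from one seed.

Evaluation follows a repeated random-holdout protocol: per repetition a
fixed number of subjects per class is removed as an untouched test set;
scaler, resampler and model are fitted on the remainder only; class-wise
accuracy (recall per class) is scored at a probability cutoff, and the
repetitions are aggregated as mean +/- SD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .fot_data import Cohort, ITEM_COLUMNS, PHASE_COLUMNS, _COLUMN_TO_ITEM

__all__ = [
    "FeatureSpec",
    "MlpSpec",
    "TrainConfig",
    "EvalProtocol",
    "EvalReport",
    "assemble_features",
    "Scaler",
    "oversample_duplicate",
    "smote",
    "undersample",
    "class_weights",
    "build_model",
    "train",
    "evaluate_binary",
    "auc",
    "iterated_holdout",
    "NumpyMLP",
    "LogisticRegressionIRLS",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.99


# ----------------------------------------------------------------------
# feature assembly
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Which columns feed the classifier.

    ``all24`` uses every reported item; ``phase10`` uses only the 10
    independent inhale/exhale measurements (the derived items are linear in
    them, so the reduced set carries the same information without the
    multicollinearity).  Optional age (years) and sex (male=0, female=1)
    columns are appended after the measurements, in that order.
    """

    feature_set: str = "phase10"  # "all24" | "phase10"
    include_age: bool = False
    include_sex: bool = True

    def columns(self) -> list[str]:
        if self.feature_set == "all24":
            cols = list(ITEM_COLUMNS)
        elif self.feature_set == "phase10":
            cols = list(PHASE_COLUMNS)
        else:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.include_age:
            cols.append("age")
        if self.include_sex:
            cols.append("sex")
        return cols


def assemble_features(cohort: Cohort, spec: FeatureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and binary labels (asthma = 1), rows in cohort order."""
    meas_cols = spec.columns()
    base = [c for c in meas_cols if c not in ("age", "sex")]
    if spec.include_age:
        missing = [r.subject_id for r in cohort if r.age is None]
        if missing:
            raise ValueError(f"include_age set but age missing for subjects {missing}")
    sexes = {r.sex for r in cohort}
    if len(sexes) > 1 and not spec.include_sex:
        warnings.warn(
            "mixed-sex cohort without a sex feature; consider include_sex=True",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for rec in cohort:
        row = [rec.values[_COLUMN_TO_ITEM[c]] for c in base]
        if spec.include_age:
            row.append(float(rec.age))
        if spec.include_sex:
            row.append(0.0 if rec.sex == "male" else 1.0)
        rows.append(row)
    X = np.array(rows, dtype=float)
    y = np.array([1 if rec.group == "asthma" else 0 for rec in cohort], dtype=int)
    return X, y


class Scaler:
    """Column-wise standardisation fitted on training rows only.

    Constant columns pass through unscaled (guarded division).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        const = sd == 0
        self.mean_ = np.where(const, 0.0, self.mean_)
        self.scale_ = np.where(const, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


# ----------------------------------------------------------------------
# imbalance handling
# ----------------------------------------------------------------------

def _classes(y: np.ndarray) -> tuple[int, int]:
    u = np.unique(y)
    if u.size != 2:
        raise ValueError(f"expected exactly two classes, got {u.tolist()}")
    n0, n1 = (y == u[0]).sum(), (y == u[1]).sum()
    minority, majority = (u[0], u[1]) if n0 < n1 else (u[1], u[0])
    return int(minority), int(majority)


def oversample_duplicate(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by duplicating minority rows (sampling with replacement).

    Every appended row is an exact copy of an existing minority row; the
    original rows are kept untouched and in place.
    """
    X, y = np.asarray(X, float), np.asarray(y)
    minority, _ = _classes(y)
    idx_min = np.flatnonzero(y == minority)
    deficit = (y != minority).sum() - idx_min.size
    if deficit <= 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    extra = rng.choice(idx_min, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    return_parents: bool = False,
):
    """Balance classes with synthetic minority rows by SMOTE interpolation.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0,1)`` and
    ``x_nn`` one of the ``k`` nearest minority neighbours of ``x_i``
    (Euclidean), so it lies on the segment between its two parents.  When
    the minority class has <= k members, k is reduced with a warning.
    With ``return_parents`` the index pairs of both parents of each
    synthetic row are returned for auditing.
    """
    X, y = np.asarray(X, float), np.asarray(y)
    minority, _ = _classes(y)
    idx_min = np.flatnonzero(y == minority)
    deficit = int((y != minority).sum() - idx_min.size)
    if deficit <= 0:
        out = (X.copy(), y.copy())
        return (*out, np.empty((0, 2), dtype=int)) if return_parents else out
    n_min = idx_min.size
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    if n_min - 1 < k:
        warnings.warn(
            f"minority count {n_min} <= k={k}; reducing k to {n_min - 1}",
            UserWarning,
            stacklevel=2,
        )
        k = n_min - 1
    rng = np.random.default_rng(seed)
    Xm = X[idx_min]
    # pairwise distances among minority rows; self excluded from neighbours
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]  # local indices

    base_local = rng.integers(0, n_min, size=deficit)
    nn_pick = nn[base_local, rng.integers(0, k, size=deficit)]
    u = rng.uniform(0.0, 1.0, size=deficit)
    synth = Xm[base_local] + u[:, None] * (Xm[nn_pick] - Xm[base_local])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    if return_parents:
        parents = np.column_stack([idx_min[base_local], idx_min[nn_pick]])
        return X_out, y_out, parents
    return X_out, y_out


def undersample(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by discarding random majority rows (no replacement)."""
    X, y = np.asarray(X, float), np.asarray(y)
    minority, majority = _classes(y)
    idx_maj = np.flatnonzero(y == majority)
    n_keep = int((y == minority).sum())
    if idx_maj.size <= n_keep:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(idx_maj, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
    return X[keep], y[keep]


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Balanced inverse-frequency weights: w_c = n_total / (2 * n_c)."""
    y = np.asarray(y)
    u = np.unique(y)
    if u.size != 2:
        raise ValueError("expected exactly two classes")
    n = y.size
    return {int(c): n / (2.0 * (y == c).sum()) for c in u}


# ----------------------------------------------------------------------
# models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MlpSpec:
    """Architecture of the five-layer perceptron."""

    hidden_units: tuple[int, ...] = (128, 64, 32, 16)
    leaky_slope: float = 0.2
    batch_norm: bool = True


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class NumpyMLP:
    """Fully connected binary classifier on numpy arrays.

    Hidden layers: linear -> batch norm -> LeakyReLU; output: linear ->
    sigmoid.  An empty ``hidden_units`` tuple gives the one-layer network
    (single weighted layer plus sigmoid).
    """

    def __init__(self, input_dim: int, spec: MlpSpec, seed: int = 0) -> None:
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.spec = spec
        self.input_dim = input_dim
        rng = np.random.default_rng(seed)
        dims = [input_dim, *spec.hidden_units, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He-style init, suited to the LeakyReLU hidden units
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))
        nh = len(spec.hidden_units)
        self.use_bn = spec.batch_norm and nh > 0
        self.gamma = [np.ones(h) for h in spec.hidden_units]
        self.beta = [np.zeros(h) for h in spec.hidden_units]
        # bias-corrected exponential moving averages of batch statistics
        self.run_mean = [np.zeros(h) for h in spec.hidden_units]
        self.run_var = [np.zeros(h) for h in spec.hidden_units]
        self._bn_steps = 0

    @property
    def n_parameters(self) -> int:
        n = sum(W.size + b.size for W, b in zip(self.W, self.b))
        if self.use_bn:
            n += sum(g.size + bt.size for g, bt in zip(self.gamma, self.beta))
        return n

    # ---- forward -----------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        """Returns (probs, cache) — cache retains intermediates for backprop."""
        cache = []
        h = X
        a = self.spec.leaky_slope
        for i in range(len(self.spec.hidden_units)):
            lin = h @ self.W[i] + self.b[i]
            if self.use_bn:
                if training:
                    mu = lin.mean(axis=0)
                    var = lin.var(axis=0)
                    self.run_mean[i] = _BN_MOMENTUM * self.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                    self.run_var[i] = _BN_MOMENTUM * self.run_var[i] + (1 - _BN_MOMENTUM) * var
                    if i == 0:
                        self._bn_steps += 1
                elif self._bn_steps == 0:
                    mu, var = np.zeros_like(self.run_mean[i]), np.ones_like(self.run_var[i])
                else:
                    corr = 1.0 - _BN_MOMENTUM**self._bn_steps
                    mu, var = self.run_mean[i] / corr, self.run_var[i] / corr
                inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (lin - mu) * inv_sd
                z = self.gamma[i] * xhat + self.beta[i]
            else:
                xhat, inv_sd, z = None, None, lin
            act = np.where(z > 0, z, a * z)
            cache.append((h, lin, xhat, inv_sd, z, act))
            h = act
        logits = (h @ self.W[-1] + self.b[-1]).ravel()
        probs = _sigmoid(logits)
        return probs, (cache, h, logits)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, float), training=False)
        return probs

    # ---- backward ----------------------------------------------------

    def _backward(self, X, y, w, cache_tuple, probs):
        """Gradients of mean weighted BCE w.r.t. all trainable arrays."""
        cache, h_last, _ = cache_tuple
        n = X.shape[0]
        a = self.spec.leaky_slope
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gG = [np.zeros_like(g) for g in self.gamma]
        gB = [np.zeros_like(b) for b in self.beta]

        dlogits = (w * (probs - y) / n)[:, None]  # (n,1)
        gW[-1] = h_last.T @ dlogits
        gb[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self.W[-1].T

        for i in reversed(range(len(self.spec.hidden_units))):
            h_in, lin, xhat, inv_sd, z, _ = cache[i]
            dz = dh * np.where(z > 0, 1.0, a)
            if self.use_bn:
                gG[i] = (dz * xhat).sum(axis=0)
                gB[i] = dz.sum(axis=0)
                dxhat = dz * self.gamma[i]
                # batch-statistics backprop
                m = dz.shape[0]
                dvar_term = (dxhat * xhat).sum(axis=0)
                dlin = (inv_sd / m) * (
                    m * dxhat - dxhat.sum(axis=0) - xhat * dvar_term
                )
            else:
                dlin = dz
            gW[i] = h_in.T @ dlin
            gb[i] = dlin.sum(axis=0)
            dh = dlin @ self.W[i].T
        return gW, gb, gG, gB


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (arr, g) in enumerate(zip(arrays, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LogisticRegressionIRLS:
    """Logistic regression fitted by iteratively reweighted least squares.

    A tiny ridge penalty (default 1e-8) keeps the Newton step well posed on
    perfectly separable data.  Supports per-sample weights so class
    balancing behaves identically to the neural models.
    """

    def __init__(self, input_dim: int, ridge: float = 1e-8) -> None:
        self.coef_ = np.zeros(input_dim)
        self.intercept_ = 0.0
        self.ridge = ridge

    def fit(self, X, y, sample_weight=None, max_iter: int = 100, tol: float = 1e-10):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, d = X.shape
        sw = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        Xb = np.column_stack([X, np.ones(n)])
        beta = np.zeros(d + 1)
        for _ in range(max_iter):
            p = _sigmoid(Xb @ beta)
            Wdiag = sw * p * (1 - p)
            grad = Xb.T @ (sw * (y - p)) - self.ridge * beta
            H = (Xb * Wdiag[:, None]).T @ Xb + self.ridge * np.eye(d + 1)
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
        self.coef_ = beta[:-1]
        self.intercept_ = float(beta[-1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(np.asarray(X, float) @ self.coef_ + self.intercept_)


def build_model(kind: str, input_dim: int, spec: MlpSpec | None = None, seed: int = 0):
    """Construct one of the three comparator models.

    ``mlp5``: the five-layer network; ``mono``: a single weighted layer plus
    sigmoid; ``logreg``: logistic regression (IRLS, not gradient-trained).
    """
    spec = spec or MlpSpec()
    if kind == "mlp5":
        return NumpyMLP(input_dim, spec, seed=seed)
    if kind == "mono":
        return NumpyMLP(input_dim, MlpSpec(hidden_units=(), batch_norm=False), seed=seed)
    if kind == "logreg":
        return LogisticRegressionIRLS(input_dim)
    raise ValueError(f"unknown model kind {kind!r}")


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Protocol constants for gradient training."""

    epochs: int = 2500
    batch_size: int = 32
    validation_split: float = 0.05
    sampling: str = "duplicate"  # "duplicate" | "smote" | "undersample" | "none"
    class_weighting: bool = True
    optimizer_name: str = "adam"
    learning_rate: float = 1e-3
    smote_k: int = 5
    seed: int = 0
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_split < 1.0):
            raise ValueError("validation_split must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.sampling not in {"duplicate", "smote", "undersample", "none"}:
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


def train(model: NumpyMLP, X: np.ndarray, y: np.ndarray, config: TrainConfig) -> dict:
    """Mini-batch Adam training on weighted binary cross-entropy.

    The rows are shuffled once; the trailing ``validation_split`` fraction
    is held out for the per-epoch validation history (batch norm switches to
    running statistics there).  Returns the history dict, including the
    validation row indices so callers can run cutoff searches on validation
    predictions without touching any test data.
    """
    if not isinstance(model, NumpyMLP):
        raise TypeError("gradient training applies to mlp5/mono models only")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(config.seed)

    perm = rng.permutation(X.shape[0])
    n_val = max(1, int(round(config.validation_split * X.shape[0]))) if X.shape[0] > 1 else 0
    train_idx = perm[: X.shape[0] - n_val]
    val_idx = perm[X.shape[0] - n_val :]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    if config.class_weighting:
        cw = class_weights(ytr.astype(int))
        wtr = np.array([cw[int(t)] for t in ytr])
    else:
        wtr = np.ones(ytr.size)

    params = model.W + model.b
    if model.use_bn:
        params += model.gamma + model.beta
    opt = _Adam(params, config.learning_rate)

    hist = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
            "val_idx": val_idx.astype(int)}

    def _wbce(p, t, w):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.mean(w * -(t * np.log(p) + (1 - t) * np.log(1 - p))))

    for _ in range(config.epochs):
        order = rng.permutation(Xtr.shape[0])
        ep_loss, ep_correct, ep_n = 0.0, 0.0, 0
        for start in range(0, Xtr.shape[0], config.batch_size):
            bidx = order[start : start + config.batch_size]
            Xb, yb, wb = Xtr[bidx], ytr[bidx], wtr[bidx]
            probs, cache = model._forward(Xb, training=True)
            if not np.all(np.isfinite(probs)):
                raise RuntimeError("NaN/inf in forward pass: training diverged")
            gW, gb, gG, gB = model._backward(Xb, yb, wb, cache, probs)
            grads = gW + gb + (gG + gB if model.use_bn else [])
            opt.step(params, grads)
            bl = _wbce(probs, yb, wb)
            if not np.isfinite(bl):
                raise RuntimeError("NaN loss: training diverged")
            ep_loss += bl * len(bidx)
            ep_correct += ((probs >= 0.5) == yb).sum()
            ep_n += len(bidx)
        hist["loss"].append(ep_loss / ep_n)
        hist["accuracy"].append(ep_correct / ep_n)
        if Xval.shape[0] > 0:
            pv = model.predict_proba(Xval)
            hist["val_loss"].append(_wbce(pv, yval, np.ones(yval.size)))
            hist["val_accuracy"].append(float(((pv >= 0.5) == yval).mean()))
        else:
            hist["val_loss"].append(float("nan"))
            hist["val_accuracy"].append(float("nan"))
    return hist


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney concordance AUC, ties counted one half."""
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    pos, neg = p[y == 1], p[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def youden_cutoff(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Cutoff maximising sensitivity + specificity - 1 over unique probs.

    Classification convention is ``prob >= cutoff -> asthma``; smallest
    maximiser wins on ties.
    """
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    best_c, best_j = 0.5, -np.inf
    for c in np.unique(p):
        pred = p >= c
        sens = pred[y == 1].mean() if (y == 1).any() else 0.0
        spec = (~pred[y == 0]).mean() if (y == 0).any() else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_c = j, float(c)
    return best_c


def evaluate_binary(probs: Sequence[float], labels: Sequence[int], cutoff: float = 0.5) -> dict:
    """Threshold metrics at ``prob >= cutoff -> asthma`` plus concordance AUC.

    ``accuracy_control`` / ``accuracy_asthma`` are recall per class (the
    class-wise diagnostic accuracies); F1 treats asthma as the positive
    class.
    """
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    pred = (p >= cutoff).astype(int)
    sens = float(pred[y == 1].mean()) if (y == 1).any() else float("nan")
    spec = float((1 - pred[y == 0]).mean()) if (y == 0).any() else float("nan")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    out = {
        "cutoff": float(cutoff),
        "accuracy_control": spec,
        "accuracy_asthma": sens,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": float((pred == y).mean()),
        "f1": float(f1),
    }
    if (y == 1).any() and (y == 0).any():
        out["auc"] = auc(p, y)
    return out


# ----------------------------------------------------------------------
# iterated holdout protocol
# ----------------------------------------------------------------------

@dataclass
class EvalProtocol:
    """Repetition structure of the holdout evaluation."""

    repeats: int = 5
    test_per_group: int = 10
    metric_mode: str = "accuracy_at_cutoff"  # or "youden_metrics"

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.test_per_group < 1:
            raise ValueError("repeats and test_per_group must be >= 1")
        if self.metric_mode not in {"accuracy_at_cutoff", "youden_metrics"}:
            raise ValueError(f"unknown metric_mode {self.metric_mode!r}")


@dataclass
class EvalReport:
    """Per-repetition metrics plus mean +/- SD aggregates and full protocol."""

    per_repeat: list[dict]
    aggregate: dict
    protocol: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"per_repeat": self.per_repeat, "aggregate": self.aggregate,
                 "protocol": self.protocol},
                fh,
                indent=2,
                sort_keys=True,
            )


def _aggregate(per_repeat: list[dict]) -> dict:
    keys = [
        k
        for k in per_repeat[0]
        if k != "repeat" and isinstance(per_repeat[0][k], (int, float))
    ]
    agg = {}
    for k in keys:
        vals = np.array([r[k] for r in per_repeat], float)
        agg[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return agg


def iterated_holdout(
    cohort: Cohort,
    feature_spec: FeatureSpec,
    config: TrainConfig,
    protocol: EvalProtocol,
    model_kind: str = "mlp5",
    mlp_spec: MlpSpec | None = None,
) -> EvalReport:
    """Repeated random-holdout evaluation of one model configuration.

    Per repetition: remove ``test_per_group`` subjects per class (uniform,
    without replacement, fresh seed stream); fit scaler, resampler, class
    weights and model on the remainder only; score the untouched test set.
    In ``youden_metrics`` mode the cutoff is chosen on validation
    predictions, never on test data.
    """
    X_all, y_all = assemble_features(cohort, feature_spec)
    n1, n0 = int((y_all == 1).sum()), int((y_all == 0).sum())
    if min(n0, n1) <= protocol.test_per_group:
        raise ValueError(
            f"need more than {protocol.test_per_group} subjects per class; "
            f"have control={n0}, asthma={n1}"
        )

    streams = np.random.SeedSequence(config.seed).spawn(protocol.repeats)
    per_repeat: list[dict] = []
    for rep, stream in enumerate(streams):
        split_seed, resample_seed, model_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in stream.spawn(3)
        )
        rng = np.random.default_rng(split_seed)
        test_idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(y_all == c), size=protocol.test_per_group, replace=False)
                for c in (0, 1)
            ]
        )
        mask = np.zeros(y_all.size, dtype=bool)
        mask[test_idx] = True
        Xtr, ytr = X_all[~mask], y_all[~mask]
        Xte, yte = X_all[mask], y_all[mask]

        scaler = Scaler().fit(Xtr)
        Xtr_s, Xte_s = scaler.transform(Xtr), scaler.transform(Xte)

        if config.sampling == "duplicate":
            Xtr_s, ytr = oversample_duplicate(Xtr_s, ytr, seed=resample_seed)
        elif config.sampling == "smote":
            Xtr_s, ytr = smote(Xtr_s, ytr, k=config.smote_k, seed=resample_seed)
        elif config.sampling == "undersample":
            Xtr_s, ytr = undersample(Xtr_s, ytr, seed=resample_seed)

        rep_config = TrainConfig(**{**asdict(config), "seed": model_seed})
        if model_kind == "logreg":
            # same validation holdout as the gradient models, for cutoff search
            rng_m = np.random.default_rng(model_seed)
            perm = rng_m.permutation(Xtr_s.shape[0])
            n_val = max(1, int(round(config.validation_split * Xtr_s.shape[0])))
            fit_idx, val_idx = perm[:-n_val], perm[-n_val:]
            model = build_model("logreg", Xtr_s.shape[1])
            sw = None
            if config.class_weighting:
                cw = class_weights(ytr[fit_idx])
                sw = np.array([cw[int(t)] for t in ytr[fit_idx]])
            model.fit(Xtr_s[fit_idx], ytr[fit_idx], sample_weight=sw)
            val_probs, val_labels = model.predict_proba(Xtr_s[val_idx]), ytr[val_idx]
        else:
            model = build_model(model_kind, Xtr_s.shape[1], mlp_spec, seed=model_seed)
            hist = train(model, Xtr_s, ytr, rep_config)
            val_idx = hist["val_idx"]
            val_probs, val_labels = model.predict_proba(Xtr_s[val_idx]), ytr[val_idx]

        cutoff = config.cutoff
        if protocol.metric_mode == "youden_metrics":
            if np.unique(val_labels).size == 2:
                cutoff = youden_cutoff(val_probs, val_labels)
            else:
                warnings.warn(
                    "validation split contains one class; keeping default cutoff",
                    UserWarning,
                    stacklevel=2,
                )
        te_probs = model.predict_proba(Xte_s)
        metrics = evaluate_binary(te_probs, yte, cutoff=cutoff)
        metrics["repeat"] = rep
        per_repeat.append(metrics)

    report = EvalReport(
        per_repeat=per_repeat,
        aggregate=_aggregate(per_repeat),
        protocol={
            "model_kind": model_kind,
            "feature_spec": asdict(feature_spec),
            "train_config": asdict(config),
            "eval_protocol": asdict(protocol),
            "mlp_spec": asdict(mlp_spec or MlpSpec()),
        },
    )
    return report
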