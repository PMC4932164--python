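"""Fixed-configuration radial-kernel SVM training and LOOCV scoring.

The classifier configuration is frozen to C-classification with an RBF
kernel K(u,v) = exp(-gamma * ||u-v||^2), cost 1, gamma = 1/n_features, and
feature standardization by training-set mean and standard deviation
(ddof=1, the R convention) — the e1071-style defaults. libsvm (through
scikit-learn) is the solver; the greedy feature search evaluates on the
order of 10^5–10^6 tiny LOOCV fits, so training goes through
scikit-learn's low-level libsvm bindings when available, with the public
``SVC`` estimator as a fallback. A unit test pins exact agreement between
the two routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from sklearn.svm import SVC

try:  # fast path: same libsvm solver without estimator overhead
    from sklearn.svm import _libsvm as _fast_libsvm

    _fast_libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - exercised only on unusual builds
    _fast_libsvm = None

SVM_TOL = 1e-3  # libsvm default stopping tolerance


@dataclass(frozen=True)
class SvmSpec:
    """Frozen SVM configuration. ``gamma_rule`` is ``"one_over_n_features"``
    or a fixed positive float; positive class is AD."""

    kernel: str = "radial"
    cost: float = 1.0
    gamma_rule: Union[str, float] = "one_over_n_features"
    standardize: bool = True
    positive_label: str = "AD"

    def __post_init__(self) -> None:
        if self.kernel != "radial":
            raise ValueError("only the radial kernel is supported")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if isinstance(self.gamma_rule, str):
            if self.gamma_rule != "one_over_n_features":
                raise ValueError(f"unknown gamma rule {self.gamma_rule!r}")
        elif self.gamma_rule <= 0:
            raise ValueError("fixed gamma must be positive")

    def resolve_gamma(self, n_features: int) -> float:
        if isinstance(self.gamma_rule, str):
            return 1.0 / n_features
        return float(self.gamma_rule)


def _standardize_params(X: np.ndarray, standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    if not standardize:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0.0] = 1.0  # zero-variance feature: center only
    return mean, scale


class FittedSvm:
    """A trained C-SVC with its standardization transform baked in.

    ``predict`` returns 0/1 labels; ``decision_score`` returns a real value
    per sample, higher = more AD-like (sign convention of scikit-learn's
    ``decision_function`` for classes ordered [0, 1]).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: SvmSpec):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be a 2-D samples x features array")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training fold has one class")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must be binary 0/1")
        self.spec = spec
        self.gamma = spec.resolve_gamma(X.shape[1])
        self.mean, self.scale = _standardize_params(X, spec.standardize)
        Xs = np.ascontiguousarray((X - self.mean) / self.scale)
        yf = np.ascontiguousarray(y, dtype=np.float64)
        if _fast_libsvm is not None:
            out = _fast_libsvm.fit(
                Xs, yf, svm_type=0, kernel="rbf",
                gamma=self.gamma, C=spec.cost, tol=SVM_TOL,
            )
            self._model = out[:7]
            # calibrate the decision-value orientation against the model's own
            # training predictions so that positive score always means class 1
            dec = _fast_libsvm.decision_function(
                Xs, *self._model, svm_type=0, kernel="rbf", gamma=self.gamma
            ).ravel()
            pred = _fast_libsvm.predict(
                Xs, *self._model, svm_type=0, kernel="rbf", gamma=self.gamma)
            anchor = int(np.argmax(np.abs(dec)))
            self._sign = 1.0 if (dec[anchor] > 0) == (pred[anchor] == 1) else -1.0
            self._svc = None
        else:  # pragma: no cover
            self._svc = SVC(C=spec.cost, kernel="rbf", gamma=self.gamma, tol=SVM_TOL)
            self._svc.fit(Xs, y)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        return np.ascontiguousarray((X - self.mean) / self.scale)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._transform(X)
        if self._svc is not None:  # pragma: no cover
            return self._svc.predict(Xs).astype(int)
        pred = _fast_libsvm.predict(Xs, *self._model, svm_type=0, kernel="rbf", gamma=self.gamma)
        return pred.astype(int)

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        Xs = self._transform(X)
        if self._svc is not None:  # pragma: no cover
            return self._svc.decision_function(Xs)
        dec = _fast_libsvm.decision_function(
            Xs, *self._model, svm_type=0, kernel="rbf", gamma=self.gamma
        )
        return self._sign * dec.ravel()


def train_svm(X: np.ndarray, y: np.ndarray, spec: SvmSpec | None = None) -> FittedSvm:
    """Train the fixed-configuration radial SVM on a binary problem."""
    return FittedSvm(X, y, spec if spec is not None else SvmSpec())


def loocv_accuracy(X: np.ndarray, y: np.ndarray, spec: SvmSpec | None = None) -> float:
    """Leave-one-out cross-validated accuracy of the fixed SVM.

    Standardization statistics and gamma are re-resolved inside every fold
    from that fold's n-1 training samples, so no information leaks from
    the held-out sample. Deterministic given inputs and spec.
    """
    spec = spec if spec is not None else SvmSpec()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
    if _fast_libsvm is None:  # pragma: no cover
        correct = 0
        idx = np.arange(n)
        for i in range(n):
            mask = idx != i
            model = FittedSvm(X[mask], y[mask], spec)
            correct += int(model.predict(X[i])[0] == y[i])
        return correct / n

    # fast path: same per-fold arithmetic as train_svm (so results are
    # bitwise identical) but without estimator/validation overhead
    gamma = spec.resolve_gamma(X.shape[1])
    yf = y.astype(np.float64)
    correct = 0
    for i in range(n):
        Xtr = np.delete(X, i, axis=0)
        mean, scale = _standardize_params(Xtr, spec.standardize)
        Xs = np.ascontiguousarray((Xtr - mean) / scale)
        model = _fast_libsvm.fit(Xs, np.ascontiguousarray(np.delete(yf, i)),
                                 svm_type=0, kernel="rbf", gamma=gamma,
                                 C=spec.cost, tol=SVM_TOL)
        xi = np.ascontiguousarray((X[i:i + 1] - mean) / scale)
        pred = _fast_libsvm.predict(xi, *model[:7],
                                    svm_type=0, kernel="rbf", gamma=gamma)
        correct += int(pred[0] == y[i])
    return correct / n
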