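"""Kernel support-vector classification solved by a from-scratch SMO.

The soft-margin dual problem for labels g in {-1, +1} and kernel K:

    maximize   U(k) = sum_i k_i - 1/2 sum_{i,s} k_i k_s g_i g_s K(a_i, a_s)
    subject to sum_i k_i g_i = 0,   0 <= k_i <= C

is solved by sequential minimal optimization with maximal-violating-pair
working-set selection: at each step the most KKT-violating pair of
multipliers is updated analytically along the equality constraint and
clipped to the box, until the violation gap falls below tolerance.  The
decision function is

    f(a) = sgn( sum_i k_i g_i K(a_i, a) + b )

with the offset ``b`` averaged over unbounded support vectors
(0 < k_i < C).  Linear and Gaussian RBF kernels are provided; for the
linear kernel the explicit primal weight vector is recovered as
``w = sum_i k_i g_i a_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "KernelSpec",
    "KernelSVC",
    "kernel_matrix",
    "svm_train",
    "svm_predict",
    "dual_objective",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: 'linear' (dot product) or 'rbf' exp(-gamma ||a-b||^2)."""

    kind: str = "rbf"
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf" and self.gamma <= 0:
            raise ValueError("rbf gamma must be > 0")


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if spec.kind == "linear":
        return X @ Y.T
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    """U(k) = sum k - 1/2 k^T (yy^T * K) k (the maximized dual)."""
    q = (y[:, None] * y[None, :]) * K
    return float(alpha.sum() - 0.5 * alpha @ q @ alpha)


def _smo_solve(K, y, C, tol, max_iter):
    """Maximal-violating-pair SMO on the dual.

    Internally minimizes 1/2 a^T Q a - e^T a with Q = yy^T * K.  Returns
    (alpha, b, n_iter).  Raises on non-convergence.
    """
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad of the minimized objective: Q a - e

    for it in range(max_iter):
        # I_up: can increase y*alpha;  I_low: can decrease y*alpha
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        yg = -y * grad
        m_up = np.where(up, yg, -np.inf)
        m_low = np.where(low, yg, np.inf)
        i = int(np.argmax(m_up))
        j = int(np.argmin(m_low))
        gap = m_up[i] - m_low[j]
        if gap < tol:
            # at optimum -y*grad equals the offset b on free SVs
            b = (m_up[i] + m_low[j]) / 2.0
            return alpha, float(b), it
        # analytic update of the (i, j) pair along sum y*alpha = const
        quad = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        quad = max(quad, 1e-12)
        delta = gap / quad  # step in y_i*alpha_i (= -step in y_j*alpha_j)
        # box limits for the step
        if y[i] > 0:
            delta = min(delta, C - alpha[i])
        else:
            delta = min(delta, alpha[i])
        if y[j] > 0:
            delta = min(delta, alpha[j])
        else:
            delta = min(delta, C - alpha[j])
        alpha[i] += y[i] * delta
        alpha[j] -= y[j] * delta
        grad += delta * (y[i] * Q[:, i] - y[j] * Q[:, j])

    raise RuntimeError(
        f"SMO did not converge in {max_iter} pair updates "
        f"(last KKT gap {gap:.3e}, tolerance {tol:.1e})"
    )


class KernelSVC(BaseEstimator, ClassifierMixin):
    """Binary soft-margin SVM with an internal SMO dual solver.

    Parameters
    ----------
    C : float
        Box penalty; multipliers live in [0, C].
    kernel : {"rbf", "linear"}
    gamma : float
        RBF width parameter (ignored by the linear kernel).
    tol : float
        SMO stopping tolerance on the maximal KKT violation gap.
    max_iter : int
        Maximum number of pair updates before the solver errors out.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (mapped to -1/+1 in order)
    alpha_ : ndarray, shape (n_samples,) — dual multipliers in [0, C]
    support_ : indices with alpha above ``support_tol``
    support_vectors_ : the corresponding training rows
    dual_coef_ : alpha * y restricted to support vectors
    intercept_ : float offset, averaged over unbounded support vectors
    coef_ : primal weight vector (linear kernel only)
    dual_objective_ : value of the maximized dual at the solution
    """

    support_tol = 1e-8

    def __init__(self, C=1.0, kernel="rbf", gamma=1.0, tol=1e-7, max_iter=200_000):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    def _kernel_spec(self) -> KernelSpec:
        return KernelSpec(kind=self.kernel, gamma=self.gamma)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"binary classifier needs exactly 2 classes, got {len(classes)}"
            )
        self.classes_ = classes
        sign = np.where(y == classes[1], 1.0, -1.0)
        spec = self._kernel_spec()
        K = kernel_matrix(spec, X, X)
        alpha, b, n_iter = _smo_solve(
            K, sign, float(self.C), float(self.tol), int(self.max_iter)
        )
        self.X_ = X
        self.y_sign_ = sign
        self.alpha_ = alpha
        self.intercept_ = self._refine_intercept(K, alpha, sign, b)
        self.n_iter_ = n_iter
        self.dual_objective_ = dual_objective(alpha, sign, K)
        sv = np.flatnonzero(alpha > self.support_tol)
        self.support_ = sv
        self.support_vectors_ = X[sv]
        self.dual_coef_ = (alpha * sign)[sv]
        if spec.kind == "linear":
            self.coef_ = (alpha * sign) @ X
        return self

    def _refine_intercept(self, K, alpha, sign, fallback):
        """Average b over unbounded SVs; fall back to the SMO midpoint."""
        unbounded = (alpha > self.support_tol) & (alpha < self.C - self.support_tol)
        if not unbounded.any():
            return float(fallback)
        f_no_b = K[unbounded] @ (alpha * sign)
        return float(np.mean(sign[unbounded] - f_no_b))

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model has {self.X_.shape[1]}, "
                f"input has {X.shape[1]}"
            )
        K = kernel_matrix(self._kernel_spec(), X, self.support_vectors_)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        # sgn(0) -> +1 by convention
        pos = self.decision_function(X) >= 0
        return np.where(pos, self.classes_[1], self.classes_[0])

    def _check_fitted(self) -> None:
        if not hasattr(self, "alpha_"):
            raise RuntimeError("model is not trained; call fit first")

    # -- serialization (JSON-friendly) --------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        d = {
            "C": self.C,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "classes": np.asarray(self.classes_).tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }
        if hasattr(self, "coef_"):
            d["coef"] = self.coef_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSVC":
        model = cls(C=d["C"], kernel=d["kernel"], gamma=d["gamma"])
        model.classes_ = np.asarray(d["classes"])
        model.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        sv = model.support_vectors_
        model.X_ = sv
        model.alpha_ = np.abs(model.dual_coef_)
        model.y_sign_ = np.sign(model.dual_coef_)
        model.support_ = np.arange(len(sv))
        if "coef" in d:
            model.coef_ = np.asarray(d["coef"], dtype=float)
        return model


def svm_train(X, y, C: float, kernel: KernelSpec | None = None, **kwargs) -> KernelSVC:
    """Train a :class:`KernelSVC` on features X and labels y in {-1, +1}."""
    kernel = kernel or KernelSpec()
    return KernelSVC(C=C, kernel=kernel.kind, gamma=kernel.gamma, **kwargs).fit(X, y)


def svm_predict(model: KernelSVC, X) -> np.ndarray:
    """Predict labels for points X with a trained model."""
    return model.predict(X)
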