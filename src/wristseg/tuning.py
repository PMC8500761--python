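"""PSO-driven SVM hyperparameter search.

The swarm minimizes (1 - k-fold cross-validated accuracy) over the
log-scaled box log10(C) in [-2, 4], log10(gamma) in [-4, 2].  Fold
assignment is stratified and fixed by seed, so a rerun with the same
seeds returns the same (C*, gamma*).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .svm import KernelSVC
from .swarm import SwarmConfig, pso_minimize

__all__ = ["DEFAULT_LOG_C_BOUNDS", "DEFAULT_LOG_GAMMA_BOUNDS", "cv_accuracy",
           "pso_svm_tune", "PSOTunedSVC"]

DEFAULT_LOG_C_BOUNDS = (-2.0, 4.0)
DEFAULT_LOG_GAMMA_BOUNDS = (-4.0, 2.0)


def cv_accuracy(X, y, C: float, gamma: float, folds: int, seed: int,
                kernel: str = "rbf") -> float:
    """Mean stratified k-fold accuracy of a KernelSVC at (C, gamma)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        model = KernelSVC(C=C, kernel=kernel, gamma=gamma, tol=1e-4)
        model.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def pso_svm_tune(
    X,
    y,
    folds: int = 3,
    swarm: SwarmConfig | None = None,
    seed: int = 0,
    log_c_bounds: tuple[float, float] = DEFAULT_LOG_C_BOUNDS,
    log_gamma_bounds: tuple[float, float] = DEFAULT_LOG_GAMMA_BOUNDS,
) -> tuple[float, float, float]:
    """Return (C*, gamma*, cv_accuracy) found by the swarm.

    ``swarm`` may override particle count / iterations / factors; its
    bounds are replaced by the log-scaled (C, gamma) box.  Deterministic
    for fixed seeds and fold assignment.
    """
    y = np.asarray(y).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("tuning needs exactly 2 classes")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold CV"
        )
    bounds = (tuple(log_c_bounds), tuple(log_gamma_bounds))
    if swarm is None:
        swarm = SwarmConfig(
            n_particles=8, bounds=bounds, max_iters=10,
            inertia=0.9, inertia_final=0.4, seed=seed,
        )
    else:
        swarm = SwarmConfig(
            n_particles=swarm.n_particles, bounds=bounds,
            cognitive=swarm.cognitive, social=swarm.social,
            inertia=swarm.inertia, inertia_final=swarm.inertia_final,
            max_iters=swarm.max_iters,
            init_velocity_fraction=swarm.init_velocity_fraction,
            seed=swarm.seed,
        )
    fold_seed = seed + 1

    def objective(v):
        C = 10.0 ** v[0]
        gamma = 10.0 ** v[1]
        return 1.0 - cv_accuracy(X, y, C, gamma, folds, fold_seed)

    result = pso_minimize(objective, swarm)
    c_star = 10.0 ** result.x[0]
    gamma_star = 10.0 ** result.x[1]
    return c_star, gamma_star, 1.0 - result.fun


class PSOTunedSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM whose (C, gamma) are tuned by particle swarm.

    ``fit`` runs the swarm over the cross-validation objective, then
    refits a :class:`KernelSVC` on the full training set at the best
    hyperparameters.

    Attributes
    ----------
    best_C_, best_gamma_ : tuned hyperparameters
    cv_score_ : cross-validated accuracy at the optimum
    svc_ : the refitted KernelSVC
    classes_ : class labels
    """

    def __init__(
        self,
        n_particles: int = 8,
        max_iters: int = 10,
        folds: int = 3,
        cognitive: float = 1.5,
        social: float = 1.5,
        inertia: float = 0.9,
        inertia_final: float | None = 0.4,
        seed: int = 0,
        log_c_bounds: tuple[float, float] = DEFAULT_LOG_C_BOUNDS,
        log_gamma_bounds: tuple[float, float] = DEFAULT_LOG_GAMMA_BOUNDS,
    ):
        self.n_particles = n_particles
        self.max_iters = max_iters
        self.folds = folds
        self.cognitive = cognitive
        self.social = social
        self.inertia = inertia
        self.inertia_final = inertia_final
        self.seed = seed
        self.log_c_bounds = log_c_bounds
        self.log_gamma_bounds = log_gamma_bounds

    def fit(self, X, y):
        swarm = SwarmConfig(
            n_particles=self.n_particles,
            bounds=(tuple(self.log_c_bounds), tuple(self.log_gamma_bounds)),
            cognitive=self.cognitive,
            social=self.social,
            inertia=self.inertia,
            inertia_final=self.inertia_final,
            max_iters=self.max_iters,
            seed=self.seed,
        )
        c_star, gamma_star, cv_acc = pso_svm_tune(
            X, y, folds=self.folds, swarm=swarm, seed=self.seed,
            log_c_bounds=self.log_c_bounds,
            log_gamma_bounds=self.log_gamma_bounds,
        )
        self.best_C_ = c_star
        self.best_gamma_ = gamma_star
        self.cv_score_ = cv_acc
        self.svc_ = KernelSVC(C=c_star, kernel="rbf", gamma=gamma_star).fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(X)

    def predict(self, X):
        return self.svc_.predict(X)
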