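"""Kernel ridge regression with k-fold cross-validated RMSE.

The learners used with the fingerprints: KRR with a Laplacian, Gaussian or
linear kernel. Exponential kernels are parameterized by a length scale
``gamma`` (laplacian: exp(-||x-x'||_1 / gamma); gaussian:
exp(-||x-x'||_2**2 / (2 gamma**2))). Features are standardized per column
with training-fold statistics before the kernel, so length scales are
comparable across feature sets of different magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, lstsq
from sklearn.metrics.pairwise import pairwise_kernels

__all__ = ["KRRModel", "CVReport", "kernel_matrix", "fit", "cross_validate",
           "grid_search"]

KERNELS = ("laplacian", "gaussian", "linear")


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: str, gamma: float = 1.0) -> np.ndarray:
    """Kernel Gram matrix between the rows of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature dimensions differ: {X.shape[1]} vs {Y.shape[1]}")
    if kernel == "linear":
        return pairwise_kernels(X, Y, metric="linear")
    if gamma <= 0:
        raise ValueError("gamma must be positive for exponential kernels")
    if kernel == "laplacian":
        return pairwise_kernels(X, Y, metric="laplacian", gamma=1.0 / gamma)
    if kernel == "gaussian":
        return pairwise_kernels(X, Y, metric="rbf", gamma=1.0 / (2.0 * gamma**2))
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


@dataclass
class KRRModel:
    """Fitted kernel ridge regressor: dual coefficients over training rows."""

    kernel: str
    gamma: float
    lam: float
    X_train: np.ndarray
    dual_coef: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float = 0.0
    standardized: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        X = (X - self.x_mean) / self.x_scale
        K = kernel_matrix(X, self.X_train, self.kernel, self.gamma)
        return K @ self.dual_coef + self.y_mean

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(f"{self.kernel}|{self.gamma}|{self.lam}".encode())
        h.update(np.ascontiguousarray(self.dual_coef).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        """Serialize as JSON metadata plus .npz arrays next to it."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), X_train=self.X_train,
                 dual_coef=self.dual_coef, x_mean=self.x_mean, x_scale=self.x_scale)
        meta = {"kernel": self.kernel, "gamma": self.gamma, "lam": self.lam,
                "y_mean": self.y_mean, "standardized": self.standardized}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KRRModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrs = np.load(path.with_suffix(".npz"))
        return cls(meta["kernel"], meta["gamma"], meta["lam"], arrs["X_train"],
                   arrs["dual_coef"], arrs["x_mean"], arrs["x_scale"],
                   meta["y_mean"], meta["standardized"])


@dataclass
class CVReport:
    """Per-fold RMSEs (kcal/mol) with their mean and standard deviation."""

    fold_rmse: list[float]
    seed: int
    standardized: bool = True

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.fold_rmse, ddof=0))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"fold_rmse": self.fold_rmse, "mean_rmse": self.mean_rmse,
             "sd_rmse": self.sd_rmse, "seed": self.seed,
             "standardized": self.standardized}, indent=2) + "\n")


def _preprocess(X: np.ndarray, standardize: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns always; scale them only when standardizing.

    Centering X pairs with centering y: together they keep affine targets
    exactly representable by the linear kernel, and they change nothing for
    the translation-invariant exponential kernels.
    """
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale == 0.0, 1.0, scale)  # constant columns pass through
    else:
        scale = np.ones(X.shape[1])
    return (X - mean) / scale, mean, scale


def fit(X: np.ndarray, y: np.ndarray, kernel: str = "laplacian",
        gamma: float = 1.0, lam: float = 1e-8, standardize: bool = True) -> KRRModel:
    """Solve (K + lam I) a = y on the training kernel matrix.

    Labels are centered on their training mean (the dual solve sees
    y - y_mean and predictions add it back), the kernel analogue of an
    intercept: a saturated exponential kernel then falls back to the mean
    label instead of zero. With lam = 0 and distinct points the model
    interpolates the labels. A singular system (e.g. duplicate rows at
    lam = 0) raises with advice to regularize.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the sample count")
    if X.shape[0] < 1:
        raise ValueError("need at least one training point")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in training data")
    if lam < 0:
        raise ValueError("ridge lam must be >= 0")
    Xs, mean, scale = _preprocess(X, standardize)
    y_mean = float(y.mean())
    yc = y - y_mean
    K = kernel_matrix(Xs, Xs, kernel, gamma)
    A = K + lam * np.eye(K.shape[0])
    try:
        coef = cho_solve(cho_factor(A), yc)
    except LinAlgError:
        # PSD but rank-deficient (e.g. linear kernel with d < n): take the
        # minimum-norm solution; an inconsistent system (duplicate rows with
        # different labels at lam = 0) shows up as a large residual
        coef, *_ = lstsq(A, yc, lapack_driver="gelsd")
        resid = np.linalg.norm(A @ coef - yc)
        if not np.all(np.isfinite(coef)) or resid > 1e-6 * max(1.0, np.linalg.norm(yc)):
            raise LinAlgError(
                "singular kernel system (duplicate rows at lam = 0?); "
                "use lam > 0"
            ) from None
    return KRRModel(kernel, gamma, lam, Xs, coef, mean, scale, y_mean, standardize)


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def cross_validate(X: np.ndarray, y: np.ndarray, kernel: str = "laplacian",
                   gamma: float = 1.0, lam: float = 1e-8, k: int = 10,
                   seed: int = 0, standardize: bool = True) -> CVReport:
    """k-fold CV RMSE with seeded shuffling into near-equal folds.

    Standardization statistics are recomputed inside each training fold, so
    no information leaks from the held-out fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    rmses = []
    for test_idx in _fold_indices(n, k, rng):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = fit(X[mask], y[mask], kernel, gamma, lam, standardize)
        pred = model.predict(X[test_idx])
        rmses.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
    return CVReport(rmses, seed, standardize)


def grid_search(X: np.ndarray, y: np.ndarray, kernel: str,
                gamma_grid: list[float], lam_grid: list[float],
                k: int = 10, seed: int = 0,
                standardize: bool = True) -> tuple[float, float, CVReport]:
    """Pick (gamma, lam) minimizing mean CV RMSE; ties go to more regularization.

    Returns the winning (gamma, lam) and its CV report. Tie-break: larger
    lam first, then larger gamma.
    """
    if not gamma_grid or not lam_grid:
        raise ValueError("grids must be non-empty")
    best: tuple[float, float, CVReport] | None = None
    best_key: tuple[float, float, float] | None = None
    for gamma in gamma_grid:
        for lam in lam_grid:
            report = cross_validate(X, y, kernel, gamma, lam, k, seed, standardize)
            key = (report.mean_rmse, -lam, -gamma)
            if best_key is None or key < best_key:
                best_key = key
                best = (gamma, lam, report)
    assert best is not None
    return best
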