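"""Multitask Gaussian-process regression core for pairwise treatment effects.

The model is an intrinsic-coregionalization multitask GP over the two
potential-outcome surfaces of a treatment pair: with arm label ``w`` in
{0, 1},

    cov(f_w(x), f_w'(x')) = B[w, w'] * k(x, x'),    y = f_w(x) + eps_w,

where ``k`` is a unit-variance RBF or Matern-5/2 input kernel (optionally
with per-dimension ARD lengthscales), ``B = L L^T`` is a free 2x2 PSD task
covariance parameterized by its lower-triangular factor (signal variances
live in ``B``), and each arm has its own Gaussian noise variance.  Binary
outcomes are treated as real-valued on {0, 1}; the posterior mean of each
surface is read as a response probability.  Hyperparameters are fitted by
multi-restart L-BFGS on the log marginal likelihood with analytic gradients.

A per-arm constant mean (the arm's training outcome mean) is subtracted
before fitting and added back at prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = ["KernelConfig", "MultitaskGP", "kernel_matrix"]

_JITTER = 1e-8
_LOG_BOUND = 12.0


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family and optimizer settings for the multitask GP.

    ``lengthscale`` is the initial (pre-optimization) value; ``None`` uses the
    median-distance heuristic.  ``diagonal_task`` constrains the task
    covariance to be diagonal, decoupling the two arms (shared input kernel
    aside); it exists chiefly for validation against independent single-output
    GPs.
    """

    kernel: str = "rbf"              # "rbf" | "matern52"
    ard: bool = False
    lengthscale: float | None = None
    diagonal_task: bool = False
    n_restarts: int = 5
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "matern52"):
            raise ValueError(f"unknown kernel family {self.kernel!r}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")

    @property
    def label(self) -> str:
        return f"{self.kernel}{'-ard' if self.ard else ''}"


# ---------------------------------------------------------------------------
# Kernels (unit signal variance; variance lives in the task covariance)
# ---------------------------------------------------------------------------

def _scaled_sqdist(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    return cdist(X1 / ls, X2 / ls, metric="sqeuclidean")


def kernel_matrix(name: str, X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Unit-variance kernel matrix between rows of ``X1`` and ``X2``."""
    ls = np.broadcast_to(np.asarray(ls, dtype=float), (X1.shape[1],))
    D2 = _scaled_sqdist(X1, X2, ls)
    if name == "rbf":
        return np.exp(-0.5 * D2)
    if name == "matern52":
        s = np.sqrt(5.0 * D2)
        return (1.0 + s + s**2 / 3.0) * np.exp(-s)
    raise ValueError(f"unknown kernel family {name!r}")


def _kernel_and_grads(name: str, X: np.ndarray, ls: np.ndarray, ard: bool):
    """Kernel matrix and its gradients w.r.t. each log-lengthscale."""
    n, d = X.shape
    ls = np.broadcast_to(np.asarray(ls, dtype=float), (d,)).copy()
    D2 = _scaled_sqdist(X, X, ls)
    grads: list[np.ndarray] = []
    if name == "rbf":
        K = np.exp(-0.5 * D2)
        if ard:
            for j in range(d):
                diff2 = (X[:, j, None] - X[None, :, j]) ** 2 / ls[j] ** 2
                grads.append(K * diff2)
        else:
            grads.append(K * D2)
    else:  # matern52
        s = np.sqrt(5.0 * D2)
        e = np.exp(-s)
        K = (1.0 + s + s**2 / 3.0) * e
        # dK/dlog ls_j = (5 diff_j^2 / (3 ls_j^2)) (1 + s) e^{-s}
        common = (1.0 + s) * e / 3.0
        if ard:
            for j in range(d):
                diff2 = (X[:, j, None] - X[None, :, j]) ** 2 / ls[j] ** 2
                grads.append(5.0 * diff2 * common)
        else:
            grads.append(5.0 * D2 * common)
    return K, grads


def median_heuristic(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median pairwise distance on a subsample, as a lengthscale scale."""
    n = len(X)
    idx = rng.choice(n, size=min(n, 300), replace=False)
    D = cdist(X[idx], X[idx])
    med = np.median(D[np.triu_indices_from(D, k=1)])
    return float(med) if med > 0 else 1.0


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

class _ParamLayout:
    """theta = [log ls (1 or d) | log l11 | (l21) | log l22 | log n0 | log n1]."""

    def __init__(self, d: int, ard: bool, diagonal_task: bool):
        self.n_ls = d if ard else 1
        self.diagonal = diagonal_task
        self.size = self.n_ls + (2 if diagonal_task else 3) + 2

    def unpack(self, theta: np.ndarray):
        i = self.n_ls
        ls = np.exp(theta[:i])
        l11 = np.exp(theta[i]); i += 1
        if self.diagonal:
            l21 = 0.0
        else:
            l21 = theta[i]; i += 1
        l22 = np.exp(theta[i]); i += 1
        n0 = np.exp(theta[i]); i += 1
        n1 = np.exp(theta[i])
        return ls, l11, l21, l22, n0, n1

    def pack(self, ls, l11, l21, l22, n0, n1) -> np.ndarray:
        parts = [np.log(np.atleast_1d(ls))]
        parts.append([np.log(l11)])
        if not self.diagonal:
            parts.append([l21])
        parts.append([np.log(l22), np.log(n0), np.log(n1)])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def _task_cov(l11: float, l21: float, l22: float) -> np.ndarray:
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class MultitaskGP:
    """Two-task GP regression with ICM covariance and per-arm noise."""

    def __init__(self, config: KernelConfig | None = None):
        self.config = config or KernelConfig()
        self.fitted_ = False

    # -- likelihood and gradient --------------------------------------------
    def _nll_and_grad(self, theta, X, w, y, layout):
        n = len(y)
        ls, l11, l21, l22, n0, n1 = layout.unpack(theta)
        B = _task_cov(l11, l21, l22)
        Kin, Kin_grads = _kernel_and_grads(self.config.kernel, X, ls, self.config.ard)
        Bm = B[np.ix_(w, w)]
        noise = np.where(w == 0, n0, n1)
        K = Bm * Kin + np.diag(noise + _JITTER)
        try:
            c, lower = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        alpha = cho_solve((c, lower), y)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        nll = 0.5 * (y @ alpha + logdet + n * np.log(2 * np.pi))

        Kinv = cho_solve((c, lower), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv  # dL/dK = 0.5 W (L = log lik)

        grad = np.zeros_like(theta)
        i = 0
        # lengthscales
        for g in Kin_grads:
            grad[i] = -0.5 * np.sum(W * (Bm * g))
            i += 1
        # task-covariance factor entries
        E11 = np.zeros((2, 2)); E11[0, 0] = 1.0
        E21 = np.zeros((2, 2)); E21[1, 0] = 1.0
        E22 = np.zeros((2, 2)); E22[1, 1] = 1.0
        L = np.array([[l11, 0.0], [l21, l22]])

        def dB(E):
            return E @ L.T + L @ E.T

        # d theta uses log for l11/l22 (chain rule multiplies by the value)
        dB11 = dB(E11) * l11
        grad[i] = -0.5 * np.sum(W * (dB11[np.ix_(w, w)] * Kin)); i += 1
        if not layout.diagonal:
            dB21 = dB(E21)
            grad[i] = -0.5 * np.sum(W * (dB21[np.ix_(w, w)] * Kin)); i += 1
        dB22 = dB(E22) * l22
        grad[i] = -0.5 * np.sum(W * (dB22[np.ix_(w, w)] * Kin)); i += 1
        # noises (log scale)
        diagW = np.diag(W)
        grad[i] = -0.5 * np.sum(diagW[w == 0]) * n0; i += 1
        grad[i] = -0.5 * np.sum(diagW[w == 1]) * n1
        return nll, grad

    # -- fitting -------------------------------------------------------------
    def fit(self, X: np.ndarray, w: np.ndarray, y: np.ndarray, seed: int = 0,
            n_restarts: int | None = None) -> "MultitaskGP":
        X = np.asarray(X, dtype=float)
        w = np.asarray(w, dtype=int)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(w) or len(w) != len(y):
            raise ValueError("X, w, y must be aligned")
        if not (np.any(w == 0) and np.any(w == 1)):
            raise ValueError("both arms must be represented in the training data")

        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        restarts = cfg.n_restarts if n_restarts is None else n_restarts

        # per-arm constant means
        self.arm_means_ = np.array([y[w == 0].mean(), y[w == 1].mean()])
        yc = y - self.arm_means_[w]
        sd_y = max(yc.std(), 0.1)

        d = X.shape[1]
        layout = _ParamLayout(d, cfg.ard, cfg.diagonal_task)
        ls0 = cfg.lengthscale if cfg.lengthscale is not None else median_heuristic(X, rng)
        base = layout.pack(np.full(layout.n_ls, ls0), sd_y, 0.0, sd_y, sd_y**2, sd_y**2)

        self.initial_theta_ = base.copy()
        best = None
        diagnostics = []
        for r in range(restarts):
            theta0 = base.copy()
            if r > 0:
                theta0 = theta0 + rng.normal(0.0, 0.5, size=theta0.size)
            res = minimize(
                self._nll_and_grad, theta0, args=(X, w, yc, layout),
                jac=True, method="L-BFGS-B",
                bounds=[(-_LOG_BOUND, _LOG_BOUND)] * theta0.size,
                options={"maxiter": cfg.max_iter},
            )
            diagnostics.append((r, res.fun, res.message))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"GP optimization failed on all restarts: {diagnostics}")

        self.theta_ = best.x
        self.layout_ = layout
        ls, l11, l21, l22, n0, n1 = layout.unpack(best.x)
        self.lengthscale_ = ls
        self.task_cov_ = _task_cov(l11, l21, l22)
        self.noise_ = np.array([n0, n1])
        self.log_marginal_likelihood_ = -best.fun
        self.X_, self.w_, self.yc_ = X, w, yc

        Bm = self.task_cov_[np.ix_(w, w)]
        Kin = kernel_matrix(cfg.kernel, X, X, ls)
        K = Bm * Kin + np.diag(self.noise_[w] + _JITTER)
        self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, yc)
        self.fitted_ = True
        return self

    def log_marginal_likelihood(self, theta: np.ndarray | None = None) -> float:
        """LML at ``theta`` (packed) or at the fitted optimum."""
        if theta is None:
            return self.log_marginal_likelihood_
        nll, _ = self._nll_and_grad(theta, self.X_, self.w_, self.yc_, self.layout_)
        return -nll

    def set_hyperparameters(self, X, w, y, *, lengthscale, task_cov, noise) -> "MultitaskGP":
        """Condition on data at fixed hyperparameters (no optimization)."""
        X = np.asarray(X, dtype=float)
        w = np.asarray(w, dtype=int)
        y = np.asarray(y, dtype=float)
        self.arm_means_ = np.array([y[w == 0].mean(), y[w == 1].mean()])
        yc = y - self.arm_means_[w]
        self.lengthscale_ = np.asarray(lengthscale, dtype=float)
        self.task_cov_ = np.asarray(task_cov, dtype=float)
        self.noise_ = np.asarray(noise, dtype=float)
        self.X_, self.w_, self.yc_ = X, w, yc
        self.log_marginal_likelihood_ = np.nan
        Bm = self.task_cov_[np.ix_(w, w)]
        Kin = kernel_matrix(self.config.kernel, X, X, self.lengthscale_)
        K = Bm * Kin + np.diag(self.noise_[w] + _JITTER)
        self._chol = cho_factor(K, lower=True)
        self._alpha = cho_solve(self._chol, yc)
        self.fitted_ = True
        return self

    # -- prediction ----------------------------------------------------------
    def predict_surfaces(self, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior means (m0, m1) of the two outcome surfaces at ``Xnew``."""
        if not self.fitted_:
            raise RuntimeError("model is not fitted")
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        if Xnew.shape[1] != self.X_.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model has {self.X_.shape[1]}, "
                f"got {Xnew.shape[1]}"
            )
        Kx = kernel_matrix(self.config.kernel, Xnew, self.X_, self.lengthscale_)
        out = []
        for task in (0, 1):
            cross = self.task_cov_[task, self.w_][None, :] * Kx
            out.append(self.arm_means_[task] + cross @ self._alpha)
        return out[0], out[1]

    def predict_tau(self, Xnew: np.ndarray) -> np.ndarray:
        """Posterior-mean treatment effect m1(x) - m0(x)."""
        m0, m1 = self.predict_surfaces(Xnew)
        return m1 - m0
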