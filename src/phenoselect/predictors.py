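"""Prediction models: ridge-regression BLUP and partial least squares.

rrBLUP fits ``y = 1*mu + Z u + e`` with ``u ~ N(0, I sigma2_u)``.  The
REML variances come from a single eigendecomposition of the (projected)
feature kernel, which makes the shrinkage search one-dimensional in
``log lambda`` (``lambda = sigma2_e / sigma2_u``); effects are then
``u_hat = (Z'Z + lambda I)^-1 Z'y``, computed through the dual kernel
form when there are more features than samples.

PLSR is a deterministic univariate NIPALS recursion on centered data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigError, DegenerateModelError

_LOG_LAM_LO, _LOG_LAM_HI = -18.0, 18.0


@dataclass
class RRBLUPModel:
    intercept: float
    u: np.ndarray
    lam: float
    sigma2_u: float
    sigma2_e: float
    feature_ids: Optional[list] = None
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept, "u": self.u.tolist(),
            "lam": self.lam, "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e, "feature_ids": self.feature_ids,
            "degenerate": self.degenerate})

    @classmethod
    def from_json(cls, text: str) -> "RRBLUPModel":
        d = json.loads(text)
        d["u"] = np.asarray(d["u"], dtype=float)
        return cls(**d)

    def predict(self, X_new: np.ndarray,
                feature_ids: Optional[Sequence] = None) -> np.ndarray:
        return predict_rrblup(self, X_new, feature_ids=feature_ids)


def _reml_lambda(theta: np.ndarray, eta2: np.ndarray) -> float:
    """Minimise the negative restricted log-likelihood over log lambda.

    ``theta`` are kernel eigenvalues on the fixed-effect complement,
    ``eta2`` the squared transformed data.  Profile form:
    f(lam) = m*log(sum(eta2/(theta+lam))) + sum(log(theta+lam)).
    """
    m = len(theta)

    def f(t: float) -> float:
        lam = np.exp(t)
        denom = theta + lam
        return m * np.log(np.sum(eta2 / denom)) + np.sum(np.log(denom))

    res = minimize_scalar(f, bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    return float(np.exp(res.x))


def fit_rrblup(X: np.ndarray, y: np.ndarray, lam: Optional[float] = None,
               feature_ids: Optional[Sequence] = None) -> RRBLUPModel:
    """Fit ridge-regression BLUP; ``lam=None`` estimates it by REML."""
    Z = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2:
        raise ConfigError("X must be 2-D")
    n, m = Z.shape
    if len(y) != n:
        raise ConfigError("X and y lengths differ")
    if n < 3:
        raise ConfigError("rrBLUP needs at least 3 samples")
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(y))):
        raise ConfigError("missing or non-finite values in input")
    ids = list(feature_ids) if feature_ids is not None else None
    if ids is not None and len(ids) != m:
        raise ConfigError("feature_ids length mismatch")

    if float(np.var(y)) < 1e-24:
        warnings.warn("zero-variance response: returning degenerate "
                      "rrBLUP model with zero effects")
        return RRBLUPModel(float(y.mean()), np.zeros(m), np.inf, 0.0, 0.0,
                           ids, degenerate=True)

    K = Z @ Z.T
    ones = np.ones(n)
    if lam is None:
        # restricted transform: eigenbasis of the kernel on the
        # orthogonal complement of the intercept
        B = _ones_complement_basis(n)
        theta, W = np.linalg.eigh(B.T @ K @ B)
        theta = np.clip(theta, 0.0, None)
        eta = W.T @ (B.T @ y)
        lam_hat = _reml_lambda(theta, eta ** 2)
        sigma2_u = float(np.sum(eta ** 2 / (theta + lam_hat)) / (n - 1))
        sigma2_e = float(lam_hat * sigma2_u)
    else:
        if lam < 0:
            raise ConfigError("lambda must be >= 0")
        lam_hat, sigma2_u, sigma2_e = float(lam), np.nan, np.nan

    # eigen-based solve of (K + lam I) x = b keeps the near-singular
    # no-noise limit stable
    d, V = np.linalg.eigh(K)
    inv = 1.0 / (np.clip(d, 0.0, None) + max(lam_hat, 1e-12 * max(
        float(d[-1]), 1.0)))
    Hi_ones = V @ (inv * (V.T @ ones))
    Hi_y = V @ (inv * (V.T @ y))
    mu = float(ones @ Hi_y / (ones @ Hi_ones))
    u = Z.T @ (Hi_y - mu * Hi_ones)
    return RRBLUPModel(mu, u, lam_hat, sigma2_u, sigma2_e, ids)


def _ones_complement_basis(n: int) -> np.ndarray:
    """Orthonormal (Helmert) basis of the complement of the all-ones
    vector, as an n x (n-1) matrix."""
    B = np.zeros((n, n - 1))
    for k in range(1, n):
        B[:k, k - 1] = 1.0
        B[k, k - 1] = -k
        B[:, k - 1] /= np.sqrt(k * (k + 1))
    return B


def predict_rrblup(model: RRBLUPModel, X_new: np.ndarray,
                   feature_ids: Optional[Sequence] = None) -> np.ndarray:
    """``y_hat = intercept + X_new @ u``, realigning features by id."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if feature_ids is not None and model.feature_ids is not None:
        ids = list(feature_ids)
        if sorted(map(str, ids)) != sorted(map(str, model.feature_ids)):
            raise ConfigError("feature ids do not match training features")
        pos = {str(f): i for i, f in enumerate(ids)}
        X_new = X_new[:, [pos[str(f)] for f in model.feature_ids]]
    elif X_new.shape[1] != len(model.u):
        raise ConfigError(
            f"expected {len(model.u)} features, got {X_new.shape[1]}")
    return model.intercept + X_new @ model.u


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (m, A)
    loadings: np.ndarray      # (m, A)
    q: np.ndarray             # (A,)
    coef: np.ndarray          # (m,) regression coefficients, centered space
    coef_path: np.ndarray = field(repr=False, default=None)  # (A, m)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X_new: np.ndarray,
                n_components: Optional[int] = None) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if n_components is None:
            b = self.coef
        else:
            if not 1 <= n_components <= self.n_components:
                raise ConfigError("n_components out of fitted range")
            b = self.coef_path[n_components - 1]
        return self.y_mean + (X_new - self.x_mean) @ b

    def to_json(self) -> str:
        return json.dumps({
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(), "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(), "q": self.q.tolist(),
            "coef": self.coef.tolist(),
            "coef_path": self.coef_path.tolist()})


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int = 12
             ) -> PLSRModel:
    """Univariate-response PLS by the NIPALS recursion on centered data.

    The requested number of latent components is capped at the
    effective rank of the deflated predictor matrix (with a warning).
    """
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    a_max = min(n_components, n - 1, m)
    W, P, Q, T = [], [], [], []
    eps = 1e-12 * max(1.0, float(np.abs(Xc).max()) ** 2)
    Xd, yd = Xc.copy(), yc.copy()
    for _ in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < eps:
            break
        p = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
        T.append(t)
    if not W:
        raise DegenerateModelError("no usable PLS component (X'y is zero)")
    A = len(W)
    if A < n_components:
        warnings.warn(f"PLSR components capped at {A} "
                      f"(requested {n_components})")
    W = np.column_stack(W)
    P = np.column_stack(P)
    Q = np.asarray(Q)

    # nested coefficient path: B_a = W_a (P_a' W_a)^-1 q_a
    coef_path = np.empty((A, m))
    for a in range(1, A + 1):
        R = np.linalg.solve(P[:, :a].T @ W[:, :a], np.eye(a))
        coef_path[a - 1] = W[:, :a] @ (R @ Q[:a])
    return PLSRModel(A, x_mean, y_mean, W, P, Q, coef_path[-1], coef_path)


def select_plsr_components(X: np.ndarray, y: np.ndarray,
                           max_components: int, k: int = 5,
                           n_replicates: int = 5, seed: int = 0) -> int:
    """Component count minimising cross-validated RMSEP with the
    one-sigma parsimony rule (smallest count within one standard error
    of the minimum)."""
    if max_components < 1:
        raise ConfigError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ConfigError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    a_cap = min(max_components, n - int(np.ceil(n / k)) - 1, X.shape[1])
    a_cap = max(a_cap, 1)
    sq_errors = [[] for _ in range(a_cap)]  # per component, per fold MSE
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, k):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsr(X[mask], y[mask], n_components=a_cap)
            for a in range(1, model.n_components + 1):
                pred = model.predict(X[fold], n_components=a)
                sq_errors[a - 1].append(float(np.mean((pred - y[fold]) ** 2)))
            for a in range(model.n_components + 1, a_cap + 1):
                sq_errors[a - 1].append(sq_errors[model.n_components - 1][-1])
    rmsep = np.array([np.sqrt(np.mean(e)) for e in sq_errors])
    se = np.array([np.std(np.sqrt(e), ddof=1) / np.sqrt(len(e))
                   if len(e) > 1 else 0.0 for e in sq_errors])
    best = int(np.argmin(rmsep))
    threshold = rmsep[best] + se[best]
    for a in range(a_cap):
        if rmsep[a] <= threshold:
            return a + 1
    return best + 1
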