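"""PLS regression and its cross-validation statistics.

The regression model is Y = X b + e with the coefficient vector b obtained
by NIPALS deflation on centered (optionally unit-scaled) data, the model
complexity A chosen by leave-one-out cross-validation.  The reported
statistics follow the standard chemometric definitions:

    q2_cv   = 1 - sum_i (obs_i - pred_i)^2 / sum_i (obs_i - mean(obs))^2
    SDEP    = sqrt( sum_i (pred_i - obs_i)^2 / n )
    q2_test = 1 - sum (obs - pred)^2 / sum (obs - mean(obs_test))^2

where the LOO predictions come from m refits each excluding one object and
mean(obs) in the q2_cv denominator is taken over all m objects.

Field (CoMFA/CoMSA) matrices are conventionally centered but not
unit-scaled; general descriptor matrices are usually standardized — the
``scale`` flag records the choice in the fit.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class CVStats(NamedTuple):
    q2: float
    sdep: float


class ExternalStats(NamedTuple):
    sdep: float
    q2_test: float


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    return X, y


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 NIPALS on centered data.

    Returns (W, P, q, n_used): X-weights, X-loadings, y-loadings.  Stops
    early (with a warning upstream) when the residual collapses, i.e. the
    requested complexity exceeds the effective rank.
    """
    n, p = Xc.shape
    Xr, yr = Xc.copy(), yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    tol = 1e-12 * max(1.0, float(np.abs(Xc).max()) ** 2)
    used = 0
    for a in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt < tol:
            break
        P[:, a] = Xr.T @ t / tt
        q[a] = float(yr @ t) / tt
        W[:, a] = w
        Xr -= np.outer(t, P[:, a])
        yr -= q[a] * t
        used += 1
    return W[:, :used], P[:, :used], q[:used], used


class NipalsPLS(BaseEstimator, RegressorMixin):
    """PLS1 regression via NIPALS deflation.

    Parameters
    ----------
    n_components : int
        Latent components A; clamped (with a warning) to the effective rank.
    scale : bool
        Unit-variance scaling of columns after centering.  Off by default,
        matching the field-matrix convention.

    Attributes
    ----------
    coef_ : coefficient vector b on the original (unscaled) variables.
    n_components_ : number of components actually extracted.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "NipalsPLS":
        X, y = _as_xy(X, y)
        if len(y) < 3:
            raise ValueError("need at least 3 training objects")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            self.x_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.x_std_ = np.ones(X.shape[1])
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        a_cap = min(len(y) - 1, X.shape[1])
        a_req = min(self.n_components, a_cap)
        W, P, q, used = _nipals(Xc, yc, a_req)
        if used < self.n_components:
            warnings.warn(
                f"n_components clamped from {self.n_components} to {used} (rank limit)",
                stacklevel=2,
            )
        self.n_components_ = used
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        if used == 0:  # constant response: b = 0
            self.coef_ = np.zeros(X.shape[1])
        else:
            # b for centered/scaled data: W (P'W)^-1 q
            b = W @ np.linalg.solve(P.T @ W, q)
            self.coef_ = b / self.x_std_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def score(self, X, y) -> float:
        """q2_test of the fitted model on external data."""
        return external_stats(self, X, y).q2_test


def fit_pls(X, y, n_components: int, scale: bool = False) -> NipalsPLS:
    """Fit a PLS model; thin functional wrapper over :class:`NipalsPLS`."""
    return NipalsPLS(n_components=n_components, scale=scale).fit(X, y)


def _loo_pred_multi(X: np.ndarray, y: np.ndarray, a_max: int, scale: bool):
    """LOO predictions for every component count 1..a_max.

    Returns (preds, B) where preds has shape (n, a_max) — the prediction of
    object i from the model trained without it, per complexity — and B has
    shape (n, p): the coefficient vector of each LOO submodel at a_max.
    """
    n, p = X.shape
    preds = np.empty((n, a_max))
    B = np.empty((n, p))
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        Xi, yi = X[m], y[m]
        mu, ym = Xi.mean(axis=0), yi.mean()
        if scale:
            sd = Xi.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            sd = 1.0
        Xc = (Xi - mu) / sd
        W, P, q, used = _nipals(Xc, yi - ym, min(a_max, n - 2, p))
        xt = (X[i] - mu) / sd
        # accumulate the test prediction component by component
        pred = ym
        for a in range(a_max):
            if a < used:
                t = float(xt @ W[:, a])
                pred += t * q[a]
                xt = xt - t * P[:, a]
            preds[i, a] = pred
        if used == 0:
            B[i] = 0.0
        else:
            b = W @ np.linalg.solve(P.T @ W, q)
            B[i] = b / (sd if np.ndim(sd) else np.ones(p))
    return preds, B


def loo_predictions(X, y, n_components: int, scale: bool = False) -> np.ndarray:
    """Prediction of each object from the model excluding it (fixed A)."""
    X, y = _as_xy(X, y)
    preds, _ = _loo_pred_multi(X, y, n_components, scale)
    return preds[:, -1]


def loo_coefficients(X, y, n_components: int, scale: bool = False) -> np.ndarray:
    """Coefficient vector b of every LOO submodel, shape (n, p)."""
    X, y = _as_xy(X, y)
    _, B = _loo_pred_multi(X, y, n_components, scale)
    return B


def _q2(obs: np.ndarray, pred: np.ndarray, center: float) -> float:
    denom = float(((obs - center) ** 2).sum())
    if denom == 0:
        raise ValueError("response has zero variance; q2 undefined")
    return 1.0 - float(((obs - pred) ** 2).sum()) / denom


def loo_q2(X, y, n_components: int, scale: bool = False) -> CVStats:
    """Leave-one-out q2_cv and SDEP_cv at a fixed complexity."""
    X, y = _as_xy(X, y)
    pred = loo_predictions(X, y, n_components, scale)
    q2 = _q2(y, pred, float(y.mean()))
    sdep = float(np.sqrt(((pred - y) ** 2).mean()))
    return CVStats(q2, sdep)


def external_stats(fit: NipalsPLS, X_test, y_test) -> ExternalStats:
    """SDEP and q2_test of a fitted model on held-out objects."""
    X_test, y_test = _as_xy(X_test, y_test)
    if len(y_test) < 2:
        raise ValueError("need at least 2 test objects")
    pred = fit.predict(X_test)
    sdep = float(np.sqrt(((pred - y_test) ** 2).mean()))
    q2 = _q2(y_test, pred, float(y_test.mean()))
    return ExternalStats(sdep, q2)


def select_components(X, y, a_max: int = 5, scale: bool = False) -> int:
    """Smallest A attaining the maximal LOO q2 (parsimony tie-break)."""
    X, y = _as_xy(X, y)
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    a_max = min(a_max, len(y) - 2, X.shape[1])
    a_max = max(a_max, 1)
    preds, _ = _loo_pred_multi(X, y, a_max, scale)
    denom = float(((y - y.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("response has zero variance; q2 undefined")
    q2s = 1.0 - ((y[:, None] - preds) ** 2).sum(axis=0) / denom
    best = float(q2s.max())
    return int(np.argmax(q2s >= best - 1e-12)) + 1
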