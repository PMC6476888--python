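"""Iterative variable elimination for PLS (IVE-PLS).

Column stability is the ratio |mean(b_j)| / std(b_j) over an ensemble of
PLS submodels (here: the leave-one-out refits that already drive q2_cv).
The elimination loop repeatedly removes the single column with the lowest
stability, refits, and tracks q2_cv; the retained subset is the one at the
q2_cv-maximal step.  The procedure is fully deterministic: ties in
stability are broken toward the lowest column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from naphqsar.pls import _as_xy, _loo_pred_multi


@dataclass(frozen=True)
class EliminationStep:
    columns: tuple[int, ...]  # column ids remaining at this step
    q2: float
    sdep: float
    eliminated: int | None  # column removed after this step
    eliminated_stability: float | None
    stability: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class EliminationTrace:
    steps: tuple[EliminationStep, ...]

    @property
    def optimal_index(self) -> int:
        """First step attaining the maximal q2 (ties keep more columns)."""
        q2s = [s.q2 for s in self.steps]
        return int(np.argmax(q2s))

    @property
    def selected_columns(self) -> tuple[int, ...]:
        return self.steps[self.optimal_index].columns

    @property
    def q2_path(self) -> np.ndarray:
        return np.array([s.q2 for s in self.steps])


def _stability_from_b(B: np.ndarray) -> np.ndarray:
    """|mean(b_j)| / std(b_j) per column; 0/0 -> 0, x/0 -> +inf."""
    mean = B.mean(axis=0)
    std = B.std(axis=0, ddof=1)
    out = np.empty(B.shape[1])
    zero = std < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero] = np.abs(mean[~zero]) / std[~zero]
    out[zero] = np.where(np.abs(mean[zero]) > 0, np.inf, 0.0)
    return out


def column_stability(X, y, n_components: int, scale: bool = False) -> np.ndarray:
    """Per-column stability over the LOO submodel coefficient ensemble."""
    X, y = _as_xy(X, y)
    if len(y) < 3:
        raise ValueError("need at least 3 rows")
    _, B = _loo_pred_multi(X, y, min(n_components, len(y) - 2, X.shape[1]), scale)
    return _stability_from_b(B)


def run_ive(
    X,
    y,
    n_components: int,
    min_columns: int = 1,
    scale: bool = False,
) -> EliminationTrace:
    """Backward elimination of the least stable column, tracking LOO q2.

    Each step runs one LOO pass that yields both the q2/SDEP of the current
    subset and the coefficient ensemble for the stability ranking; exactly
    one column is removed per step until ``min_columns`` remain.
    """
    X, y = _as_xy(X, y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns to eliminate from")
    if not 1 <= min_columns <= X.shape[1]:
        raise ValueError("min_columns out of range")
    cols = np.arange(X.shape[1])
    denom = float(((y - y.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("response has zero variance")
    steps = []
    while True:
        a = min(n_components, len(y) - 2, len(cols))
        preds, B = _loo_pred_multi(X[:, cols], y, a, scale)
        pred = preds[:, -1]
        q2 = 1.0 - float(((y - pred) ** 2).sum()) / denom
        sdep = float(np.sqrt(((pred - y) ** 2).mean()))
        stability = _stability_from_b(B)
        if len(cols) <= min_columns:
            steps.append(EliminationStep(tuple(cols), q2, sdep, None, None, stability))
            break
        j = int(np.argmin(stability))  # argmin takes the lowest index on ties
        steps.append(
            EliminationStep(tuple(cols), q2, sdep, int(cols[j]), float(stability[j]), stability)
        )
        cols = np.delete(cols, j)
    return EliminationTrace(tuple(steps))


class IVEPLS(BaseEstimator, TransformerMixin):
    """Feature selector driven by IVE-PLS.

    ``fit`` records the full elimination trace; ``transform`` keeps the
    q2-optimal column subset.  Compatible with sklearn pipelines.
    """

    def __init__(self, n_components: int = 3, min_columns: int = 1, scale: bool = False):
        self.n_components = n_components
        self.min_columns = min_columns
        self.scale = scale

    def fit(self, X, y) -> "IVEPLS":
        X, y = _as_xy(X, y)
        self.trace_ = run_ive(X, y, self.n_components, self.min_columns, self.scale)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(self.trace_.selected_columns)] = True
        self.q2_ = float(self.trace_.steps[self.trace_.optimal_index].q2)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
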