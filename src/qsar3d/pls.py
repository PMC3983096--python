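"""Partial least squares engine: NIPALS fit, cross-validation, component
selection, region focusing and bootstrap stability.

The descriptor matrix is far wider than it is tall (thousands of grid-point
columns, tens of compounds), the regime PLS was designed for: activities
are regressed on a few latent components extracted by the NIPALS algorithm
from mean-centred data. Model quality is tracked with

* ``r^2`` and ``SEE = sqrt(RSS / (n - c - 1))`` on the training fit,
* ``q^2 = 1 - PRESS / sum((y - ybar)^2)`` and
  ``SEP = sqrt(PRESS / (n - c - 1))`` from leave-one-out or leave-group-out
  cross-validation, where PRESS sums squared errors of compounds predicted
  while left out,
* ``F = [r^2 / (1 - r^2)] * [(n - c - 1) / c]``.

The component count is chosen by a parsimony rule: a model with one more
component is accepted only while it improves q^2 by more than 10% (relative
to the current q^2). Region focusing reweights each column by
``(|coefficient| * column stdev)^w`` and refits, sharpening the model around
lattice regions that already carry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .fields import DescriptorMatrix

__all__ = [
    "PLSModel", "FitStatistics", "CVResult", "BootstrapResult",
    "RegionFocusResult", "fit_pls", "predict_activity", "loo_cv",
    "select_onc", "group_cv", "bootstrap_fit", "region_focus", "model_summary",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.X
    return np.asarray(X, dtype=float)


@dataclass(frozen=True)
class PLSModel:
    n_components: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    x_weights: np.ndarray  # (p, c)
    x_loadings: np.ndarray  # (p, c)
    x_scores: np.ndarray  # (n, c)
    y_loadings: np.ndarray  # (c,)
    coef: np.ndarray  # (p,), on centred data
    training_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite regression coefficients")

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, X) -> np.ndarray:
        X = _as_array(X)
        if X.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"column mismatch: model has {self.coef.shape[0]} columns, "
                f"data has {X.shape[1]}")
        return (X - self.x_mean) @ self.coef + self.y_mean


@dataclass(frozen=True)
class FitStatistics:
    r2: float
    see: float
    f: float
    n: int
    n_components: int
    contributions: dict[str, float]  # per field block, sums to 1


@dataclass(frozen=True)
class CVResult:
    predictions: np.ndarray  # one per compound, predicted while left out
    q2: float
    sep: float
    n_components: int


@dataclass(frozen=True)
class BootstrapResult:
    r2_mean: float
    r2_sd: float
    see_mean: float
    see_sd: float
    n_resamples: int
    n_skipped: int


@dataclass
class RegionFocusResult:
    matrix: DescriptorMatrix
    model: PLSModel
    q2_before: float
    q2_after: float
    weights: np.ndarray = dc_field(repr=False)


def _check_xy(X: np.ndarray, y: np.ndarray, c: int) -> None:
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")
    if np.ptp(y) == 0:
        raise ValueError("constant activities: model undefined")
    if not (1 <= c <= min(n - 1, p)):
        raise ValueError(f"components must lie in [1, min(n-1, p)] = "
                         f"[1, {min(n - 1, p)}], got {c}")


def fit_pls(X, y: Sequence[float], c: int,
            training_ids: Sequence[str] | None = None) -> PLSModel:
    """Fit a PLS1 model with *c* latent components by NIPALS.

    X and y are mean-centred internally; no per-column autoscaling is
    applied (block scaling, if any, happens in the descriptor matrix).
    For univariate y each NIPALS component is a single deflation step, so
    the algorithm is exact, not iterative.
    """
    ids = tuple(X.ids) if isinstance(X, DescriptorMatrix) and training_ids is None \
        else (tuple(training_ids) if training_ids is not None else None)
    X = _as_array(X).copy()
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, c)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, c))
    P = np.zeros((p, c))
    T = np.zeros((n, c))
    q = np.zeros(c)
    for h in range(c):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual X carries no covariance with y; pad with zeros
            W, P, T, q = W[:, :h], P[:, :h], T[:, :h], q[:h]
            c = h
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, T, q = W[:, :h], P[:, :h], T[:, :h], q[:h]
            c = h
            break
        p_h = E.T @ t / tt
        q_h = float(f @ t / tt)
        E = E - np.outer(t, p_h)
        f = f - q_h * t
        W[:, h], P[:, h], T[:, h], q[h] = w, p_h, t, q_h
    if c == 0:
        raise ValueError("no extractable PLS component (X uncorrelated with y)")
    # B = W (P^T W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_components=c, x_mean=x_mean, y_mean=y_mean,
                    x_weights=W, x_loadings=P, x_scores=T, y_loadings=q,
                    coef=coef, training_ids=ids)


def predict_activity(model: PLSModel, X) -> np.ndarray:
    """Predicted activities for descriptor rows matching the model's columns."""
    return model.predict(X)


def _press_stats(y: np.ndarray, pred: np.ndarray, c: int) -> tuple[float, float]:
    press = float(np.sum((pred - y) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss
    n = len(y)
    sep = float(np.sqrt(press / (n - c - 1))) if n - c - 1 > 0 else float("nan")
    return q2, sep


def loo_cv(X, y: Sequence[float], c: int) -> CVResult:
    """Leave-one-out cross-validation: refit without each compound, predict it."""
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 compounds")
    _check_xy(X, y, c)
    pred = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = fit_pls(X[mask], y[mask], min(c, n - 2))
        pred[i] = m.predict(X[i:i + 1])[0]
        mask[i] = True
    q2, sep = _press_stats(y, pred, c)
    return CVResult(predictions=pred, q2=q2, sep=sep, n_components=c)


def select_onc(X, y: Sequence[float], c_max: int = 10,
               threshold: float = 0.10, eps: float = 0.01
               ) -> tuple[int, list[float]]:
    """Choose the optimal number of components by the 10% improvement rule.

    Starting at one component, a higher component count is accepted only
    while it raises cross-validated q^2 by more than ``threshold`` relative
    to the current value (``eps`` floors the comparison base so the rule
    stays meaningful when q^2 is near zero or negative). Ties and marginal
    gains resolve to the smaller count. Returns the chosen count and the
    trace of every q^2 evaluated.
    """
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    limit = min(c_max, X.shape[0] - 2, X.shape[1])
    trace = [loo_cv(X, y, 1).q2]
    c = 1
    while c < limit:
        q2_next = loo_cv(X, y, c + 1).q2
        trace.append(q2_next)
        if q2_next - trace[c - 1] > threshold * max(trace[c - 1], eps):
            c += 1
        else:
            break
    return c, trace


def group_cv(X, y: Sequence[float], c: int, groups: int = 10,
             repeats: int = 25, seed: int = 0) -> CVResult:
    """Leave-group-out cross-validation, averaged over random partitions.

    Compounds are split into ``groups`` nearly equal folds; each fold is
    predicted by a model trained on the remainder. q^2 and SEP are averaged
    over ``repeats`` partitions; the returned predictions are per-compound
    means over repeats. ``groups == n`` reduces exactly to leave-one-out.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not (2 <= groups <= n):
        raise ValueError(f"groups must lie in [2, n={n}]")
    _check_xy(X, y, c)
    rng = np.random.default_rng(seed)
    q2s, seps = [], []
    pred_sum = np.zeros(n)
    for _ in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, groups)
        pred = np.empty(n)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            m = fit_pls(X[mask], y[mask], min(c, int(mask.sum()) - 1))
            pred[fold] = m.predict(X[fold])
        q2, sep = _press_stats(y, pred, c)
        q2s.append(q2)
        seps.append(sep)
        pred_sum += pred
    return CVResult(predictions=pred_sum / repeats, q2=float(np.mean(q2s)),
                    sep=float(np.mean(seps)), n_components=c)


def bootstrap_fit(X, y: Sequence[float], c: int, B: int = 100,
                  seed: int = 0) -> BootstrapResult:
    """Row-resampling bootstrap of the non-validated fit at fixed c.

    Each of B resamples draws n compounds with replacement and refits;
    r^2 and SEE are summarised as mean +/- sd. Degenerate resamples
    (constant activity) are skipped and counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, c)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    r2s, sees = [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.ptp(yb) == 0:
            skipped += 1
            continue
        m = fit_pls(X[idx], yb, min(c, n - 2))
        stats = _fit_stats(m, X[idx], yb)
        r2s.append(stats[0])
        sees.append(stats[1])
    return BootstrapResult(r2_mean=float(np.mean(r2s)), r2_sd=float(np.std(r2s)),
                           see_mean=float(np.mean(sees)), see_sd=float(np.std(sees)),
                           n_resamples=len(r2s), n_skipped=skipped)


def _fit_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    pred = model.predict(X)
    ss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - rss / ss
    n, c = len(y), model.n_components
    dof = n - c - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    if r2 >= 1.0 - 1e-15:
        f = float("inf")
    else:
        f = (r2 / (1.0 - r2)) * (dof / c)
    return r2, see, f


def region_focus(X: DescriptorMatrix, y: Sequence[float], model: PLSModel,
                 weight_power: float = 1.0) -> RegionFocusResult:
    """Reweight columns by (|coef| * stdev)^w, normalised to unit mean, refit.

    Columns whose coefficient-times-spread product is large — the lattice
    regions the model already leans on — gain weight; noise columns shrink.
    ``weight_power = 0`` is the identity. q^2 before and after (leave-one-out
    at the model's component count) are both reported.
    """
    if weight_power < 0:
        raise ValueError("weight power must be >= 0")
    y = np.asarray(y, dtype=float)
    std = X.X.std(axis=0, ddof=1)
    base = np.abs(model.coef) * std
    w = base ** weight_power
    mean_w = w.mean()
    if mean_w <= 0:
        raise ValueError("all focusing weights vanished (all-zero coefficients)")
    w = w / mean_w
    q2_before = loo_cv(X, y, model.n_components).q2
    Xf = X.reweighted(w)
    refit = fit_pls(Xf, y, model.n_components)
    q2_after = loo_cv(Xf, y, model.n_components).q2
    return RegionFocusResult(matrix=Xf, model=refit, q2_before=q2_before,
                             q2_after=q2_after, weights=w)


def model_summary(model: PLSModel, X, y: Sequence[float]) -> FitStatistics:
    """Training-fit statistics plus per-field-block contribution fractions.

    A block's contribution is its share of sum(|coef_j| * stdev_j) over all
    retained columns — the conventional field-distribution measure.
    """
    Xarr = _as_array(X)
    y = np.asarray(y, dtype=float)
    r2, see, f = _fit_stats(model, Xarr, y)
    contrib: dict[str, float] = {}
    std = Xarr.std(axis=0, ddof=1)
    importance = np.abs(model.coef) * std
    total = importance.sum()
    if isinstance(X, DescriptorMatrix) and total > 0:
        for kind in X.calculator.kinds:
            cols = X.block_columns(kind)
            if cols.size:
                contrib[kind] = float(importance[cols].sum() / total)
    else:
        contrib["x"] = 1.0
    return FitStatistics(r2=r2, see=see, f=f, n=len(y),
                         n_components=model.n_components, contributions=contrib)
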