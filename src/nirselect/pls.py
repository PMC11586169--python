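"""NIPALS partial least squares regression (PLS1) with RMSECV model selection.

The calibration model relates a mean-centered spectral matrix ``X`` (samples x
wavelengths) to the SSC vector ``y`` through a small number of latent variables
(LVs). Each NIPALS component extracts a weight vector ``w = X'y / ||X'y||``, a
score ``t = Xw``, loadings ``p = X't / t't`` and ``q = y't / t't``, then deflates
``X``. With a single response the inner loop is non-iterative, and successive
score vectors are mutually orthogonal. The accumulated model collapses to one
regression vector in wavelength space, so prediction is a single dot product.

Model order is chosen by cross-validated RMSECV (leave-one-out by default),
taking the first LV count that attains the minimum. Model quality is reported
in the convention of fruit-calibration studies:

    r     = 1 - SSE / SST        (the Rc / Rp columns)
    rmse  = sqrt(SSE / n)

where SSE sums squared prediction errors and SST squared deviations of ``y``
from its mean. The first quantity is algebraically a coefficient of
determination even though calibration literature often labels it a correlation
coefficient; a Pearson variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ReferenceTable, SpectrumSet

__all__ = [
    "PLSModel",
    "Metrics",
    "CVResult",
    "fit",
    "predict",
    "rmsecv",
    "evaluate",
    "split_calibration_prediction",
    "split_indices",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500  # single-response NIPALS converges in one pass; kept for safety


# -- core decomposition --------------------------------------------------


def _coef_paths(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; cumulative regression vectors per LV count.

    Returns ``(B, W, P, Q, T, n_eff)`` where ``B[:, k-1]`` is the regression
    vector of the k-LV model, rows of ``W``/``P`` are weights/loadings, ``Q``
    the y-loadings and ``T`` the score matrix. If deflation exhausts the signal
    before ``n_lv`` components (``n_eff < n_lv``), later columns of ``B``
    repeat the last informative one.
    """
    n, p = Xc.shape
    X = Xc.copy()
    B = np.zeros((p, n_lv))
    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    Q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    R = np.zeros((n_lv, p))  # weights orthogonalized against previous loadings
    y_scale = float(np.sqrt(yc @ yc)) or 1.0
    n_eff = 0
    b_prev = np.zeros(p)
    for i in range(n_lv):
        w = X.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= _NIPALS_TOL * y_scale:
            B[:, i:] = b_prev[:, None]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _NIPALS_TOL:
            B[:, i:] = b_prev[:, None]
            break
        p_i = (X.T @ t) / tt
        q_i = float(yc @ t) / tt
        X -= np.outer(t, p_i)
        # r_i makes B cumulative: r_i = w_i - sum_{j<i} (p_j . w_i) r_j
        r = w.copy()
        if i:
            r -= R[:i].T @ (P[:i] @ w)
        W[i], P[i], Q[i], T[:, i], R[i] = w, p_i, q_i, t, r
        b_prev = b_prev + q_i * r
        B[:, i] = b_prev
        n_eff = i + 1
    if n_eff < n_lv:
        for j in range(n_eff, n_lv):
            B[:, j] = b_prev
    return B, W[:n_eff], P[:n_eff], Q[:n_eff], T[:, :n_eff], n_eff


@dataclass
class PLSModel:
    """A fitted centered PLS1 model."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_eff, p)
    x_loadings: np.ndarray  # (n_eff, p)
    y_loadings: np.ndarray  # (n_eff,)
    regression_vector: np.ndarray  # (p,)
    n_lv: int
    n_effective: int
    training_meta: dict = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return self.regression_vector.size

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "n_lv": self.n_lv,
            "n_effective": self.n_effective,
            "training_meta": self.training_meta,
        }


def _check_Xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return X, y


def fit(X: np.ndarray, y: np.ndarray, n_lv: int, training_meta: dict | None = None) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (mean-centering only)."""
    X, y = _check_Xy(X, y)
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} out of bounds [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        warnings.warn("y is constant; returning a zero regression vector", stacklevel=2)
        return PLSModel(x_mean, y_mean, np.zeros((0, p)), np.zeros((0, p)), np.zeros(0),
                        np.zeros(p), n_lv, 0, training_meta or {})
    B, W, P, Q, T, n_eff = _coef_paths(X - x_mean, yc, n_lv)
    return PLSModel(x_mean, y_mean, W, P, Q, B[:, n_lv - 1].copy(), n_lv, n_eff,
                    training_meta or {})


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict SSC: ``y_hat = (X - x_mean) . regression_vector + y_mean``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_variables:
        raise ValueError(
            f"X has {X.shape[1]} variables but model expects {model.n_variables}"
        )
    return (X - model.x_mean) @ model.regression_vector + model.y_mean


# -- evaluation ----------------------------------------------------------


@dataclass
class Metrics:
    """Calibration/prediction quality (r and RMSE on the same samples)."""

    r: float
    rmse: float
    n: int
    y: np.ndarray
    y_hat: np.ndarray
    y_bar: float


def evaluate(y: np.ndarray, y_hat: np.ndarray, method: str = "printed") -> Metrics:
    """Compute ``r`` and RMSE for measured vs predicted values.

    ``method="printed"`` uses ``r = 1 - SSE/SST``, the formula behind the
    Rc/Rp columns of calibration reports; ``method="pearson"`` substitutes the
    Pearson correlation between ``y`` and ``y_hat``.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat lengths differ")
    if y.size < 2:
        raise ValueError("need n >= 2")
    y_bar = float(y.mean())
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y_bar) ** 2))
    if sst <= 0:
        raise ValueError("undefined r: y is constant (SST = 0)")
    if method == "printed":
        r = 1.0 - sse / sst
    elif method == "pearson":
        r = float(np.corrcoef(y, y_hat)[0, 1])
    else:
        raise ValueError(f"unknown metric method {method!r}")
    rmse = float(np.sqrt(sse / y.size))
    return Metrics(r=r, rmse=rmse, n=y.size, y=y, y_hat=y_hat, y_bar=y_bar)


# -- cross-validation ----------------------------------------------------


@dataclass
class CVResult:
    rmsecv_by_lv: np.ndarray  # index k-1 holds the k-LV RMSECV, % SSC
    chosen_lv: int  # first LV count attaining the minimum
    cv_scheme: str


def _folds(n: int, cv: str | tuple, seed: int) -> list[np.ndarray]:
    """Validation-index folds for 'loo' or ('kfold', k) / 'kfold:k'."""
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    if isinstance(cv, tuple) and cv[0] == "kfold":
        k = int(cv[1])
    elif isinstance(cv, str) and cv.startswith("kfold"):
        k = int(cv.split(":")[1]) if ":" in cv else 5
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")
    if not 2 <= k <= n:
        raise ValueError(f"kfold k={k} invalid for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def _scheme_name(cv) -> str:
    if cv == "loo":
        return "loo"
    if isinstance(cv, tuple):
        return f"kfold:{cv[1]}"
    return str(cv)


def max_allowed_lv(n: int, p: int, cv: str | tuple = "loo") -> int:
    """Largest LV count usable with ``rmsecv`` given n samples, p variables."""
    if cv == "loo":
        biggest_fold = 1
    else:
        k = int(cv[1]) if isinstance(cv, tuple) else (
            int(cv.split(":")[1]) if ":" in str(cv) else 5)
        biggest_fold = int(np.ceil(n / k))
    return max(1, min(p, n - biggest_fold - 1))


def rmsecv(X: np.ndarray, y: np.ndarray, max_lv: int, cv: str | tuple = "loo",
           seed: int = 0) -> CVResult:
    """Cross-validated RMSE for every LV count 1..max_lv.

    For each fold a single ``max_lv``-component model is fitted on the training
    part and its cumulative regression vectors predict the held-out samples for
    all LV counts at once. ``chosen_lv`` is the first minimum (parsimony on
    ties). ``seed`` only shuffles k-fold assignment; LOO is deterministic.
    """
    X, y = _check_Xy(X, y)
    n, p = X.shape
    folds = _folds(n, cv, seed)
    min_train = n - max(f.size for f in folds)
    if not 1 <= max_lv <= min(min_train - 1, p):
        raise ValueError(
            f"max_lv={max_lv} out of bounds [1, {min(min_train - 1, p)}] for the smallest fold"
        )
    sse = np.zeros(max_lv)
    mask = np.ones(n, dtype=bool)
    for val in folds:
        mask[:] = True
        mask[val] = False
        Xtr, ytr = X[mask], y[mask]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        yc = ytr - ym
        if np.allclose(yc, 0.0):
            pred = np.full((val.size, max_lv), ym)
        else:
            B, *_ = _coef_paths(Xtr - xm, yc, max_lv)
            pred = (X[val] - xm) @ B + ym
        sse += ((pred - y[val, None]) ** 2).sum(axis=0)
    curve = np.sqrt(sse / n)
    chosen = int(np.argmin(curve)) + 1  # argmin returns the first minimum
    return CVResult(rmsecv_by_lv=curve, chosen_lv=chosen, cv_scheme=_scheme_name(cv))


# -- calibration / prediction split --------------------------------------


def split_indices(n: int, ratio: str = "3:1", seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint calibration/prediction index split at ``ratio`` (e.g. '3:1')."""
    try:
        c, p = (int(t) for t in ratio.split(":"))
    except Exception as exc:
        raise ValueError(f"ratio {ratio!r} must look like '3:1'") from exc
    if c <= 0 or p <= 0:
        raise ValueError("ratio parts must be positive integers")
    if n < c + p:
        raise ValueError(f"n={n} too small for a {ratio} split")
    n_pred = int(round(n * p / (c + p)))
    n_pred = min(max(n_pred, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_pred:]), np.sort(perm[:n_pred])


def split_calibration_prediction(sset: SpectrumSet, ref: ReferenceTable,
                                 ratio: str = "3:1", seed: int = 0):
    """Split a SpectrumSet + ReferenceTable into (cal_set, cal_ref, pred_set, pred_ref)."""
    if sset.n_samples != len(ref):
        raise ValueError("spectra and reference table sizes differ")
    cal_idx, pred_idx = split_indices(sset.n_samples, ratio, seed)
    step_c = f"split(ratio={ratio},seed={seed},part=calibration)"
    step_p = f"split(ratio={ratio},seed={seed},part=prediction)"
    return (
        sset.select_samples(cal_idx, step_c),
        ref.select_samples(cal_idx),
        sset.select_samples(pred_idx, step_p),
        ref.select_samples(pred_idx),
    )


def format_metrics_table(rows: Sequence[dict]) -> str:
    """Human-readable table in the LVs | Rc | RMSEC | Rp | RMSEP layout."""
    header = f"{'Model':<28}{'Vars':>6}{'LVs':>5}{'Rc':>8}{'RMSEC(%)':>10}{'Rp':>8}{'RMSEP(%)':>10}"
    lines = [header, "-" * len(header)]
    for row in rows:
        lines.append(
            f"{row['model']:<28}{row['n_variables']:>6}{row['n_lv']:>5}"
            f"{row['Rc']:>8.3f}{row['RMSEC']:>10.3f}{row['Rp']:>8.3f}{row['RMSEP']:>10.3f}"
        )
    return "\n".join(lines)
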