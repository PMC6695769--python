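"""Latent-variable chemometrics: PCA outlier screening and PLS calibration.

The modelling protocol mirrors standard spectroscopic calibration practice:

* the block-averaged, preprocessed spectra and their reference chemistry
  form a :class:`CalibrationDataset` (one sample per block × date);
* samples are screened with PCA Q residuals and Hotelling T² at a joint
  99% criterion (a sample is anomalous only when *both* statistics exceed
  their limits);
* the dataset is split 80/20 into calibration and external-validation sets
  by a response-stratified random draw so both sets cover the full
  concentration range;
* a PLS model (NIPALS, univariate response, X deflation) is trained per
  analyte; the latent-variable count is chosen by 10-fold venetian-blinds
  cross-validation as the smallest count reaching the minimum RMSECV;
* calibration, cross-validation and prediction performance are reported as
  RMSE and R² per set.

X is mean-centered only (no autoscaling): all channels share absorbance
units, so variance scaling would only amplify noise channels.  R² is
computed as explained variance, ``1 - SSE/SST`` about the evaluated set's
own mean; ``r2_mode="corr"`` switches to squared Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.99
DEFAULT_VARIANCE_CAPTURE = 0.95


@dataclass
class CalibrationDataset:
    """Preprocessed sample matrix paired with per-analyte responses.

    ``X`` rows are block × date samples in acquisition-table order
    (block-major, date-minor); ``y`` maps analyte name to its response
    vector.  ``split_labels`` holds ``"calibration"`` / ``"validation"``
    per sample once :func:`split_dataset` has run.
    """

    X: np.ndarray
    y: dict[str, np.ndarray]
    block_ids: list[str]
    date_indices: np.ndarray
    split_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        n = self.X.shape[0]
        for name, vec in self.y.items():
            self.y[name] = np.asarray(vec, dtype=float)
            if self.y[name].size != n:
                raise ValueError(f"response {name} has wrong length")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def calibration_mask(self) -> np.ndarray:
        if self.split_labels is None:
            raise ValueError("dataset has not been split")
        return self.split_labels == "calibration"


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(
    y: np.ndarray, calibration_fraction: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Response-stratified calibration/validation split labels.

    The calibration set holds ``ceil(fraction * n)`` samples.  Samples are
    ranked by the response; the ranked order is cut into ``n - cal`` nearly
    equal consecutive bins and one random sample per bin goes to
    validation, so both sets span the full response range.  The global
    response extremes stay in calibration whenever their bin offers an
    alternative, so the model is never asked to extrapolate.  Deterministic
    under ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_cal = int(np.ceil(calibration_fraction * n))
    n_val = n - n_cal
    labels = np.full(n, "calibration", dtype=object)
    if n_val == 0:
        return labels.astype(str)
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    # n_val consecutive rank bins of near-equal size
    bounds = np.linspace(0, n, n_val + 1).round().astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ranks = np.arange(lo, hi)
        inner = ranks[(ranks != 0) & (ranks != n - 1)]
        pool = inner if inner.size else ranks
        pick = order[pool[rng.integers(pool.size)]]
        labels[pick] = "validation"
    return labels.astype(str)


# ---------------------------------------------------------------------------
# PCA and outlier statistics


@dataclass
class PCAModel:
    """Mean-centered PCA with Q / T² control limits."""

    mean: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), non-increasing; covariance eigenvalues
    all_eigenvalues: np.ndarray  # full spectrum, for Q limits
    n_samples: int
    alpha: float = DEFAULT_ALPHA
    q_limit: float = field(default=np.nan)
    t2_limit: float = field(default=np.nan)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component mean-centered PCA by singular value decomposition.

    Eigenvalues are those of the sample covariance (``ddof=1``).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for shape {X.shape}")
    mean = X.mean(axis=0)
    xc = X - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    return PCAModel(
        mean=mean,
        loadings=vt[:k].T,
        eigenvalues=eig[:k],
        all_eigenvalues=eig,
        n_samples=n,
    )


def q_statistic(x: np.ndarray, pca: PCAModel) -> np.ndarray | float:
    """Squared residual distance from the PCA subspace (SPE)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xc = np.atleast_2d(x) - pca.mean
    resid = xc - (xc @ pca.loadings) @ pca.loadings.T
    q = np.sum(resid**2, axis=1)
    return float(q[0]) if single else q


def t2_statistic(x: np.ndarray, pca: PCAModel) -> np.ndarray | float:
    """Hotelling T²: Mahalanobis distance within the PCA subspace."""
    if np.any(pca.eigenvalues <= 0):
        raise ValueError("T² undefined: zero eigenvalue among retained components")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    t = (np.atleast_2d(x) - pca.mean) @ pca.loadings
    t2 = np.sum(t**2 / pca.eigenvalues, axis=1)
    return float(t2[0]) if single else t2


def control_limits(pca: PCAModel, alpha: float = DEFAULT_ALPHA) -> tuple[float, float]:
    """(Q, T²) control limits at confidence ``alpha``.

    T² limit: ``k (n-1) / (n-k) · F_alpha(k, n-k)``.  Q limit: the
    Jackson–Mudholkar normal approximation built from the eigenvalues left
    out of the model.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n, k = pca.n_samples, pca.k
    if n <= k:
        raise ValueError("need more samples than components for limits")
    t2_limit = k * (n - 1) / (n - k) * stats.f.ppf(alpha, k, n - k)

    trailing = pca.all_eigenvalues[k:]
    trailing = trailing[trailing > 0]
    if trailing.size == 0:
        q_limit = 0.0
    else:
        th1 = trailing.sum()
        th2 = np.sum(trailing**2)
        th3 = np.sum(trailing**3)
        h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
        if h0 <= 0:
            h0 = 1e-4  # Jackson–Mudholkar safeguard for extreme spectra
        z = stats.norm.ppf(alpha)
        term = (
            z * np.sqrt(2.0 * th2 * h0**2) / th1
            + 1.0
            + th2 * h0 * (h0 - 1.0) / th1**2
        )
        q_limit = th1 * term ** (1.0 / h0)
    return float(q_limit), float(t2_limit)


def detect_outliers(
    X: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    variance_capture: float = DEFAULT_VARIANCE_CAPTURE,
    k: int | None = None,
    extreme_factor: float = 10.0,
) -> tuple[np.ndarray, PCAModel | None]:
    """Flag atypical spectra with the joint Q ∧ T² rule.

    The component count is the smallest capturing at least
    ``variance_capture`` of the variance (unless ``k`` is given).  A sample
    is flagged when both its Q residual and its T² exceed the ``alpha``
    limits — a conservative single-pass rule — or when either statistic
    alone exceeds ``extreme_factor`` times its limit.  The second clause
    guards against gross anomalies (e.g. an amplitude spike) that inflate
    a principal component of their own and therefore show an extreme T²
    with an unremarkable residual, which the joint rule cannot see.
    Returns the flag vector and the fitted PCA (``None`` for degenerate
    inputs).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        warnings.warn("too few samples for outlier screening; no flags raised")
        return np.zeros(n, dtype=bool), None
    full = pca_fit(X, min(n - 1, p))
    total = full.all_eigenvalues.sum()
    if total == 0:
        warnings.warn("zero-variance matrix; no flags raised")
        return np.zeros(n, dtype=bool), None
    if k is None:
        frac = np.cumsum(full.all_eigenvalues) / total
        k = int(np.searchsorted(frac, variance_capture) + 1)
        k = min(k, full.all_eigenvalues.size)
    pca = pca_fit(X, k)
    q_limit, t2_limit = control_limits(pca, alpha)
    pca.alpha = alpha
    pca.q_limit, pca.t2_limit = q_limit, t2_limit
    q = q_statistic(X, pca)
    t2 = t2_statistic(X, pca)
    if q_limit <= 0:  # model captured everything; Q carries no information
        flags = t2 > t2_limit
    else:
        flags = (q > q_limit) & (t2 > t2_limit)
        flags |= q > extreme_factor * q_limit
        flags |= t2 > extreme_factor * t2_limit
    return np.asarray(flags, dtype=bool), pca


# ---------------------------------------------------------------------------
# PLS (NIPALS, univariate response)


@dataclass
class PLSModel:
    """A fitted PLS1 regression model.

    Prediction is ``ŷ = ȳ + (x - x̄)ᵀ b`` with the regression vector
    ``b = W (PᵀW)⁻¹ q`` assembled from the NIPALS weights ``W``,
    X-loadings ``P`` and y-loadings ``q``.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k)
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    coef: np.ndarray  # (p,)
    n_lv: int
    treatment: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray | float:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        yhat = self.y_mean + (np.atleast_2d(X) - self.x_mean) @ self.coef
        return float(yhat[0]) if single else yhat


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by sequential NIPALS extraction with X deflation.

    Each latent variable's weight vector is the (normalised) covariance
    direction ``Xᵀy``; scores, loadings and the response loading follow,
    then X is deflated by the rank-one score/loading product.  The
    procedure is fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} out of range for shape {X.shape}")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    e = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # X exhausted: remaining LVs carry nothing
            W, P, q = W[:, : a or 1], P[:, : a or 1], q[: a or 1]
            n_lv = max(a, 1)
            break
        w /= norm
        t = e @ w
        tt = float(t @ t)
        p_a = e.T @ t / tt
        q_a = float(f @ t) / tt
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        e = e - np.outer(t, p_a)
        f = f - q_a * t
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
        y_loadings=q, coef=coef, n_lv=n_lv,
    )


# ---------------------------------------------------------------------------
# cross-validation


def venetian_blinds_folds(n: int, n_folds: int = 10) -> np.ndarray:
    """Interleaved fold labels: sample ``i`` goes to fold ``i mod n_folds``.

    Fold sizes differ by at most one; the assignment depends on dataset
    order, which is the intended behaviour of the venetian-blinds scheme.
    """
    if n < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n} samples")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    return np.arange(n) % n_folds


@dataclass
class CVResult:
    """RMSECV per latent-variable count and the selected count."""

    rmsecv: np.ndarray  # (max_lv,), index a -> a+1 latent variables
    cv_predictions: np.ndarray  # (n,) pooled held-out ŷ at the selected LV
    n_lv: int


def cross_validate(
    X: np.ndarray, y: np.ndarray, max_lv: int = 15, n_folds: int = 10
) -> CVResult:
    """Venetian-blinds cross-validation over latent-variable counts.

    For each count, every fold is predicted by a model fitted on its
    complement; RMSECV pools all held-out predictions.  The selected count
    is the smallest one attaining the minimum RMSECV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    folds = venetian_blinds_folds(n, n_folds)
    min_train = min(np.sum(folds != f) for f in range(n_folds))
    max_lv = int(min(max_lv, min_train - 1, X.shape[1]))
    if max_lv < 1:
        raise ValueError("folds too small for even one latent variable")
    preds = np.zeros((max_lv, n))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        model = pls_fit(X[train], y[train], max_lv)
        # nested models: rebuild the coefficient for every truncation
        for a in range(1, max_lv + 1):
            Wa, Pa, qa = model.weights[:, :a], model.x_loadings[:, :a], \
                model.y_loadings[:a]
            coef = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
            preds[a - 1, test] = model.y_mean + (X[test] - model.x_mean) @ coef
    rmsecv = np.sqrt(np.mean((preds - y[None, :]) ** 2, axis=1))
    n_lv = int(np.argmin(rmsecv)) + 1
    return CVResult(rmsecv=rmsecv, cv_predictions=preds[n_lv - 1], n_lv=n_lv)


# ---------------------------------------------------------------------------
# model statistics


@dataclass
class ModelStats:
    """The per-analyte performance row of a calibration report."""

    analyte: str
    treatment: str
    n_calibration: int
    n_validation: int
    sd_reference: float
    range_reference: tuple[float, float]
    n_lv: int
    rmsec: float
    r2_c: float
    rmsecv: float
    r2_cv: float
    rmsep: float
    r2_p: float


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray, mode: str = "explained") -> float:
    """Determination coefficient on one evaluation set.

    ``"explained"``: ``1 - SSE / SST`` about the set's own mean (can go
    negative for models worse than the mean).  ``"corr"``: squared Pearson
    correlation of ``y`` and ``ŷ``.
    """
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    if mode == "explained":
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            raise ValueError("R² undefined: reference values are constant")
        return 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    if mode == "corr":
        return float(np.corrcoef(y, yhat)[0, 1] ** 2)
    raise ValueError(f"unknown R² mode {mode!r}")


def model_statistics(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cv: CVResult,
    analyte: str = "",
    r2_mode: str = "explained",
) -> ModelStats:
    """Assemble the calibration / cross-validation / prediction statistics."""
    yhat_cal = model.predict(X_cal)
    yhat_val = model.predict(X_val)
    y_all = np.concatenate([y_cal, y_val])
    return ModelStats(
        analyte=analyte,
        treatment=model.treatment,
        n_calibration=int(len(y_cal)),
        n_validation=int(len(y_val)),
        sd_reference=float(np.std(y_cal, ddof=1)),
        range_reference=(float(y_all.min()), float(y_all.max())),
        n_lv=model.n_lv,
        rmsec=rmse(y_cal, yhat_cal),
        r2_c=r_squared(y_cal, yhat_cal, r2_mode),
        rmsecv=rmse(y_cal, cv.cv_predictions),
        r2_cv=r_squared(y_cal, cv.cv_predictions, r2_mode),
        rmsep=rmse(y_val, yhat_val),
        r2_p=r_squared(y_val, yhat_val, r2_mode),
    )


def train_analyte(
    dataset: CalibrationDataset,
    analyte: str,
    treatment: str = "",
    calibration_fraction: float = 0.8,
    n_folds: int = 10,
    max_lv: int = 15,
    seed: int = 0,
    r2_mode: str = "explained",
) -> tuple[PLSModel, ModelStats, CVResult]:
    """End-to-end calibration of one analyte on a preprocessed dataset.

    Splits (stratified on this analyte's response), cross-validates to pick
    the latent-variable count, refits on the full calibration set and
    reports the statistics row.
    """
    y = dataset.y[analyte]
    labels = split_dataset(y, calibration_fraction, seed)
    dataset.split_labels = labels
    cal = labels == "calibration"
    X_cal, y_cal = dataset.X[cal], y[cal]
    X_val, y_val = dataset.X[~cal], y[~cal]
    cv = cross_validate(X_cal, y_cal, max_lv=max_lv, n_folds=n_folds)
    model = pls_fit(X_cal, y_cal, cv.n_lv)
    model.treatment = treatment
    statistics = model_statistics(
        model, X_cal, y_cal, X_val, y_val, cv, analyte=analyte, r2_mode=r2_mode
    )
    return model, statistics, cv
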