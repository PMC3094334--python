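"""PLS1 calibration, cross-validation and validation descriptors.

The decomposition is NIPALS PLS1 on mean-centred spectra and trait values:
each factor extracts the weight direction w = X'y/||X'y||, scores t = Xw,
X-loading p = X't/t't and y-loading q = t'y/t't, then deflates X and y.
Regression vectors for every truncation k are reconstructed via the
R = W (P'W)^{-1} recursion, so one fit serves all factor counts.

Leave-one-out cross-validation is a literal refit: the left-out sample
never touches the fold's centring means or decomposition.  The fold loop is
vectorised (all n folds advance one factor per step via einsum), which is
algebraically identical to deleting a row and refitting — a property pinned
by an explicit naive-loop oracle in the test suite.

Descriptor conventions (all reported in trait units):

* RMSEC  — in-sample RMSE, divisor n (configurable to n-k-1);
* RMSECV — leave-one-out RMSE, divisor n;
* RMSEP  — RMSE on an independent validation set after excluding
  predictions outside the calibration range;
* R²(calibration) and R²(cv) — 1 - SSE/TSS;
* R²(validation) — squared Pearson correlation of measured vs predicted
  (the best-fit-line convention); the 1 - PRESS/TSS form is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocessing import PreprocessConfig, apply_pipeline
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "select_factors",
    "loo_cv",
    "calibration_metrics",
    "training_residual_variance",
    "predict",
    "external_validate",
    "calibrate",
]

DEFAULT_MAX_FACTORS = 16
FACTOR_SELECT_THRESHOLD = 0.02


# ---------------------------------------------------------------------------
# Core NIPALS machinery (single fit)
# ---------------------------------------------------------------------------


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, k_max: int):
    """NIPALS PLS1 on pre-centred data.

    Returns (W, P, q, T): weights p×K, X-loadings p×K, y-loadings K,
    scores n×K.  Stops early if a deflated X'y vanishes.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    T = np.zeros((n, k_max))
    k_eff = 0
    nw0 = None
    for k in range(k_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0.0 or (nw0 is not None and nw < 1e-14 * nw0):
            break  # residual covariance exhausted
        if nw0 is None:
            nw0 = nw
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        pl = (X.T @ t) / tt
        qk = float(t @ y) / tt
        X -= np.outer(t, pl)
        y = y - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pl, qk, t
        k_eff = k + 1
    return W[:, :k_eff], P[:, :k_eff], q[:k_eff], T[:, :k_eff]


def _regression_vectors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Coefficient matrix B (p×K): column k-1 uses the first k factors.

    Uses the recursion r_k = w_k - sum_{j<k} (p_j·w_k) r_j, i.e.
    R = W (P'W)^{-1} built column by column; B_k = R_k q_k.
    """
    p, K = W.shape
    R = np.zeros((p, K))
    B = np.zeros((p, K))
    acc = np.zeros(p)
    for k in range(K):
        r = W[:, k] - R[:, :k] @ (P[:, :k].T @ W[:, k])
        R[:, k] = r
        acc = acc + q[k] * r
        B[:, k] = acc
    return B


@dataclass
class PLSModel:
    """Fitted mean-centred PLS1 model plus the recipe to apply it.

    ``regression_vectors[:, k-1]`` are the coefficients (on centred
    spectra) using the first k factors; ``chosen_factors`` selects the
    column used by :func:`predict`.
    """

    mean_spectrum: np.ndarray
    mean_y: float
    weights: np.ndarray  # p × K
    x_loadings: np.ndarray  # p × K
    y_loadings: np.ndarray  # K
    scores: np.ndarray  # n × K
    regression_vectors: np.ndarray  # p × K
    max_factors: int
    chosen_factors: int
    calibration_range: tuple[float, float]
    recipe: PreprocessConfig | None = None
    grid: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_factors_available(self) -> int:
        return self.scores.shape[1]

    def coefficients(self, k: int | None = None) -> np.ndarray:
        k = self.chosen_factors if k is None else k
        if not 1 <= k <= self.n_factors_available:
            raise ValueError(f"k must be in 1..{self.n_factors_available}")
        return self.regression_vectors[:, k - 1]

    def predict_matrix(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Predict from an already-preprocessed n×p matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.mean_y + (X - self.mean_spectrum) @ self.coefficients(k)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "mean_spectrum": self.mean_spectrum.tolist(),
            "mean_y": self.mean_y,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "regression_vectors": self.regression_vectors.tolist(),
            "max_factors": self.max_factors,
            "chosen_factors": self.chosen_factors,
            "calibration_range": list(self.calibration_range),
            "recipe": None if self.recipe is None else self.recipe.to_dict(),
            "grid": None if self.grid is None else self.grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        if d.get("format_version") != 1:
            raise ValueError("unsupported model format version")
        return cls(
            mean_spectrum=np.array(d["mean_spectrum"], float),
            mean_y=float(d["mean_y"]),
            weights=np.array(d["weights"], float),
            x_loadings=np.array(d["x_loadings"], float),
            y_loadings=np.array(d["y_loadings"], float),
            scores=np.array(d["scores"], float),
            regression_vectors=np.array(d["regression_vectors"], float),
            max_factors=int(d["max_factors"]),
            chosen_factors=int(d["chosen_factors"]),
            calibration_range=tuple(d["calibration_range"]),
            recipe=None if d["recipe"] is None else PreprocessConfig.from_dict(d["recipe"]),
            grid=None if d["grid"] is None else np.array(d["grid"], float),
        )


@dataclass
class CVResult:
    """Table-style performance descriptors for one model variant."""

    r2_calibration: float
    r2_cv: float
    rmsec: float
    rmsecv: float
    n_factors: int
    rmsep: float | None = None
    r2_validation: float | None = None
    predictions: list[tuple[float, float]] = field(default_factory=list)
    rmsecv_by_k: np.ndarray | None = None
    r2_cv_by_k: np.ndarray | None = None
    n_excluded: int = 0


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = DEFAULT_MAX_FACTORS,
    recipe: PreprocessConfig | None = None,
    grid: np.ndarray | None = None,
    chosen_factors: int | None = None,
) -> PLSModel:
    """Fit NIPALS PLS1 on raw (uncentred) X, y.

    ``max_factors`` is capped at min(n-1, p); deflation may terminate the
    decomposition earlier if the residual covariance vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 calibration samples")
    if y.size != n:
        raise ValueError("y length must match the number of rows of X")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to calibrate")
    k_max = min(int(max_factors), n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_pls1(X - x_mean, y - y_mean, k_max)
    B = _regression_vectors(W, P, q)
    k_avail = W.shape[1]
    return PLSModel(
        mean_spectrum=x_mean,
        mean_y=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        regression_vectors=B,
        max_factors=k_max,
        chosen_factors=min(chosen_factors or k_avail, k_avail),
        calibration_range=(float(y.min()), float(y.max())),
        recipe=recipe,
        grid=grid,
    )


def select_factors(
    residual_y_variance_by_k: Sequence[float],
    threshold: float = FACTOR_SELECT_THRESHOLD,
    max_factors: int | None = None,
) -> int:
    """Smallest k whose next factor no longer pays its way.

    Scans the residual y-variance after 1..K factors and returns the first k
    for which the relative decrease from k to k+1 falls below ``threshold``;
    if every step keeps reducing variance substantially, returns K (or the
    ``max_factors`` cap).
    """
    v = np.asarray(list(residual_y_variance_by_k), dtype=float)
    if v.size == 0:
        raise ValueError("empty residual-variance sequence")
    cap = v.size if max_factors is None else min(v.size, int(max_factors))
    for k in range(cap - 1):
        prev = v[k]
        if prev <= 0:
            return k + 1
        rel_drop = (prev - v[k + 1]) / prev
        if rel_drop < threshold:
            return k + 1
    return cap


def calibration_metrics(model: PLSModel, X: np.ndarray, y: np.ndarray, k: int | None = None,
                        divisor: str = "n") -> tuple[float, float]:
    """In-sample (R², RMSEC) using k factors (k=0 gives the mean model)."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k == 0:
        pred = np.full(n, model.mean_y)
        k_used = 0
    else:
        pred = model.predict_matrix(X, k)
        k_used = model.chosen_factors if k is None else k
    sse = float(np.sum((pred - y) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    denom = n if divisor == "n" else max(n - k_used - 1, 1)
    return r2, float(np.sqrt(sse / denom))


def training_residual_variance(model: PLSModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual y-variance (SSE_k / TSS) after 1..K factors, in sample."""
    y = np.asarray(y, dtype=float).ravel()
    Xc = np.atleast_2d(np.asarray(X, float)) - model.mean_spectrum
    tss = float(np.sum((y - y.mean()) ** 2))
    out = np.empty(model.n_factors_available)
    for k in range(1, model.n_factors_available + 1):
        pred = model.mean_y + Xc @ model.regression_vectors[:, k - 1]
        out[k - 1] = float(np.sum((pred - y) ** 2)) / tss
    return out


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation (refit per fold, vectorised across folds)
# ---------------------------------------------------------------------------


def _loo_prediction_curves(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """n × k_max matrix: column k-1 holds each sample's LOO prediction
    from a model refit without it, using the first k factors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    k_max = min(k_max, n - 2, p)
    idx = np.arange(n)
    fold_rows = np.array([np.delete(idx, i) for i in range(n)])  # n × (n-1)
    Xf = X[fold_rows]  # n folds × (n-1) × p
    yf = y[fold_rows]  # n × (n-1)
    xbar = Xf.mean(axis=1)  # n × p (per-fold recentring)
    ybar = yf.mean(axis=1)  # n
    Xc = Xf - xbar[:, None, :]
    yc = yf - ybar[:, None]
    xs = X - xbar  # centred left-out sample per fold
    preds = np.empty((n, k_max))
    cum = ybar.copy()
    for k in range(k_max):
        w = np.einsum("fnp,fn->fp", Xc, yc)
        nw = np.linalg.norm(w, axis=1)
        nw[nw == 0] = 1.0  # dead fold: zero weight, predictions freeze
        w /= nw[:, None]
        t = np.einsum("fnp,fp->fn", Xc, w)
        tt = np.einsum("fn,fn->f", t, t)
        tt[tt == 0] = np.inf
        pl = np.einsum("fnp,fn->fp", Xc, t) / tt[:, None]
        q = np.einsum("fn,fn->f", t, yc) / tt
        Xc -= t[:, :, None] * pl[:, None, :]
        yc -= q[:, None] * t
        tstar = np.einsum("fp,fp->f", xs, w)  # left-out score via projection
        xs = xs - tstar[:, None] * pl
        cum = cum + q * tstar
        preds[:, k] = cum
    return preds


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = DEFAULT_MAX_FACTORS,
    factor_choice: str = "min_rmsecv",
    threshold: float = FACTOR_SELECT_THRESHOLD,
) -> CVResult:
    """Leave-one-out cross-validation on a preprocessed matrix.

    Each fold refits the PLS1 decomposition from scratch on the remaining
    n-1 samples (recentring inside the fold) and predicts the held-out one.
    ``factor_choice`` is ``"min_rmsecv"`` (default) or
    ``"residual_variance"`` (the substantial-reduction rule applied to the
    PRESS curve).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("leave-one-out CV needs at least 4 samples")
    preds = _loo_prediction_curves(X, y, max_factors)
    k_avail = preds.shape[1]
    press = np.sum((preds - y[:, None]) ** 2, axis=0)
    tss = float(np.sum((y - y.mean()) ** 2))
    rmsecv_by_k = np.sqrt(press / n)
    r2_cv_by_k = 1.0 - press / tss
    if factor_choice == "min_rmsecv":
        k = int(np.argmin(rmsecv_by_k)) + 1
    elif factor_choice == "residual_variance":
        k = select_factors(press / tss, threshold, k_avail)
    else:
        raise ValueError("factor_choice must be 'min_rmsecv' or 'residual_variance'")
    model = fit_pls(X, y, max_factors=k_avail)
    k = max(1, min(k, model.n_factors_available))
    r2_cal, rmsec = calibration_metrics(model, X, y, k)
    return CVResult(
        r2_calibration=r2_cal,
        r2_cv=float(r2_cv_by_k[k - 1]),
        rmsec=rmsec,
        rmsecv=float(rmsecv_by_k[k - 1]),
        n_factors=k,
        predictions=list(zip(y.tolist(), preds[:, k - 1].tolist())),
        rmsecv_by_k=rmsecv_by_k,
        r2_cv_by_k=r2_cv_by_k,
    )


# ---------------------------------------------------------------------------
# Prediction and external validation through the stored recipe
# ---------------------------------------------------------------------------


def _recipe_matrix(model: PLSModel, spectra: SpectraSet) -> np.ndarray:
    if model.recipe is not None:
        spectra = apply_pipeline(spectra, model.recipe)
    if model.grid is not None and not np.array_equal(spectra.grid, model.grid):
        raise ValueError("spectra grid incompatible with the model's recipe/grid")
    X = spectra.to_matrix()
    if X.shape[1] != model.mean_spectrum.size:
        raise ValueError("preprocessed width does not match the model")
    return X


def predict(model: PLSModel, spectra: SpectraSet) -> list[tuple[str, float, bool]]:
    """Apply the model's recipe and predict each sample.

    Returns (sample_id, value, in_calibration_range) triples; the flag is
    False when the prediction falls outside the training y range, the
    screen used to exclude extrapolated samples from external validation.
    """
    X = _recipe_matrix(model, spectra)
    vals = model.predict_matrix(X)
    lo, hi = model.calibration_range
    return [
        (sid, float(v), bool(lo <= v <= hi))
        for sid, v in zip(spectra.sample_ids, vals)
    ]


def external_validate(
    model: PLSModel,
    spectra: SpectraSet,
    references: ReferenceTable,
    exclude_out_of_range: bool = True,
) -> CVResult:
    """Independent-set validation with out-of-range exclusion.

    Predictions outside the calibration range are excluded (disable with
    ``exclude_out_of_range=False``); RMSEP and the squared Pearson
    correlation of measured vs predicted are computed on the rest.
    """
    triples = predict(model, spectra)
    kept = [(sid, v) for sid, v, ok in triples if ok or not exclude_out_of_range]
    n_excluded = len(triples) - len(kept)
    if not kept:
        raise ValueError("all validation samples were excluded as out of range")
    measured = np.array([references.values[sid] for sid, _ in kept])
    predicted = np.array([v for _, v in kept])
    resid = predicted - measured
    rmsep = float(np.sqrt(np.mean(resid**2)))
    tss = float(np.sum((measured - measured.mean()) ** 2))
    r2_press = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
    if np.ptp(measured) > 0 and np.ptp(predicted) > 0:
        r2_pearson = float(np.corrcoef(measured, predicted)[0, 1] ** 2)
    else:
        r2_pearson = float("nan")
    return CVResult(
        r2_calibration=float("nan"),
        r2_cv=r2_press,
        rmsec=float("nan"),
        rmsecv=float("nan"),
        n_factors=model.chosen_factors,
        rmsep=rmsep,
        r2_validation=r2_pearson,
        predictions=list(zip(measured.tolist(), predicted.tolist())),
        n_excluded=n_excluded,
    )


def calibrate(
    spectra: SpectraSet,
    references: ReferenceTable,
    recipe: PreprocessConfig,
    max_factors: int = DEFAULT_MAX_FACTORS,
    factor_choice: str = "min_rmsecv",
) -> tuple[PLSModel, CVResult]:
    """Preprocess, cross-validate, and fit the final model at the chosen k."""
    pre = apply_pipeline(spectra, recipe)
    X = pre.to_matrix()
    y = references.aligned_to(spectra.sample_ids)
    cv = loo_cv(X, y, max_factors=max_factors, factor_choice=factor_choice)
    model = fit_pls(
        X, y, max_factors=max_factors, recipe=recipe, grid=pre.grid,
        chosen_factors=cv.n_factors,
    )
    return model, cv
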