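"""Wavenumber-region search, preprocessing grid search, outlier screening.

The automatic region search tiles a search window (default 2000-700 cm^-1)
into fixed-width subregions (default 112 cm^-1, the width of the intervals
a QUANT-style search returns) and evaluates every combination of up to
``max_combination`` tiles by leave-one-out RMSECV under a fixed
preprocessing recipe.  Shape transforms are applied once on the full grid;
candidates differ only in the columns kept, so the 231-candidate default
search is a column-selection loop around the vectorised LOO engine.

Spectral outliers are screened by Mahalanobis distance in whitened PLS
score space, flagged against Limit = (Factor × Rank) / M with Factor = 5 by
default (M = number of calibration samples, Rank = PLS factors used).  The
full-spectrum covariance is singular for p >> n, so score space is the only
well-posed metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocessing import PreprocessConfig, RegionSet, apply_pipeline, restrict
from .pls_regression import CVResult, PLSModel, fit_pls, loo_cv
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "RegionSearchSpec",
    "CalibrationReport",
    "OutlierScreen",
    "enumerate_region_candidates",
    "auto_select_regions",
    "grid_search",
    "mahalanobis_screen",
    "iterative_outlier_removal",
]

DEFAULT_OUTLIER_FACTOR = 5.0


@dataclass(frozen=True)
class RegionSearchSpec:
    """Search window, tile width (cm^-1) and combination cap."""

    window: tuple[float, float] = (2000.0, 700.0)
    subregion_width: float = 112.0
    max_combination: int = 3
    factor_cap: int = 12

    def __post_init__(self) -> None:
        hi, lo = max(self.window), min(self.window)
        object.__setattr__(self, "window", (float(hi), float(lo)))
        if hi - lo < self.subregion_width:
            raise ValueError("window narrower than one subregion")
        if self.max_combination < 1:
            raise ValueError("max_combination must be >= 1")


def enumerate_region_candidates(spec: RegionSearchSpec) -> list[RegionSet]:
    """All combinations of 1..max_combination full-width tiles.

    Tiles are laid contiguously from the high edge of the window; a short
    remainder at the low edge is discarded (only full-width tiles enter the
    candidate set).  Order is deterministic: combination size ascending,
    then lexicographic by descending high edges.
    """
    hi, lo = spec.window
    w = spec.subregion_width
    n_tiles = int(np.floor((hi - lo) / w + 1e-9))
    tiles = [(hi - i * w, hi - (i + 1) * w) for i in range(n_tiles)]
    if not tiles:
        raise ValueError("window narrower than one tile")
    out: list[RegionSet] = []
    for r in range(1, spec.max_combination + 1):
        for combo in itertools.combinations(tiles, r):
            out.append(RegionSet(tuple(combo)))
    return out


@dataclass
class CalibrationReport:
    """Descriptor grid over (preprocessing variant, region variant) cells."""

    rows: dict[str, CVResult] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)

    def add(self, name: str, result: CVResult) -> None:
        if name in self.rows:
            raise ValueError(f"variant {name!r} already present")
        self.rows[name] = result
        self.order.append(name)

    def to_frame(self) -> pd.DataFrame:
        """Table-style grid: descriptor rows × variant columns."""
        descriptors = [
            "R2 (calibration)",
            "R2 (cross-validation)",
            "RMSEC",
            "RMSECV",
            "RMSEP",
            "No. of PLS factors",
        ]
        data = {}
        for name in self.order:
            r = self.rows[name]
            data[name] = [
                r.r2_calibration,
                r.r2_cv,
                r.rmsec,
                r.rmsecv,
                r.rmsep if r.rmsep is not None else np.nan,
                r.n_factors,
            ]
        return pd.DataFrame(data, index=descriptors)


@dataclass
class OutlierScreen:
    """Mahalanobis distances, the (factor × rank)/m limit, and flags."""

    distances: np.ndarray
    limit: float
    factor: float
    rank: int
    m: int
    flags: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _press_se(cv: CVResult) -> float:
    """Standard error of the candidate's CV mean squared error."""
    e2 = np.array([(p - m) ** 2 for m, p in cv.predictions])
    n = e2.size
    return float(e2.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def auto_select_regions(
    spectra: SpectraSet,
    references: ReferenceTable,
    preprocess: PreprocessConfig,
    spec: RegionSearchSpec = RegionSearchSpec(),
    factor_choice: str = "min_rmsecv",
    parsimony: str = "1se",
    log=None,
) -> tuple[RegionSet, CVResult]:
    """Pick the tile combination minimising leave-one-out RMSECV.

    ``preprocess.region`` is ignored; shape transforms run once on the full
    grid and every candidate is a column restriction of that matrix.

    CV errors of neighbouring candidates are statistically tied far more
    often than exactly equal, so with ``parsimony="1se"`` (default) the
    winner is the most parsimonious candidate whose mean squared CV error
    lies within one standard error of the global minimum — the classic
    one-SE rule — ordered by fewer tiles, then lower RMSECV, then fewer
    PLS factors, then highest-wavenumber-first.  ``parsimony="none"``
    takes the exact minimiser with the same tie-break order.
    """
    if parsimony not in ("1se", "none"):
        raise ValueError("parsimony must be '1se' or 'none'")
    base = replace(preprocess, region=None)
    pre = apply_pipeline(spectra, base)
    y = references.aligned_to(spectra.sample_ids)
    evaluated: list[tuple[RegionSet, CVResult]] = []
    for region in enumerate_region_candidates(spec):
        sub = restrict(pre, region)
        cv = loo_cv(sub.to_matrix(), y, max_factors=spec.factor_cap,
                    factor_choice=factor_choice)
        if log is not None:
            log(region, cv)
        evaluated.append((region, cv))

    def lex(region: RegionSet) -> tuple:
        return tuple(-hi for hi, _ in region.intervals)

    mses = np.array([cv.rmsecv**2 for _, cv in evaluated])
    i_min = int(np.argmin(mses))
    if parsimony == "1se":
        threshold = mses[i_min] + _press_se(evaluated[i_min][1])
        pool = [(r, cv) for (r, cv), mse in zip(evaluated, mses) if mse <= threshold]
    else:
        pool = evaluated
    best_region, best_cv = min(
        pool,
        key=lambda rc: (
            len(rc[0].intervals), rc[1].rmsecv, rc[1].n_factors, lex(rc[0])
        ) if parsimony == "1se" else (
            rc[1].rmsecv, rc[1].n_factors, len(rc[0].intervals), lex(rc[0])
        ),
    )
    return best_region, best_cv


def grid_search(
    spectra: SpectraSet,
    references: ReferenceTable,
    variants: Sequence[tuple[str, PreprocessConfig]],
    max_factors: int = 16,
    factor_choice: str = "min_rmsecv",
) -> CalibrationReport:
    """Evaluate each named preprocessing×region variant by LOO CV."""
    if not variants:
        raise ValueError("need at least one variant")
    y = references.aligned_to(spectra.sample_ids)
    report = CalibrationReport()
    for name, cfg in variants:
        X = apply_pipeline(spectra, cfg).to_matrix()
        report.add(name, loo_cv(X, y, max_factors=max_factors, factor_choice=factor_choice))
    return report


def mahalanobis_screen(
    model: PLSModel,
    X: np.ndarray | None = None,
    factor: float = DEFAULT_OUTLIER_FACTOR,
    rank: int | None = None,
) -> OutlierScreen:
    """Mahalanobis distances in whitened PLS score space.

    With calibration scores T (m × rank), the squared distance of a sample
    with scores t is (1/m) Σ_k t_k² / var_k where var_k = Σ_i T_ik² / m —
    equivalently t' (T'T)^{-1} t, so the calibration distances average
    rank/m.  A sample is flagged when its distance exceeds
    Limit = (factor × rank) / m.  ``X`` (already preprocessed, centred by
    the model's mean internally) screens new samples; ``None`` screens the
    calibration set itself.
    """
    rank = model.chosen_factors if rank is None else int(rank)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    T = model.scores[:, :rank]
    m = T.shape[0]
    ss = np.einsum("ik,ik->k", T, T)  # per-factor score sum of squares
    if np.any(ss <= 0):
        raise ValueError("singular score covariance (dead factor)")
    if X is None:
        scores = T
    else:
        Xc = np.atleast_2d(np.asarray(X, float)) - model.mean_spectrum
        # NIPALS projection with deflation
        scores = np.empty((Xc.shape[0], rank))
        R = Xc.copy()
        for k in range(rank):
            tk = R @ model.weights[:, k]
            R -= np.outer(tk, model.x_loadings[:, k])
            scores[:, k] = tk
    d = np.einsum("ik,k->i", scores**2, 1.0 / ss)
    limit = factor * rank / m
    return OutlierScreen(
        distances=d, limit=float(limit), factor=float(factor), rank=rank, m=m,
        flags=d > limit,
    )


def iterative_outlier_removal(
    spectra: SpectraSet,
    references: ReferenceTable,
    recipe: PreprocessConfig,
    factor: float = DEFAULT_OUTLIER_FACTOR,
    max_rounds: int = 5,
    max_factors: int = 16,
    max_removed_fraction: float = 0.5,
    drop: str = "worst",
) -> tuple[list[int], list[OutlierScreen]]:
    """Alternate fit → screen → drop until no sample is flagged.

    The screening rank is min(max_factors, ⌊(m−1)/factor⌋): a sample's
    whitened squared distance cannot exceed ~1 however extreme it is (it
    can at most dominate its own factors), so the (factor × rank)/m limit
    flags nothing once it passes 1 — the screen therefore uses the largest
    score subspace for which the limit stays below that bound, maximising
    sensitivity to artifacts in any spectral direction.

    ``drop="worst"`` (default) removes only the most distant flagged sample
    per round before refitting — backward deletion, which keeps a gross
    outlier from distorting the subspace under which its neighbours are
    judged.  ``drop="all"`` removes every flagged sample each round.
    Returns the surviving indices (into the input set) and the screen
    history; aborts if more than half of the samples would be removed.
    """
    if drop not in ("worst", "all"):
        raise ValueError("drop must be 'worst' or 'all'")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    pre = apply_pipeline(spectra, recipe)
    X_all = pre.to_matrix()
    y_all = references.aligned_to(spectra.sample_ids)
    kept = list(range(len(spectra)))
    history: list[OutlierScreen] = []
    for _ in range(max_rounds):
        X, y = X_all[kept], y_all[kept]
        model = fit_pls(X, y, max_factors=max_factors)
        rank = max(1, min(model.n_factors_available, int((len(kept) - 1) // factor)))
        screen = mahalanobis_screen(model, None, factor=factor, rank=rank)
        history.append(screen)
        if not screen.flags.any():
            break
        if drop == "worst":
            worst = int(np.argmax(screen.distances))
            kept = [i for j, i in enumerate(kept) if j != worst]
        else:
            kept = [i for i, flagged in zip(kept, screen.flags) if not flagged]
        if len(kept) < (1 - max_removed_fraction) * len(spectra):
            raise RuntimeError("outlier screening removed more than half the samples")
    return kept, history
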