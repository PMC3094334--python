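"""Deterministic spectral transforms applied before modelling.

The menu mirrors common FTIR-ATR chemometric practice: ATR penetration-depth
rescaling, rubberband (lower convex hull) baseline subtraction, vector
normalisation, Savitzky-Golay first derivative, and restriction to a set of
wavenumber intervals.  All operators are deterministic and invariant to the
orientation of the stored grid; shape transforms run on the full contiguous
grid, region restriction always comes last (derivatives and hulls need
contiguous support, and the restriction defines the "active region" of the
downstream mean-centring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet, Spectrum

__all__ = [
    "RegionSet",
    "PreprocessConfig",
    "FULL_REGION",
    "atr_correction",
    "rubberband_baseline",
    "vector_normalize",
    "first_derivative",
    "restrict",
    "apply_pipeline",
]

_STEP_NAMES = ("atr_correction", "rubberband_baseline", "vector_normalize", "first_derivative")


@dataclass(frozen=True)
class RegionSet:
    """Ordered, non-overlapping closed wavenumber intervals [high, low] cm^-1."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            hi, lo = float(max(iv)), float(min(iv))
            if not hi > lo:
                raise ValueError(f"degenerate interval {iv}")
            norm.append((hi, lo))
        norm.sort(key=lambda iv: -iv[0])
        for (hi1, lo1), (hi2, lo2) in zip(norm, norm[1:]):
            if hi2 > lo1:
                raise ValueError("intervals overlap")
        object.__setattr__(self, "intervals", tuple(norm))

    def mask(self, grid: np.ndarray) -> np.ndarray:
        """Boolean membership of grid points (closed intervals)."""
        grid = np.asarray(grid, dtype=float)
        m = np.zeros(grid.shape, dtype=bool)
        for hi, lo in self.intervals:
            m |= (grid >= lo) & (grid <= hi)
        return m

    @property
    def width(self) -> float:
        return sum(hi - lo for hi, lo in self.intervals)


#: Sentinel meaning "no restriction".
FULL_REGION: RegionSet | None = None


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered preprocessing recipe.

    ``steps`` is an ordered subset of {atr_correction, rubberband_baseline,
    vector_normalize, first_derivative}; order matters (derivative and
    normalisation do not commute).  ``region`` restricts the grid after all
    shape transforms; ``None`` keeps the full grid.
    """

    steps: tuple[str, ...] = ()
    derivative_window: int = 9
    derivative_polyorder: int = 2
    region: RegionSet | None = None
    atr_reference_wavenumber: float = 1000.0
    vector_norm_mode: str = "center_unit"  # or "unit"

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        for s in steps:
            if s not in _STEP_NAMES:
                raise ValueError(f"unknown preprocessing step {s!r}")
        if self.derivative_window % 2 == 0:
            raise ValueError("derivative_window must be odd")
        if self.derivative_polyorder >= self.derivative_window:
            raise ValueError("derivative_polyorder must be < derivative_window")
        object.__setattr__(self, "steps", steps)

    def label(self) -> str:
        base = "+".join(self.steps) if self.steps else "raw"
        if self.region is not None:
            ivs = ",".join(f"{hi:g}-{lo:g}" for hi, lo in self.region.intervals)
            base += f"|{ivs}"
        return base

    def to_dict(self) -> dict:
        return {
            "steps": list(self.steps),
            "derivative_window": self.derivative_window,
            "derivative_polyorder": self.derivative_polyorder,
            "region": None if self.region is None else [list(iv) for iv in self.region.intervals],
            "atr_reference_wavenumber": self.atr_reference_wavenumber,
            "vector_norm_mode": self.vector_norm_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        region = d.get("region")
        return cls(
            steps=tuple(d.get("steps", ())),
            derivative_window=int(d.get("derivative_window", 9)),
            derivative_polyorder=int(d.get("derivative_polyorder", 2)),
            region=None if region is None else RegionSet(tuple(tuple(iv) for iv in region)),
            atr_reference_wavenumber=float(d.get("atr_reference_wavenumber", 1000.0)),
            vector_norm_mode=d.get("vector_norm_mode", "center_unit"),
        )


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def atr_correction(spectrum: Spectrum, reference_wavenumber: float = 1000.0) -> Spectrum:
    """Rescale absorbance by nu/nu_ref.

    ATR effective penetration depth scales ~1/nu, so raw ATR absorbance is
    inflated at low wavenumbers; multiplying by nu/nu_ref flattens that
    dependence relative to the reference wavenumber.  Deliberately not
    idempotent: applying twice squares the factor.
    """
    wn = spectrum.wavenumbers
    if not (wn.min() <= reference_wavenumber <= wn.max()):
        raise ValueError("reference_wavenumber outside the grid range")
    if np.any(wn <= 0):
        raise ValueError("wavenumbers must be positive")
    return spectrum.with_absorbance(
        spectrum.absorbance * (wn / reference_wavenumber), "atr_correction"
    )


def _lower_hull_baseline(x_asc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (x, y) evaluated on x (Andrew monotone chain)."""
    hull_idx = [0]
    for i in range(1, len(x_asc)):
        while len(hull_idx) >= 2:
            i0, i1 = hull_idx[-2], hull_idx[-1]
            # keep turn strictly convex (cross product <= 0 drops i1)
            cross = (x_asc[i1] - x_asc[i0]) * (y[i] - y[i0]) - (x_asc[i] - x_asc[i0]) * (
                y[i1] - y[i0]
            )
            if cross <= 0:
                hull_idx.pop()
            else:
                break
        hull_idx.append(i)
    return np.interp(x_asc, x_asc[hull_idx], y[hull_idx])


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex hull of the spectrum (rubberband baseline).

    The hull is anchored at both end points, so the result is zero there and
    non-negative everywhere, exactly zero at every hull contact point.
    """
    if len(spectrum) < 3:
        raise ValueError("rubberband needs at least 3 points")
    x_asc = spectrum.wavenumbers[::-1]
    y_asc = spectrum.absorbance[::-1]
    baseline = _lower_hull_baseline(x_asc, y_asc)
    corrected = (y_asc - baseline)[::-1]
    corrected = np.maximum(corrected, 0.0)  # clip 1-ulp negatives from interpolation
    return spectrum.with_absorbance(corrected, "rubberband_baseline")


def vector_normalize(spectrum: Spectrum, mode: str = "center_unit") -> Spectrum:
    """Centre to zero mean then scale to unit Euclidean norm.

    ``mode="unit"`` skips the centring.  Removes path-length/contact-pressure
    scaling between ATR scans.  Raises on constant spectra (zero norm).
    """
    a = spectrum.absorbance
    if np.ptp(a) == 0 and mode == "center_unit":
        raise ValueError("cannot vector-normalize a constant spectrum")
    if mode == "center_unit":
        a = a - a.mean()
    elif mode != "unit":
        raise ValueError("mode must be 'center_unit' or 'unit'")
    nrm = np.linalg.norm(a)
    if nrm == 0.0 or not np.isfinite(nrm):
        raise ValueError("cannot vector-normalize a zero-norm spectrum")
    return spectrum.with_absorbance(a / nrm, "vector_normalize")


def first_derivative(spectrum: Spectrum, window: int = 9, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay first derivative dA/d(nu), ascending-nu sign convention.

    Exact on polynomials up to ``polyorder``; end windows use the local
    polynomial fit (no padding artefacts).  Requires a uniform grid.
    """
    n = len(spectrum)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError("window larger than the grid")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    steps = np.diff(spectrum.wavenumbers[::-1])
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("Savitzky-Golay derivative requires a uniform grid")
    delta = float(steps[0])
    asc = spectrum.absorbance[::-1]
    deriv = savgol_filter(asc, window, polyorder, deriv=1, delta=delta, mode="interp")
    return spectrum.with_absorbance(deriv[::-1], "first_derivative")


def restrict(obj: Spectrum | SpectraSet, region_set: RegionSet) -> Spectrum | SpectraSet:
    """Keep only grid points inside the (closed) intervals, descending order."""
    grid = obj.grid if isinstance(obj, SpectraSet) else obj.wavenumbers
    mask = region_set.mask(grid)
    if not mask.any():
        raise ValueError("region set does not intersect the grid")
    for hi, lo in region_set.intervals:
        if not ((grid >= lo) & (grid <= hi)).any():
            raise ValueError(f"interval [{hi}, {lo}] lies entirely outside the grid")
    if isinstance(obj, SpectraSet):
        return SpectraSet.from_matrix(
            grid[mask],
            obj.to_matrix()[:, mask],
            obj.sample_ids,
            history=obj.samples[0].history + ("restrict",),
        )
    return obj.with_grid(grid[mask], obj.absorbance[mask], "restrict")


def _apply_steps(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    s = spectrum
    for step in config.steps:
        if step == "atr_correction":
            s = atr_correction(s, config.atr_reference_wavenumber)
        elif step == "rubberband_baseline":
            s = rubberband_baseline(s)
        elif step == "vector_normalize":
            s = vector_normalize(s, config.vector_norm_mode)
        elif step == "first_derivative":
            s = first_derivative(s, config.derivative_window, config.derivative_polyorder)
    return s


def apply_pipeline(spectra: SpectraSet | Spectrum, config: PreprocessConfig):
    """Apply the configured steps in order, then restrict to the region."""
    if isinstance(spectra, Spectrum):
        out = _apply_steps(spectra, config)
        return out if config.region is None else restrict(out, config.region)
    out_set = SpectraSet(tuple(_apply_steps(s, config) for s in spectra))
    if config.region is not None:
        out_set = restrict(out_set, config.region)
    return out_set
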