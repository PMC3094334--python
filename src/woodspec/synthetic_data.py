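"""Generator of wood-like FTIR-ATR spectra with paired reference values.

No instrument spectra accompany the populations this package models, so the
generator emulates their reported statistical structure: lignin contents
uniform over 23.4-32.1 % (w/w), gross calorific values spanning
17260-19767 J g⁻¹, the two traits statistically independent, the lignin
signal carried by aromatic-band intensities (1593, 1506, 1458, 1420, 1328,
1234, 1120 cm⁻¹) and the energy signal by carbohydrate ring-vibration
bands.  Bands are Gaussian (near-Gaussian is typical for condensed-phase
mid-IR after ATR correction, and Gaussian areas give closed-form oracles);
each spectrum adds a smooth low-order polynomial baseline drift and white
noise, and reference values add trait-scaled measurement noise.

Defaults (reference noise 0.3 % lignin, 60 J g⁻¹ energy — the order of
realistic assay scatter; spectral noise 0.3 % of the maximum peak height)
define the study conditions used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra_io import ReferenceTable, SpectraSet, Spectrum

__all__ = [
    "BandLibrary",
    "SimConfig",
    "default_band_library",
    "default_grid",
    "simulate_sample",
    "simulate_dataset",
    "inject_artifact",
]

AROMATIC = "aromatic/lignin"
CARBOHYDRATE = "carbohydrate"
OTHER = "other"


@dataclass(frozen=True)
class BandLibrary:
    """Gaussian band catalogue: (center cm^-1, FWHM cm^-1, intensity AU, class)."""

    bands: tuple[tuple[float, float, float, str], ...]

    def __post_init__(self) -> None:
        for c, w, a, cls in self.bands:
            if not 800.0 <= c <= 1800.0:
                raise ValueError(f"band center {c} outside 800-1800 cm^-1")
            if not 8.0 <= w <= 60.0:
                raise ValueError(f"band width {w} outside [8, 60] cm^-1")
            if a <= 0:
                raise ValueError("band intensity must be > 0")
            if cls not in (AROMATIC, CARBOHYDRATE, OTHER):
                raise ValueError(f"unknown band class {cls!r}")

    def by_class(self, cls: str) -> list[tuple[float, float, float, str]]:
        return [b for b in self.bands if b[3] == cls]


def default_band_library() -> BandLibrary:
    """Aromatic lignin bands plus carbohydrate ring-vibration bands.

    Intensities are order-of-magnitude values scaled so the strongest
    carbohydrate band (~1035 cm^-1, the dominant feature of wood mid-IR
    spectra) peaks near 1 AU at mid-range composition.
    """
    return BandLibrary(
        bands=(
            # aromatic / lignin
            (1593.0, 30.0, 0.35, AROMATIC),
            (1506.0, 20.0, 0.45, AROMATIC),
            (1458.0, 24.0, 0.35, AROMATIC),
            (1420.0, 24.0, 0.30, AROMATIC),
            (1328.0, 22.0, 0.25, AROMATIC),
            (1234.0, 30.0, 0.40, AROMATIC),
            (1120.0, 20.0, 0.30, AROMATIC),
            # carbohydrate ring / skeletal vibrations
            (1740.0, 30.0, 0.40, CARBOHYDRATE),
            (1060.0, 30.0, 0.80, CARBOHYDRATE),
            (1035.0, 28.0, 1.00, CARBOHYDRATE),
            (898.0, 16.0, 0.15, CARBOHYDRATE),
            # adsorbed water, trait-independent
            (1640.0, 40.0, 0.20, OTHER),
        )
    )


def default_grid() -> np.ndarray:
    """Instrument grid: 4000 -> 600 cm^-1 in 4 cm^-1 steps (descending)."""
    return np.arange(4000.0, 600.0 - 1e-9, -4.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated dataset (seed mandatory)."""

    n_samples: int
    seed: int
    lignin_range: tuple[float, float] = (23.4, 32.1)
    energy_range: tuple[float, float] = (17260.0, 19767.0)
    carb_latent_range: tuple[float, float] = (0.7, 1.3)
    spectral_noise_sd: float = 0.003
    baseline_drift_amplitude: float = 0.02
    lignin_reference_noise_sd: float = 0.3
    energy_reference_noise_sd: float = 60.0
    band_library: BandLibrary = field(default_factory=default_band_library)
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.lignin_range[0] >= self.lignin_range[1]:
            raise ValueError("lignin_range must be ordered")
        if self.energy_range[0] >= self.energy_range[1]:
            raise ValueError("energy_range must be ordered")
        if self.carb_latent_range[0] >= self.carb_latent_range[1]:
            raise ValueError("carb_latent_range must be ordered")
        for name in ("spectral_noise_sd", "baseline_drift_amplitude",
                     "lignin_reference_noise_sd", "energy_reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Reference lignin level (% w/w) at which aromatic bands take their
#: catalogue intensity; intensities scale linearly with the latent.
LIGNIN_SCALE_ANCHOR = 27.0



def _gaussian_bands(grid: np.ndarray, bands, scale: float) -> np.ndarray:
    out = np.zeros_like(grid)
    for center, fwhm, amp, _ in bands:
        sigma = fwhm * _FWHM_TO_SIGMA
        out += scale * amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return out


def carb_latent_to_energy(carb_latent: float, config: SimConfig) -> float:
    """Affine map hitting the configured energy range at the latent extremes."""
    lo, hi = config.carb_latent_range
    e_lo, e_hi = config.energy_range
    return e_lo + (carb_latent - lo) / (hi - lo) * (e_hi - e_lo)


def simulate_sample(
    lignin_latent: float,
    carb_latent: float,
    config: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> tuple[Spectrum, float, float]:
    """One spectrum plus noisy (lignin, energy) reference values.

    Aromatic band intensities scale with ``lignin_latent`` (linear, unit
    scale at 27 %), carbohydrate intensities with ``carb_latent``; the
    water band is trait-independent.  Baseline drift is a random cubic with
    the configured amplitude; white noise has the configured SD.
    """
    grid = config.grid
    lib = config.band_library
    lignin_scale = lignin_latent / LIGNIN_SCALE_ANCHOR
    if lignin_scale <= 0 or carb_latent <= 0:
        raise ValueError("latents must give positive band intensities")
    absorbance = (
        _gaussian_bands(grid, lib.by_class(AROMATIC), lignin_scale)
        + _gaussian_bands(grid, lib.by_class(CARBOHYDRATE), carb_latent)
        + _gaussian_bands(grid, lib.by_class(OTHER), 1.0)
    )
    if config.baseline_drift_amplitude > 0:
        u = (grid - grid.mean()) / (grid.max() - grid.min())
        coeffs = rng.normal(size=4)
        drift = np.polyval(coeffs, u)
        span = np.abs(drift).max()
        if span > 0:
            absorbance = absorbance + config.baseline_drift_amplitude * (drift / span)
    if config.spectral_noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, config.spectral_noise_sd, grid.size)
    lignin_ref = lignin_latent + rng.normal(0.0, config.lignin_reference_noise_sd)
    energy_ref = carb_latent_to_energy(carb_latent, config) + rng.normal(
        0.0, config.energy_reference_noise_sd
    )
    return Spectrum(grid, absorbance, sample_id, ("simulate",)), lignin_ref, energy_ref


def simulate_dataset(
    config: SimConfig,
) -> tuple[SpectraSet, ReferenceTable, ReferenceTable]:
    """Seeded dataset: spectra plus lignin and energy reference tables.

    Latents are drawn independently and uniformly over their configured
    ranges, so the two traits are uncorrelated by construction.
    """
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(config.seed)
    lignins = rng.uniform(*config.lignin_range, size=config.n_samples)
    carbs = rng.uniform(*config.carb_latent_range, size=config.n_samples)
    spectra: list[Spectrum] = []
    lig_refs: dict[str, float] = {}
    en_refs: dict[str, float] = {}
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        sp, lig, en = simulate_sample(lignins[i], carbs[i], config, rng, sid)
        spectra.append(sp)
        lig_refs[sid] = lig
        en_refs[sid] = en
    return (
        SpectraSet(tuple(spectra)),
        ReferenceTable("lignin_percent", lig_refs),
        ReferenceTable("energy_J_per_g", en_refs),
    )


def inject_artifact(
    spectrum: Spectrum,
    kind: str,
    magnitude: float,
    rng: np.random.Generator,
) -> Spectrum:
    """Plant a measurement artifact for outlier-screening tests.

    ``spike``: a narrow Gaussian of height magnitude × max absorbance at a
    random wavenumber inside the fingerprint region (1800-800 cm^-1, so the
    artifact perturbs the channels calibration models actually analyse).
    ``baseline_jump``: a step of magnitude × max absorbance from a random
    point downward.  ``scaling``: multiply the whole trace by
    (1 + magnitude).  magnitude 0 is the identity; the artifact location is
    recorded in the history.
    """
    a = spectrum.absorbance
    grid = spectrum.wavenumbers
    peak = float(np.abs(a).max())
    if kind == "spike":
        candidates = np.flatnonzero((grid <= 1800.0) & (grid >= 800.0))
        if candidates.size == 0:
            candidates = np.arange(grid.size)
        idx = int(candidates[rng.integers(0, candidates.size)])
        if magnitude == 0:
            return spectrum.with_absorbance(a.copy(), f"artifact:spike@{grid[idx]:.0f}")
        sigma = 6.0
        bump = magnitude * peak * np.exp(-0.5 * ((grid - grid[idx]) / sigma) ** 2)
        return spectrum.with_absorbance(a + bump, f"artifact:spike@{grid[idx]:.0f}")
    if kind == "baseline_jump":
        idx = int(rng.integers(0, grid.size))
        out = a.copy()
        out[idx:] += magnitude * peak
        return spectrum.with_absorbance(out, f"artifact:baseline_jump@{grid[idx]:.0f}")
    if kind == "scaling":
        return spectrum.with_absorbance(a * (1.0 + magnitude), "artifact:scaling")
    raise ValueError(f"unknown artifact kind {kind!r}")
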