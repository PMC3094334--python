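"""PCA of stratified spectral subsets and loading-peak band attribution.

To ask *which* cell-wall constituents drive trait variation, spectra of the
samples with lowest / medium / highest trait values (10 each by default) are
pooled, the fingerprint region (1800-900 cm^-1) is rubberband
baseline-corrected, vector-normalised and mean-centred, and a PCA is run.
Peaks in the factor loadings are then matched against a band-assignment
table: aromatic skeletal and syringyl/guaiacyl ring bands indicate lignin,
ring vibrations of polysaccharides indicate carbohydrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import PreprocessConfig, RegionSet, apply_pipeline
from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "PCAResult",
    "BandTable",
    "DEFAULT_BAND_TABLE",
    "PCA_REGION",
    "PCA_PREPROCESS",
    "stratify_extremes",
    "fit_pca",
    "top_peaks",
    "assign_bands",
]

AROMATIC = "aromatic/lignin"
CARBOHYDRATE = "carbohydrate"
OTHER = "other"

#: Fingerprint window used for the stratified PCA.
PCA_REGION = RegionSet((( 1800.0, 900.0),))

#: Baseline-correct, vector-normalise; mean-centring happens inside the PCA.
PCA_PREPROCESS = PreprocessConfig(
    steps=("rubberband_baseline", "vector_normalize"), region=PCA_REGION
)


@dataclass(frozen=True)
class BandTable:
    """Mid-IR band assignments: (wavenumber cm^-1, assignment, class)."""

    rows: tuple[tuple[float, str, str], ...]
    version: str = "1"

    def __post_init__(self) -> None:
        wns = [r[0] for r in self.rows]
        if len(set(wns)) != len(wns):
            raise ValueError("duplicate wavenumbers in band table")
        for wn, _, cls in self.rows:
            if not 800.0 <= wn <= 1800.0:
                raise ValueError(f"band {wn} outside 800-1800 cm^-1")
            if cls not in (AROMATIC, CARBOHYDRATE, OTHER):
                raise ValueError(f"unknown band class {cls!r}")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array([r[0] for r in self.rows])


#: Fingerprint-region assignments for extractive-free hardwood: aromatic
#: skeletal / C-H deformation / syringyl+guaiacyl ring bands for lignin,
#: ester carbonyl and pyranose-ring C-O/C-C bands for the polysaccharides.
DEFAULT_BAND_TABLE = BandTable(
    rows=(
        (1740.0, "C=O stretch, acetyl/ester (hemicellulose)", CARBOHYDRATE),
        (1640.0, "adsorbed water bending", OTHER),
        (1593.0, "aromatic skeletal vibration", AROMATIC),
        (1506.0, "aromatic skeletal vibration", AROMATIC),
        (1458.0, "C-H deformation, lignin", AROMATIC),
        (1420.0, "C-H deformation, lignin", AROMATIC),
        (1370.0, "C-H bending, polysaccharides", CARBOHYDRATE),
        (1328.0, "syringyl plus guaiacyl ring", AROMATIC),
        (1234.0, "syringyl ring and C=O stretch", AROMATIC),
        (1158.0, "C-O-C asymmetric stretch, cellulose", CARBOHYDRATE),
        (1120.0, "aromatic skeletal vibration", AROMATIC),
        (1060.0, "C-O stretch, cellulose/hemicellulose ring", CARBOHYDRATE),
        (1035.0, "C-O stretch, carbohydrate ring", CARBOHYDRATE),
        (898.0, "glucose ring stretch, beta-glycosidic link", CARBOHYDRATE),
    ),
    version="1",
)


@dataclass
class PCAResult:
    """Unit-norm loadings (component × wavenumber), % variance, scores."""

    loadings: np.ndarray
    explained_pct: np.ndarray
    scores: np.ndarray
    grid: np.ndarray


def stratify_extremes(
    references: ReferenceTable, n_per_stratum: int = 10
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint (low, medium, high) sample-id strata of size n each.

    Low/high are the n smallest/largest trait values; medium the n values
    closest to the overall median among the remainder.  Ties break by
    sample_id order.
    """
    n = int(n_per_stratum)
    items = sorted(references.values.items(), key=lambda kv: (kv[1], kv[0]))
    if len(items) < 3 * n:
        raise ValueError(f"need at least {3 * n} samples, have {len(items)}")
    low = [sid for sid, _ in items[:n]]
    high = [sid for sid, _ in items[-n:]]
    middle_pool = items[n:-n]
    median = float(np.median([v for _, v in items]))
    middle_sorted = sorted(middle_pool, key=lambda kv: (abs(kv[1] - median), kv[0]))
    medium = [sid for sid, _ in middle_sorted[:n]]
    return low, medium, high


def fit_pca(
    spectra: SpectraSet,
    n_components: int = 4,
    preprocess: PreprocessConfig | None = PCA_PREPROCESS,
) -> PCAResult:
    """PCA of the preprocessed, mean-centred spectra.

    Components are ordered by explained variance; each loading has unit
    norm and its largest-magnitude element made positive (deterministic
    sign convention).
    """
    if preprocess is not None:
        spectra = apply_pipeline(spectra, preprocess)
    X = spectra.to_matrix()
    n = X.shape[0]
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    var = s**2
    explained = 100.0 * var[:n_components] / var.sum()
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(
        loadings=loadings, explained_pct=explained, scores=scores, grid=spectra.grid
    )


def top_peaks(
    loading: np.ndarray,
    grid: np.ndarray,
    n_peaks: int = 8,
) -> list[tuple[float, float, int]]:
    """Largest local maxima of |loading|: (wavenumber, |height|, rank).

    A point is a peak when its magnitude strictly exceeds its neighbours;
    a flat plateau counts once, resolved to its higher-wavenumber edge.
    End points qualify when they exceed their single neighbour.  Returns
    fewer than ``n_peaks`` entries when the loading has fewer local maxima.
    """
    a = np.abs(np.asarray(loading, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if a.size != grid.size:
        raise ValueError("loading and grid lengths differ")
    # grid is descending; higher wavenumber = lower index
    peaks: list[int] = []
    i = 0
    n = a.size
    while i < n:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1  # plateau [i..j]
        left_ok = i == 0 or a[i - 1] < a[i]
        right_ok = j == n - 1 or a[j + 1] < a[i]
        if left_ok and right_ok and a[i] > 0:
            peaks.append(i)  # higher-wavenumber edge of the plateau
        i = j + 1
    peaks.sort(key=lambda idx: (-a[idx], idx))
    out = []
    for rank, idx in enumerate(peaks[: int(n_peaks)], start=1):
        out.append((float(grid[idx]), float(a[idx]), rank))
    return out


def assign_bands(
    peaks: Sequence[tuple[float, float, int]],
    band_table: BandTable = DEFAULT_BAND_TABLE,
    tolerance_cm: float = 8.0,
) -> tuple[list[tuple[float, str, str]], dict[str, int]]:
    """Map each peak to the nearest band within tolerance.

    Returns per-peak (wavenumber, assignment, class) — class
    ``"unassigned"`` when nothing is within ``tolerance_cm`` — plus a tally
    of assignments per class.
    """
    if not band_table.rows:
        raise ValueError("empty band table")
    if tolerance_cm <= 0:
        raise ValueError("tolerance must be positive")
    centers = band_table.wavenumbers
    assignments: list[tuple[float, str, str]] = []
    tallies = {AROMATIC: 0, CARBOHYDRATE: 0, OTHER: 0, "unassigned": 0}
    for wn, _, _ in peaks:
        dist = np.abs(centers - wn)
        j = int(np.argmin(dist))
        if dist[j] <= tolerance_cm:
            _, text, cls = band_table.rows[j]
            assignments.append((wn, text, cls))
            tallies[cls] += 1
        else:
            assignments.append((wn, "", "unassigned"))
            tallies["unassigned"] += 1
    return assignments, tallies
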