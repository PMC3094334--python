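"""Spectrum containers and I/O.

Mid-infrared absorbance traces are stored on a strictly monotone wavenumber
grid in *descending* order, the export convention of FTIR instruments
(scans run 4000 -> 600 cm^-1).  Constructors accept either orientation and
normalise, which removes a silent source of sign errors in derivative
preprocessing.

Supported exchange formats:

* CSV matrix — first column ``wavenumber_cm-1``, one column per sample
  (transposed layout auto-detected, override with ``orientation_hint``);
* JCAMP-DX — uncompressed AFFN ``XYDATA=(X++(Y..Y))`` and
  ``XYPOINTS=(XY..XY)`` records, the plain-number subset instruments emit
  when compression is switched off;
* reference tables — two-column CSV (``sample_id``, value) per trait.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "ReferenceTable",
    "FINGERPRINT_REGION",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "read_reference_csv",
    "write_reference_csv",
    "resample_to_grid",
    "average_replicates",
]

#: Fingerprint region (cm^-1) used when summarising replicate scatter.
FINGERPRINT_REGION = (1800.0, 800.0)


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace with provenance.

    Parameters
    ----------
    wavenumbers
        Strictly monotone grid in cm^-1; stored descending regardless of the
        orientation supplied.
    absorbance
        Absorbance in AU, same length as ``wavenumbers``, all finite.
    sample_id
        Free-text identifier.
    history
        Ordered labels of the preprocessing steps already applied.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be 1-D of equal length")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        dw = np.diff(wn)
        if np.all(dw > 0):  # ascending input -> store descending
            wn, ab = wn[::-1].copy(), ab[::-1].copy()
        elif not np.all(dw < 0):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance contains non-finite values")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "history", tuple(self.history))

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, step: str) -> "Spectrum":
        """Copy with new absorbance values and ``step`` appended to history."""
        return Spectrum(
            self.wavenumbers.copy(),
            np.asarray(absorbance, dtype=float),
            self.sample_id,
            self.history + (step,),
        )

    def with_grid(self, wavenumbers: np.ndarray, absorbance: np.ndarray, step: str) -> "Spectrum":
        return Spectrum(
            np.asarray(wavenumbers, dtype=float),
            np.asarray(absorbance, dtype=float),
            self.sample_id,
            self.history + (step,),
        )


@dataclass(frozen=True)
class SpectraSet:
    """Samples sharing one wavenumber grid (bitwise identical)."""

    samples: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if not samples:
            raise ValueError("SpectraSet needs at least one spectrum")
        grid = samples[0].wavenumbers
        for s in samples[1:]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                raise ValueError(f"spectrum {s.sample_id!r} is not on the shared grid")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "samples", samples)

    @property
    def grid(self) -> np.ndarray:
        return self.samples[0].wavenumbers

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_matrix(self) -> np.ndarray:
        """n_samples × n_wavenumbers absorbance matrix."""
        return np.vstack([s.absorbance for s in self.samples])

    @classmethod
    def from_matrix(
        cls,
        grid: np.ndarray,
        matrix: np.ndarray,
        sample_ids: Sequence[str],
        history: tuple[str, ...] = (),
    ) -> "SpectraSet":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != len(sample_ids):
            raise ValueError("row count must match sample_ids")
        return cls(
            tuple(
                Spectrum(np.asarray(grid, float), matrix[i], sid, history)
                for i, sid in enumerate(sample_ids)
            )
        )

    def map(self, fn, step: str | None = None) -> "SpectraSet":
        """Apply ``fn(Spectrum) -> Spectrum`` to every member."""
        return SpectraSet(tuple(fn(s) for s in self.samples))

    def subset(self, indices: Iterable[int]) -> "SpectraSet":
        return SpectraSet(tuple(self.samples[i] for i in indices))


_TRAIT_BOUNDS = {
    "lignin_percent": (0.0, 100.0),
    "energy_J_per_g": (0.0, np.inf),
}


@dataclass(frozen=True)
class ReferenceTable:
    """Per-sample reference values for one trait.

    ``trait`` is ``lignin_percent`` (% w/w of dry extractive-free wood) or
    ``energy_J_per_g`` (gross calorific value, J g^-1).  One row per sample;
    optional replicate values may be attached and are averaged on access.
    """

    trait: str
    values: Mapping[str, float]
    replicates: Mapping[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.trait not in _TRAIT_BOUNDS:
            raise ValueError(f"unknown trait {self.trait!r}")
        lo, hi = _TRAIT_BOUNDS[self.trait]
        vals = dict(self.values)
        for sid, v in vals.items():
            if not (lo < float(v) < hi):
                raise ValueError(f"{self.trait} value {v} for {sid!r} out of ({lo}, {hi})")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Trait vector in the order of ``sample_ids``; KeyError if missing."""
        return np.array([self.values[sid] for sid in sample_ids], dtype=float)

    def subset(self, sample_ids: Iterable[str]) -> "ReferenceTable":
        keep = set(sample_ids)
        return ReferenceTable(self.trait, {k: v for k, v in self.values.items() if k in keep})


# ---------------------------------------------------------------------------
# CSV matrix I/O
# ---------------------------------------------------------------------------

_WAVENUMBER_RE = re.compile(r"^\s*wavenumber", re.IGNORECASE)


def read_spectra_csv(path: str | Path, orientation_hint: str | None = None) -> SpectraSet:
    """Read a spectra matrix CSV.

    The canonical layout has a first column named ``wavenumber_cm-1`` and one
    column per sample.  The transposed layout (wavenumbers as the header row)
    is auto-detected by header sniffing; pass ``orientation_hint`` as
    ``"columns"`` (samples in columns, canonical) or ``"rows"`` to override.
    """
    with open(path) as fh:
        header_cells = fh.readline().rstrip("\n").split(",")
    if len(set(header_cells)) != len(header_cells):
        raise ValueError("duplicate sample ids in spectra CSV header")
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError("spectra CSV needs a wavenumber axis and at least one sample")

    if orientation_hint is None:
        orientation_hint = "columns" if _WAVENUMBER_RE.match(str(df.columns[0])) else "rows"
    if orientation_hint not in ("columns", "rows"):
        raise ValueError("orientation_hint must be 'columns' or 'rows'")

    if orientation_hint == "rows":
        # header row = wavenumbers, first column = sample ids
        try:
            grid = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise ValueError("transposed layout: header cells must be wavenumbers") from exc
        ids = [str(v) for v in df.iloc[:, 0]]
        matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        if not _WAVENUMBER_RE.match(str(df.columns[0])):
            raise ValueError("missing wavenumber axis (first column must be 'wavenumber_cm-1')")
        grid = df.iloc[:, 0].to_numpy(dtype=float)
        ids = [str(c) for c in df.columns[1:]]
        matrix = df.iloc[:, 1:].to_numpy(dtype=float).T

    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in spectra CSV")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-numeric or non-finite cells in spectra CSV")
    order = np.argsort(-grid)  # normalise to descending
    return SpectraSet.from_matrix(grid[order], matrix[:, order], ids)


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write the canonical samples-in-columns layout."""
    df = pd.DataFrame({"wavenumber_cm-1": spectra.grid})
    for s in spectra:
        df[s.sample_id] = s.absorbance
    df.to_csv(path, index=False, float_format="%.10g")


def read_reference_csv(path: str | Path, trait: str) -> ReferenceTable:
    """Two-column (sample_id, value) reference CSV for one trait."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError("reference CSV must have exactly two columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in reference CSV")
    return ReferenceTable(trait, dict(zip(ids, df.iloc[:, 1].astype(float))))


def write_reference_csv(table: ReferenceTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(table.values), table.trait: list(table.values.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------


def _jcamp_records(text: str) -> tuple[dict[str, str], list[tuple[str, list[str]]]]:
    headers: dict[str, str] = {}
    blocks: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                current = []
                blocks.append((key, current))
                headers[key] = value
            else:
                current = None
                headers[key] = value
        elif current is not None:
            current.append(line)
    return headers, blocks


def read_jcamp(path: str | Path) -> Spectrum:
    """Read an uncompressed JCAMP-DX spectrum (AFFN XYDATA or XYPOINTS).

    The grid is reconstructed from ``FIRSTX``/``LASTX``/``NPOINTS`` for
    XYDATA records; Y values are scaled by ``YFACTOR`` (X by ``XFACTOR``).
    ASDF-compressed records (SQZ/DIF/DUP pseudo-digits) are rejected.
    """
    text = Path(path).read_text()
    headers, blocks = _jcamp_records(text)
    if not blocks:
        raise ValueError("no XYDATA or XYPOINTS record found")
    kind, lines = blocks[0]
    yfactor = float(headers.get("YFACTOR", 1.0))
    xfactor = float(headers.get("XFACTOR", 1.0))
    title = headers.get("TITLE", Path(path).stem)

    body = " ".join(lines).replace(",", " ").replace(";", " ")
    if re.search(r"[A-DF-Za-df-z@%J-RS-Zj-rs-z]", body.replace("E", " ").replace("e", " ")):
        raise ValueError("compressed (ASDF) JCAMP data is not supported")
    try:
        numbers = [float(tok) for tok in body.split()]
    except ValueError as exc:
        raise ValueError("malformed numeric data in JCAMP record") from exc

    if kind == "XYPOINTS":
        if len(numbers) % 2:
            raise ValueError("XYPOINTS record has an odd token count")
        x = np.array(numbers[0::2]) * xfactor
        y = np.array(numbers[1::2]) * yfactor
    else:  # XYDATA=(X++(Y..Y)): each line starts with an X value
        npoints = int(headers["NPOINTS"])
        firstx = float(headers["FIRSTX"])
        lastx = float(headers["LASTX"])
        ys: list[float] = []
        for line in lines:
            toks = line.replace(",", " ").split()
            ys.extend(float(t) for t in toks[1:])  # drop per-line X
        if len(ys) != npoints:
            raise ValueError(f"NPOINTS={npoints} but {len(ys)} Y values present")
        x = np.linspace(firstx, lastx, npoints) * xfactor
        y = np.array(ys) * yfactor
    return Spectrum(x, y, sample_id=title, history=("read_jcamp",))


# ---------------------------------------------------------------------------
# Resampling and replicate averaging
# ---------------------------------------------------------------------------


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate onto ``grid`` (must lie inside the support)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.wavenumbers.min(), spectrum.wavenumbers.max()
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError("target grid extends beyond the spectrum's support")
    asc_w = spectrum.wavenumbers[::-1]
    asc_a = spectrum.absorbance[::-1]
    out_grid = np.sort(grid)[::-1]
    values = np.interp(out_grid, asc_w, asc_a)
    return spectrum.with_grid(out_grid, values, "resample")


def average_replicates(
    spectra_by_sample: Mapping[str, Sequence[Spectrum]],
    sd_region: tuple[float, float] = FINGERPRINT_REGION,
    sd_normalization: str = "percent_of_mean",
) -> tuple[SpectraSet, dict[str, float], float]:
    """Average technical replicates and summarise their scatter.

    For each sample the pointwise mean spectrum is returned.  Replicate
    scatter is condensed to one scalar per sample: the root of the mean
    pointwise variance over ``sd_region`` (ddof=1).  With
    ``sd_normalization="percent_of_mean"`` that scalar is expressed as a
    percentage of the sample's mean absorbance over the same region;
    ``"absolute"`` reports it in AU.  The pooled value is the root of the
    across-sample mean of the per-sample mean variances, normalised the
    same way against the grand mean absorbance.
    """
    if sd_normalization not in ("percent_of_mean", "absolute"):
        raise ValueError("sd_normalization must be 'percent_of_mean' or 'absolute'")
    means: list[Spectrum] = []
    per_sample_sd: dict[str, float] = {}
    grid: np.ndarray | None = None
    mean_vars: list[float] = []
    region_means: list[float] = []
    for sid, reps in spectra_by_sample.items():
        reps = list(reps)
        if not reps:
            raise ValueError(f"sample {sid!r} has no replicates")
        g = reps[0].wavenumbers
        for r in reps[1:]:
            if not np.array_equal(r.wavenumbers, g):
                raise ValueError(f"replicates of {sid!r} are on mismatched grids")
        if grid is None:
            grid = g
        elif not np.array_equal(g, grid):
            raise ValueError("samples are on mismatched grids")
        stack = np.vstack([r.absorbance for r in reps])
        mean = stack.mean(axis=0)
        means.append(Spectrum(g, mean, sid, ("average_replicates",)))
        hi, lo = max(sd_region), min(sd_region)
        mask = (g >= lo) & (g <= hi)
        if not mask.any():
            mask = np.ones_like(g, dtype=bool)
        var = stack[:, mask].var(axis=0, ddof=1) if len(reps) > 1 else np.zeros(mask.sum())
        mv = float(var.mean())
        region_mean = float(np.abs(mean[mask]).mean())
        mean_vars.append(mv)
        region_means.append(region_mean)
        sd = np.sqrt(mv)
        if sd_normalization == "percent_of_mean":
            sd = 100.0 * sd / region_mean if region_mean > 0 else np.nan
        per_sample_sd[sid] = float(sd)
    pooled = float(np.sqrt(np.mean(mean_vars)))
    if sd_normalization == "percent_of_mean":
        grand = float(np.mean(region_means))
        pooled = 100.0 * pooled / grand if grand > 0 else float("nan")
    return SpectraSet(tuple(means)), per_sample_sd, pooled
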