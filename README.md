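# woodspec

Chemometric calibration of mid-infrared (FTIR-ATR) spectra for
high-throughput phenotyping of wood: predicting **lignin content**
(% w/w of dry extractive-free wood) and **gross calorific value**
(J g⁻¹) without running the wet-chemistry assay or bomb calorimeter for
every sample. It is aimed at tree-breeding and bioenergy programmes that
screen hundreds of wood samples, and at anyone building PLS calibrations
on ATR spectra of plant cell walls.

## What it does

A spectrum is an absorbance trace *A(ν)* on a 4000–600 cm⁻¹ grid
(4 cm⁻¹ resolution). The pipeline is:

1. **Preprocessing** — ATR penetration-depth rescaling (×ν/ν_ref),
   rubberband baseline subtraction (lower convex hull), vector
   normalisation (centre, then ‖x‖₂ = 1), Savitzky–Golay first
   derivative, and restriction to wavenumber regions.
2. **PLS1 calibration** (NIPALS). With mean-centred spectra X and trait
   y, each factor extracts w ∝ Xᵀy, scores t = Xw, loadings
   p = Xᵀt/tᵀt, q = tᵀy/tᵀt, then deflates X and y. Performance is
   reported as R²(calibration), R²(cross-validation), RMSEC, RMSECV and —
   on an independent set — RMSEP, with leave-one-out cross-validation
   done by literal refitting (the held-out sample never touches the
   fold's centring or decomposition).
3. **Automatic wavenumber selection** — the 2000–700 cm⁻¹ window is
   tiled into 112 cm⁻¹ subregions; all combinations of up to three tiles
   (231 candidates) are scored by RMSECV and the most parsimonious
   candidate within one standard error of the minimum wins.
4. **Outlier screening** — Mahalanobis distance in whitened PLS score
   space against the limit (Factor × Rank)/M, Factor = 5 by default,
   with iterative backward deletion.
5. **PCA loading analysis** — stratified extreme/medium/extreme subsets,
   PCA of the 1800–900 cm⁻¹ fingerprint, top-8 loading peaks matched to
   a band-assignment table (aromatic lignin bands at 1593, 1506, 1458,
   1420, 1328, 1234, 1120 cm⁻¹ vs carbohydrate ring vibrations).
6. **Wet-chemistry reference arithmetic** — acetyl bromide lignin via
   Beer–Lambert (ε = 20.09 L g⁻¹ cm⁻¹) and calorimetry against the
   benzoic-acid standard (26457 J g⁻¹), plus the lignin–energy
   correlation statistic.

Because no public spectra exist for this problem, `woodspec.synthetic_data`
generates wood-like spectra with paired reference values: Gaussian bands
whose aromatic intensities follow a lignin latent (23.4–32.1 %) and whose
carbohydrate intensities follow an independent energy latent
(17260–19767 J g⁻¹), plus baseline drift and noise. Every stage of the
pipeline is tested against this generator.

## Worked example

```python
import woodspec as ws

spectra, lignin, energy = ws.simulate_dataset(ws.SimConfig(n_samples=60, seed=42))
region, cv = ws.auto_select_regions(
    spectra, lignin,
    ws.PreprocessConfig(steps=("vector_normalize",)),
    ws.RegionSearchSpec(),
)
print(region.intervals)
print(f"R2(cv)={cv.r2_cv:.3f}  RMSECV={cv.rmsecv:.3f} %  factors={cv.n_factors}")
```

prints

```
((1664.0, 1552.0), (1552.0, 1440.0))
R2(cv)=0.964  RMSECV=0.460 %  factors=2
```

The selected tiles cover the 1593/1506/1458 cm⁻¹ aromatic skeletal
bands — the search found the lignin signal where the generator planted
it — and the cross-validated error (0.46 %) is close to the 0.3 %
reference noise injected into the simulated assay values, i.e. the
calibration is nearly as good as the reference method allows.

The same workflow is available from the shell:

```bash
woodspec simulate --n 95 --seed 1 --out data/
woodspec search --spectra data/spectra.csv --references data/lignin_percent.csv \
    --trait lignin_percent --out search/
```

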