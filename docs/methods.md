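# Methods

## Model

Calibration is PLS1 (one trait per model; lignin and calorific value get
separate models, matching how the two assays are run). NIPALS on
mean-centred X (n × p absorbance matrix) and y: per factor,
w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = tᵀy/tᵀt, then X ← X − tpᵀ and
y ← y − qt. Regression vectors for every truncation k come from the
recursion rₖ = wₖ − Σⱼ<ₖ (pⱼ·wₖ) rⱼ (i.e. R = W(PᵀW)⁻¹), so one fit
serves all factor counts. The decomposition stops early when the
deflated covariance Xᵀy falls below 10⁻¹⁴ of its initial norm.

Assumptions: the trait signal is (locally) linear in absorbance over the
trait range; spectra share one uniform grid; replicate/instrument
effects are either removed by preprocessing or absorbed by extra
factors.

## Cross-validation and descriptors

Leave-one-out CV refits the whole decomposition per fold, recentring X
and y inside the fold — the held-out sample influences nothing. The
implementation advances all n folds one factor at a time with einsum;
the test suite pins exact (≤ 10⁻⁹) agreement with a literal
delete-one-row-and-refit loop, so no shortcut formula is trusted
untested.

* RMSEC: in-sample RMSE, divisor n (a `divisor` switch offers n−k−1;
  vendor conventions are undocumented, n is the default).
* RMSECV: LOO RMSE, divisor n. RMSEP: independent-set RMSE after
  excluding predictions outside the calibration y-range (switchable).
* R²(calibration), R²(cv): 1 − SSE/TSS. R²(validation): squared Pearson
  correlation of measured vs predicted (the best-fit-line convention);
  the 1 − PRESS/TSS form is also reported.
* Factor choice: per-candidate argmin of RMSECV by default, or the
  "substantial reduction" rule (first k whose next factor cuts residual
  y-variance by < 2 %) applied to the PRESS curve. Cap 16 factors;
  region-search evaluations cap at 12 to bound the cost of the
  231-candidate search.

## Region search

Window 2000–700 cm⁻¹ tiled from the high edge into 112 cm⁻¹ tiles (the
width of the intervals QUANT-style searches return); the 68 cm⁻¹
remainder is discarded; combinations of 1–3 of the 11 tiles give 231
candidates. Shape transforms (derivative, baseline, normalisation) run
once on the full contiguous grid — they need contiguous support — and
every candidate is a column restriction of that matrix, followed by the
fold-wise mean-centring inside the CV.

**Winner rule.** Neighbouring candidates' CV errors are statistically
tied far more often than exactly equal: on generator data the top ~8
candidates differ by far less than the standard error of the mean
squared CV error, so an exact argmin picks "passenger" tiles carrying no
signal quasi-randomly. The default is therefore the classic
one-standard-error rule: among candidates whose MSE_CV lies within one
SE of the global minimum, take the fewest tiles, then lowest RMSECV,
then fewest factors, then highest-wavenumber-first.
`parsimony="none"` restores the exact minimiser. Under the 1-SE rule
the winner never has a higher RMSECV than the best single-tile
candidate.

## Outlier screening

Distances are computed in whitened PLS score space: with calibration
scores T (m × rank), d = tᵀ(TᵀT)⁻¹t, so calibration distances average
rank/m; full-spectrum covariance is singular for p ≫ n, making score
space the only well-posed metric. The flag limit is
(Factor × Rank)/M, Factor = 5 by default (Factor = 2 proves too strict
on natural samples).

Two numerical choices matter. First, d is bounded near 1 — however
extreme a sample is, it can at most dominate its own factors — so the
limit can flag nothing once rank ≥ m/Factor; the screen therefore uses
rank = min(available factors, ⌊(m−1)/Factor⌋), the largest subspace for
which the limit stays below the bound. (The configuration
Factor = 5, rank = 12, m = 61 gives limit 0.98361, right at this
boundary.) Second, removal is backward deletion: only the most distant
flagged sample is dropped per round before refitting, because a gross
outlier left in the model distorts the subspace under which its
neighbours are judged. `drop="all"` removes every flagged sample per
round. Screening aborts if more than half the samples would go.

## PCA loading attribution

Stratified sets (n lowest / n closest-to-median / n highest trait
values, n = 10 by default; "medium" as closest-to-median is one
reading of an underspecified protocol and is configurable) are
baseline-corrected, vector-normalised and mean-centred over
1800–900 cm⁻¹, then decomposed by SVD. Loadings are unit-norm with the
largest-magnitude element positive. Peaks are local maxima of
|loading| (plateaus resolve to the higher-wavenumber edge), the top 8
are matched to the shipped band table within ±8 cm⁻¹ (two resolution
steps).

One caveat the tests make explicit: vector normalisation converts a
single-constituent intensity change into a compositional change of
*every* band, so attribution tests on generator data that vary only one
latent use baseline-only preprocessing; with normalisation in place the
loading legitimately shows mirror peaks at the other class's positions.

## Wet-chemistry arithmetic

Acetyl bromide lignin: cuvette concentration
c = (m_dry/V_reaction)(V_aliquot/V_final); with the default scheme
(1 mg air-dry powder in 1 mL, 100 µL diluted to 2 mL) c = 0.05 g L⁻¹
and lignin % = A₂₈₀·100/(ε·c·l) = 99.552·A₂₈₀ at ε = 20.09 L g⁻¹ cm⁻¹,
1 cm path. Moisture correction applies to the mass before the
concentration. Calorimetry: C = E_std·m/ΔT from the benzoic-acid
standard (26457 J g⁻¹); sample energy E = C·ΔT/m; the round trip on the
standard run is exact by construction. Trait correlation: squared
Pearson r with the two-sided p from t = r√((n−2)/(1−r²)),
cross-checked against a permutation p in the tests.

## Synthetic data

The generator emulates the statistical structure of field populations of
hybrid poplar wood, not any particular instrument trace:

* lignin latent uniform on 23.4–32.1 % (mean 27.0); an independent
  carbohydrate latent maps affinely onto 17260–19767 J g⁻¹ — the two
  traits are uncorrelated by construction;
* Gaussian bands (near-Gaussian is typical of condensed-phase mid-IR
  after ATR correction, and Gaussian areas give closed-form oracles):
  aromatic bands at 1593, 1506, 1458, 1420, 1328, 1234, 1120 cm⁻¹
  scale with the lignin latent (unit scale at 27 %), carbohydrate bands
  at 1740, 1060, 1035, 898 cm⁻¹ with the energy latent, a water band at
  1640 cm⁻¹ is constant; band intensities are order-of-magnitude values
  anchored to the ~1035 cm⁻¹ polysaccharide maximum (≈1 AU);
* per-sample random cubic baseline drift (default amplitude 0.02 AU)
  and white noise (default SD 0.003 AU ≈ 0.3 % of the maximum peak);
* reference noise: 0.3 % absolute for lignin, 60 J g⁻¹ for energy — the
  order of realistic assay scatter, so recovery tests are realistically
  scaled.

What it does **not** emulate: band-shape changes with composition,
extractive/moisture interference, scattering artefacts, S/G-ratio
effects, instrument drift between sessions. Passing recovery tests
therefore show the machinery is correct and sensitive under plausible
noise, not that any particular accuracy will be reached on real wood.

Artifact injection (for screening tests) places spikes inside the
fingerprint region, since an artifact outside the analysed window is
invisible to a screen over that window except indirectly through
normalisation.

## Problem sizes and determinism

Default study conditions used by the tests and the acceptance script:
n = 60 for pipeline recovery, n = 95 (61/34 split) and n = 76 (61/15)
for the full workflows, n = 200 for the independence statistic, 40
samples with 2 planted spikes (×20 seeds) for the screen, 10 seeds for
constituent attribution. All randomness flows from explicit seeds
(numpy `default_rng`); identical seeds give bitwise-identical reports,
and validation samples never influence centring, region choice or
outlier limits (pinned by a label-permutation test).

## Known limitations

* The rubberband is the classical anchored lower convex hull and the
  ATR correction the classical ν/ν_ref rescale; commercial
  implementations are proprietary and numerical equality with them is
  not claimed. Likewise both R² conventions are reported rather than
  asserting which one a vendor prints.
* The replicate-scatter summary (root mean pointwise variance,
  optionally as % of mean fingerprint absorbance) is one of several
  plausible definitions; it is configurable and no published scalar is
  claimed to match.
* JCAMP-DX support covers uncompressed AFFN XYDATA/XYPOINTS only;
  ASDF-compressed files and binary vendor formats are out of scope.
* PLS2, kernel/orthogonal variants, genetic-algorithm wavelength
  selection and prediction intervals are out of scope.
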