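import itertools

import numpy as np
import pytest

from woodspec.model_selection import (
    RegionSearchSpec,
    auto_select_regions,
    enumerate_region_candidates,
    grid_search,
    iterative_outlier_removal,
    mahalanobis_screen,
)
from woodspec.pls_regression import fit_pls, loo_cv
from woodspec.preprocessing import PreprocessConfig, RegionSet, apply_pipeline, restrict
from woodspec.spectra_io import ReferenceTable, SpectraSet
from woodspec.synthetic_data import SimConfig, inject_artifact, simulate_dataset

VN = PreprocessConfig(steps=("vector_normalize",))
WINDOW = RegionSet(((2000.0, 700.0),))


class TestEnumerate:
    def test_default_window_gives_eleven_tiles(self):
        spec = RegionSearchSpec(max_combination=1)
        cands = enumerate_region_candidates(spec)
        assert len(cands) == 11
        assert cands[0].intervals == ((2000.0, 1888.0),)
        assert cands[-1].intervals == ((880.0, 768.0),)
        # the 68 cm^-1 remainder at the low edge is discarded
        assert all(iv[0] - iv[1] == 112.0 for c in cands for iv in c.intervals)

    def test_combination_count_up_to_three(self):
        cands = enumerate_region_candidates(RegionSearchSpec(max_combination=3))
        assert len(cands) == 11 + 55 + 165  # C(11,1)+C(11,2)+C(11,3)

    def test_tile_equal_to_window_gives_single_candidate(self):
        spec = RegionSearchSpec(window=(2000.0, 1888.0), subregion_width=112.0,
                                max_combination=1)
        cands = enumerate_region_candidates(spec)
        assert len(cands) == 1
        assert cands[0].intervals == ((2000.0, 1888.0),)

    def test_window_narrower_than_tile_rejected(self):
        with pytest.raises(ValueError):
            RegionSearchSpec(window=(1000.0, 950.0), subregion_width=112.0)

    def test_ordering_is_deterministic(self):
        a = enumerate_region_candidates(RegionSearchSpec())
        b = enumerate_region_candidates(RegionSearchSpec())
        assert [c.intervals for c in a] == [c.intervals for c in b]


class TestAutoSelect:
    def test_planted_single_tile_signal_is_found(self):
        # only the 1664-1552 tile carries the latent trait; the reference
        # carries measurement noise, everything else is spectral noise
        grid = np.arange(2000.0, 700.0 - 1, -4.0)
        rng = np.random.default_rng(51)
        n = 30
        latent = rng.uniform(23.4, 32.1, size=n)
        X = rng.normal(0, 0.01, size=(n, grid.size))
        tile = (grid <= 1664.0) & (grid >= 1552.0)
        X[:, tile] += np.outer((latent - 27.0) / 27.0, np.full(tile.sum(), 0.5))
        y = latent + rng.normal(0, 0.3, size=n)
        flat = SpectraSet.from_matrix(grid, X, [f"s{i}" for i in range(n)])
        refs = ReferenceTable("lignin_percent", dict(zip(flat.sample_ids, y)))
        region, cv = auto_select_regions(flat, refs, PreprocessConfig(steps=()))
        assert region.intervals == ((1664.0, 1552.0),)
        assert cv.r2_cv > 0.9

    def test_matches_exhaustive_oracle_on_small_spec(self):
        spectra, lig, _ = simulate_dataset(SimConfig(n_samples=16, seed=52))
        spec = RegionSearchSpec(window=(1776.0, 1328.0), subregion_width=112.0,
                                max_combination=2, factor_cap=6)
        region, cv = auto_select_regions(spectra, lig, VN, spec, parsimony="none")
        # brute-force oracle: evaluate every combination independently
        pre = apply_pipeline(spectra, VN)
        y = lig.aligned_to(spectra.sample_ids)
        tiles = [(1776.0 - i * 112.0, 1776.0 - (i + 1) * 112.0) for i in range(4)]
        best = None
        for r in (1, 2):
            for combo in itertools.combinations(tiles, r):
                rs = RegionSet(tuple(combo))
                res = loo_cv(restrict(pre, rs).to_matrix(), y, max_factors=6)
                key = (res.rmsecv, res.n_factors, len(combo))
                if best is None or key < best[0]:
                    best = (key, rs, res)
        assert region.intervals == best[1].intervals
        assert cv.rmsecv == pytest.approx(best[2].rmsecv, abs=1e-12)

    def test_winner_not_worse_than_best_single_tile(self):
        spectra, lig, _ = simulate_dataset(SimConfig(n_samples=24, seed=53))
        spec = RegionSearchSpec(factor_cap=8)
        region, cv = auto_select_regions(spectra, lig, VN, spec)
        singles = enumerate_region_candidates(
            RegionSearchSpec(factor_cap=8, max_combination=1)
        )
        pre = apply_pipeline(spectra, VN)
        y = lig.aligned_to(spectra.sample_ids)
        best_single = min(
            loo_cv(restrict(pre, r).to_matrix(), y, max_factors=8).rmsecv
            for r in singles
        )
        assert cv.rmsecv <= best_single + 1e-12

    def test_all_noise_y_is_reported_not_hidden(self):
        spectra, _, _ = simulate_dataset(SimConfig(n_samples=20, seed=54))
        rng = np.random.default_rng(55)
        noise = ReferenceTable(
            "lignin_percent",
            {sid: 27.0 + rng.normal(0, 1.0) for sid in spectra.sample_ids},
        )
        spec = RegionSearchSpec(max_combination=1, factor_cap=4)
        region, cv = auto_select_regions(spectra, noise, VN, spec)
        assert len(region.intervals) >= 1
        assert cv.r2_cv <= 0.3


class TestGridSearch:
    def test_single_variant_reduces_to_loo_cv(self, small_dataset):
        spectra, lig, _ = small_dataset
        cfg = PreprocessConfig(steps=("vector_normalize",), region=WINDOW)
        report = grid_search(spectra, lig, [("VN", cfg)], max_factors=6)
        direct = loo_cv(
            apply_pipeline(spectra, cfg).to_matrix(),
            lig.aligned_to(spectra.sample_ids),
            max_factors=6,
        )
        assert report.rows["VN"].rmsecv == direct.rmsecv
        assert report.rows["VN"].n_factors == direct.n_factors

    def test_report_is_reproducible_and_ordered(self, small_dataset):
        spectra, lig, _ = small_dataset
        variants = [
            ("raw", PreprocessConfig(steps=(), region=WINDOW)),
            ("VN", PreprocessConfig(steps=("vector_normalize",), region=WINDOW)),
            ("BLC", PreprocessConfig(steps=("rubberband_baseline",), region=WINDOW)),
        ]
        a = grid_search(spectra, lig, variants, max_factors=6).to_frame()
        b = grid_search(spectra, lig, variants, max_factors=6).to_frame()
        assert a.equals(b)  # bitwise reproducible
        assert list(a.columns) == ["raw", "VN", "BLC"]

    def test_empty_variant_list_rejected(self, small_dataset):
        spectra, lig, _ = small_dataset
        with pytest.raises(ValueError):
            grid_search(spectra, lig, [])


class TestMahalanobis:
    def test_limit_formula_exact(self):
        rng = np.random.default_rng(60)
        m = fit_pls(rng.normal(size=(61, 40)), rng.normal(size=61), max_factors=12)
        screen = mahalanobis_screen(m, None, factor=5.0, rank=12)
        assert screen.limit == (5.0 * 12) / 61
        assert screen.limit == pytest.approx(0.98361, abs=5e-6)

    def test_flags_match_limit_comparison(self):
        rng = np.random.default_rng(61)
        m = fit_pls(rng.normal(size=(30, 20)), rng.normal(size=30), max_factors=5)
        screen = mahalanobis_screen(m, None, factor=2.0, rank=5)
        np.testing.assert_array_equal(screen.flags, screen.distances > screen.limit)

    def test_mean_spectrum_has_near_zero_distance(self):
        rng = np.random.default_rng(62)
        X = rng.normal(size=(25, 15))
        m = fit_pls(X, rng.normal(size=25), max_factors=4)
        screen = mahalanobis_screen(m, X.mean(axis=0), factor=5.0, rank=4)
        assert screen.distances[0] < 1e-20
        assert not screen.flags[0]

    def test_calibration_distances_average_rank_over_m(self):
        rng = np.random.default_rng(63)
        m = fit_pls(rng.normal(size=(40, 25)), rng.normal(size=40), max_factors=6)
        screen = mahalanobis_screen(m, None, factor=5.0, rank=6)
        assert screen.distances.mean() == pytest.approx(6 / 40, rel=1e-10)

    @pytest.mark.parametrize("factor_lo,factor_hi", [(2.0, 5.0)])
    def test_limit_monotonicity(self, factor_lo, factor_hi):
        rng = np.random.default_rng(64)
        m = fit_pls(rng.normal(size=(30, 20)), rng.normal(size=30), max_factors=6)
        lo = mahalanobis_screen(m, None, factor=factor_lo, rank=4).limit
        hi = mahalanobis_screen(m, None, factor=factor_hi, rank=4).limit
        assert lo < hi
        r3 = mahalanobis_screen(m, None, factor=5.0, rank=3).limit
        r5 = mahalanobis_screen(m, None, factor=5.0, rank=5).limit
        assert r3 < r5


class TestIterativeRemoval:
    def _spiked(self, seed, n=40, n_bad=2):
        spectra, lig, _ = simulate_dataset(SimConfig(n_samples=n, seed=seed))
        rng = np.random.default_rng(1000 + seed)
        bad = sorted(rng.choice(n, size=n_bad, replace=False).tolist())
        samples = list(spectra.samples)
        for i in bad:
            samples[i] = inject_artifact(samples[i], "spike", 10.0, rng)
        return SpectraSet(tuple(samples)), lig, bad

    def test_clean_set_keeps_everything(self):
        spectra, lig, _ = simulate_dataset(SimConfig(n_samples=30, seed=70))
        recipe = PreprocessConfig(steps=("vector_normalize",), region=WINDOW)
        kept, history = iterative_outlier_removal(spectra, lig, recipe, factor=5.0)
        assert kept == list(range(30))
        assert not history[0].flags.any()

    def test_planted_artifacts_are_the_only_removals(self):
        spectra, lig, bad = self._spiked(seed=71)
        recipe = PreprocessConfig(steps=("vector_normalize",), region=WINDOW)
        kept, _ = iterative_outlier_removal(spectra, lig, recipe, factor=5.0)
        assert sorted(set(range(40)) - set(kept)) == bad

    def test_stricter_factor_removes_at_least_as_many(self):
        spectra, lig, _ = self._spiked(seed=72)
        recipe = PreprocessConfig(steps=("vector_normalize",), region=WINDOW)
        k5, _ = iterative_outlier_removal(spectra, lig, recipe, factor=5.0, max_rounds=10)
        k2, _ = iterative_outlier_removal(spectra, lig, recipe, factor=2.0, max_rounds=10)
        assert len(k2) <= len(k5)

    def test_mass_removal_aborts(self):
        spectra, lig, _ = simulate_dataset(SimConfig(n_samples=12, seed=73))
        rng = np.random.default_rng(74)
        samples = [
            inject_artifact(s, "spike", 10.0, rng) if i < 8 else s
            for i, s in enumerate(spectra.samples)
        ]
        recipe = PreprocessConfig(steps=("vector_normalize",), region=WINDOW)
        with pytest.raises(RuntimeError, match="half"):
            iterative_outlier_removal(
                SpectraSet(tuple(samples)), lig, recipe, factor=0.5, max_rounds=20
            )
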