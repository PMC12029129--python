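"""Simulator tests: composition, augmentation chain, SNR, datasets."""

import numpy as np
import pytest

from nmrquant.distributions import ConcentrationSampler
from nmrquant.reference import DEFAULT_GRID, default_library
from nmrquant.simulator import (
    AugmentationConfig,
    TSP_CONCENTRATION_MM,
    add_baseline,
    add_interference,
    add_noise,
    apply_line_broadening,
    build_dataset,
    compose_mixture,
    compute_snr,
    field_noise_multiplier,
    log_transform,
    normalize_dataset,
    shift_analyte,
)
from nmrquant.workflows import nnls_concentrations


class TestCompose:
    def test_empty_mixture_is_scaled_tsp(self, small_library):
        mix = compose_mixture(small_library, np.zeros(8))
        np.testing.assert_allclose(
            mix.intensity, TSP_CONCENTRATION_MM * small_library.tsp.intensity
        )

    def test_linearity_in_concentration(self, small_library, rng):
        c = rng.uniform(0.1, 5.0, 8)
        one = compose_mixture(small_library, c, include_tsp=False)
        two = compose_mixture(small_library, 2 * c, include_tsp=False)
        np.testing.assert_allclose(two.intensity, 2 * one.intensity, rtol=1e-12)

    def test_single_analyte_identity(self, small_library):
        c = np.zeros(8)
        c[3] = 1.0
        mix = compose_mixture(small_library, c, include_tsp=False)
        np.testing.assert_allclose(mix.intensity, small_library.references[3].intensity)

    def test_negative_concentration_rejected(self, small_library):
        c = np.zeros(8)
        c[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            compose_mixture(small_library, c)


class TestLineBroadening:
    def test_zero_is_identity(self, small_library):
        x = small_library.references[0].intensity
        out = apply_line_broadening(x, 0.0, small_library.grid, 400.0)
        np.testing.assert_allclose(out, x)

    @pytest.mark.parametrize("lb", [0.3, 1.0])
    def test_integral_conserved(self, small_library, lb):
        x = small_library.references[0].intensity
        out = apply_line_broadening(x, lb, small_library.grid, 400.0)
        assert out.sum() == pytest.approx(x.sum(), rel=1e-3)

    def test_peak_height_non_increasing(self, small_library):
        x = small_library.references[0].intensity
        heights = [
            apply_line_broadening(x, lb, small_library.grid, 400.0).max()
            for lb in (0.0, 0.5, 1.0)
        ]
        assert heights[0] >= heights[1] >= heights[2]

    def test_lorentzian_widths_add(self, small_grid):
        """Broadening a w-Hz Lorentzian by lb gives FWHM w + lb within 5%.

        Uses an 8-Hz line so the width spans many grid points (the coarse
        test grid has ~0.9 Hz per point).
        """
        from nmrquant.reference import MultipletSpec, synth_reference

        ref = synth_reference(
            "iso", [MultipletSpec(5.0, 1, "singlet", linewidth=8.0)], small_grid, 400.0
        )
        out = apply_line_broadening(ref.intensity, 8.0, small_grid, 400.0)

        def fwhm_hz(y):
            half = y.max() / 2
            above = np.flatnonzero(y > half)
            # linear interpolation at both crossings
            lo, hi = above[0], above[-1]
            f = small_grid.spacing * 400.0  # Hz per point
            left = lo - 1 + (half - y[lo - 1]) / (y[lo] - y[lo - 1])
            right = hi + (y[hi] - half) / (y[hi] - y[hi + 1])
            return (right - left) * f

        assert fwhm_hz(out) == pytest.approx(16.0, rel=0.05)

    def test_negative_lb_rejected(self, small_grid):
        with pytest.raises(ValueError):
            apply_line_broadening(np.zeros(small_grid.n_points), -0.1, small_grid, 400.0)


class TestShift:
    def test_zero_is_identity(self, small_library):
        x = small_library.references[0].intensity
        out, pts = shift_analyte(x, 0.0, small_library.grid)
        assert pts == 0
        np.testing.assert_array_equal(out, x)

    def test_shift_and_unshift_identity_away_from_edges(self, small_library):
        x = small_library.references[0].intensity
        grid = small_library.grid
        fwd, p1 = shift_analyte(x, 3.0, grid, max_ppb=5)
        back, p2 = shift_analyte(fwd, -3.0, grid, max_ppb=5)
        assert p1 == -p2 != 0
        k = abs(p1)
        np.testing.assert_allclose(back[k:-k], x[k:-k])

    def test_max_shift_is_15_points_on_working_grid(self):
        """3.4 ppb on the 46,000-point grid rounds to 15 grid points."""
        x = np.zeros(DEFAULT_GRID.n_points)
        x[1000] = 1.0
        out, pts = shift_analyte(x, 3.4, DEFAULT_GRID)
        assert pts == 15
        assert out[1015] == 1.0

    def test_beyond_max_rejected(self, small_library):
        with pytest.raises(ValueError, match="exceeds"):
            shift_analyte(small_library.references[0].intensity, 4.0, small_library.grid)


class TestNoiseBaselineInterference:
    def test_zero_noise_identity(self, rng):
        x = np.ones(100)
        np.testing.assert_array_equal(add_noise(x, 0.0, rng), x)

    def test_noise_sd_matches_target(self, rng):
        n = 46_000
        s = 0.37
        out = add_noise(np.zeros(n), s, rng)
        # SE of a sample SD over n points is ~ s / sqrt(2n)
        assert abs(out.std() - s) < 3 * s / np.sqrt(2 * n)

    def test_baseline_shifts_min_and_max(self, rng):
        x = rng.normal(size=500)
        out = add_baseline(x, 0.25)
        assert out.min() == pytest.approx(x.min() + 0.25)
        assert out.max() == pytest.approx(x.max() + 0.25)

    def test_interference_forced_zero_is_identity(self, small_library, rng):
        x = small_library.references[0].intensity
        out, rec = add_interference(x, small_library.grid, 400.0, rng, force_k=0)
        assert rec == []
        np.testing.assert_array_equal(out, x)

    def test_interference_area_matches_concentration(self, small_library, rng):
        """One forced singlet adds area = concentration x unit singlet area."""
        grid = small_library.grid
        base = np.zeros(grid.n_points)
        # a wide singlet so its area is well resolved on the coarse test grid
        out, rec = add_interference(base, grid, 400.0, rng, force_k=1, linewidth_hz=8.0)
        assert len(rec) == 1
        added_area = np.trapezoid(out, dx=grid.spacing)
        assert added_area == pytest.approx(rec[0]["concentration_mM"], rel=0.01)


class TestSnr:
    def test_constructed_snr(self, small_grid):
        x = np.zeros(small_grid.n_points)
        x[small_grid.index_of(4.0)] = 1.0
        rng = np.random.default_rng(0)
        snrs = [
            compute_snr(add_noise(x, 0.01, rng), small_grid) for _ in range(20)
        ]
        assert np.mean(snrs) == pytest.approx(100.0, rel=0.10)

    def test_scale_invariance(self, small_grid, rng):
        x = add_noise(np.zeros(small_grid.n_points), 0.02, rng)
        x[small_grid.index_of(4.0)] += 1.0
        assert compute_snr(3.7 * x, small_grid) == pytest.approx(
            compute_snr(x, small_grid), rel=1e-9
        )

    def test_noise_free_flags_infinite(self, small_grid):
        x = np.zeros(small_grid.n_points)
        x[10] = 1.0
        assert compute_snr(x, small_grid) == np.inf

    def test_snr_ordering_across_fields(self, small_grid):
        """Mean SNR rises with field strength on matched mixtures."""
        means = {}
        for field in (100.0, 400.0, 800.0):
            lib = default_library(4, field_strength=field, seed=5, grid=small_grid)
            ds = build_dataset(
                lib, 10, ConcentrationSampler("uniform"), seed=9, normalize=False
            )
            means[field] = np.mean([compute_snr(s, small_grid) for s in ds.intensities])
        assert means[100.0] < means[400.0] < means[800.0]


class TestFieldNoise:
    @pytest.mark.parametrize(
        "field,expect", [(400.0, 1.0), (100.0, 8.0), (800.0, 0.5**1.5)]
    )
    def test_multiplier(self, field, expect):
        assert field_noise_multiplier(field) == pytest.approx(expect, rel=1e-12)

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            field_noise_multiplier(0.0)


class TestLogTransform:
    def test_values_and_monotonicity(self):
        x = np.array([0.0, 1.0])
        out = log_transform(x)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.log10(1001.0))
        grid = np.linspace(0, 1, 100)
        assert np.all(np.diff(log_transform(grid)) > 0)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            log_transform(np.array([0.0, -0.002]))

    def test_dataset_modification_in_place(self, small_library):
        ds = build_dataset(
            small_library, 4, ConcentrationSampler("uniform"),
            augmentation=AugmentationConfig.disabled(), seed=6,
        )
        raw = ds.intensities.copy()
        ds.apply_log_transform()
        np.testing.assert_allclose(ds.intensities, np.log10(1 + 1000 * raw), rtol=1e-6)
        assert ds.manifest["log_transformed"]


class TestDataset:
    def test_deterministic_generation(self, small_library):
        kw = dict(
            sampler=ConcentrationSampler("combined"), leave_out_scheme="half50", seed=21
        )
        a = build_dataset(small_library, 20, **kw)
        b = build_dataset(small_library, 20, **kw)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(a.truth_mM, b.truth_mM)
        assert a.records == b.records

    def test_split_sizes_80_20(self, small_library):
        ds = build_dataset(small_library, 50, ConcentrationSampler("uniform"), seed=1)
        assert len(ds.train_idx) == 40 and len(ds.val_idx) == 10
        assert set(ds.train_idx) | set(ds.val_idx) == set(range(50))
        assert not set(ds.train_idx) & set(ds.val_idx)

    def test_all_present_truth_strictly_positive(self, clean_dataset):
        assert np.all(clean_dataset.truth_mM > 0)

    def test_normalization_global_max_one(self, augmented_dataset):
        assert augmented_dataset.intensities.max() == pytest.approx(1.0)

    def test_normalize_preserves_ratios(self, small_library):
        ds = build_dataset(
            small_library, 5, ConcentrationSampler("uniform"), seed=2, normalize=False
        )
        before = ds.intensities[0, 100] / ds.intensities[1, 200]
        normalize_dataset(ds)
        after = ds.intensities[0, 100] / ds.intensities[1, 200]
        assert after == pytest.approx(before, rel=1e-12)

    def test_augmentation_records_within_bounds(self, augmented_dataset):
        cfg = AugmentationConfig()
        tsp_height = None
        for rec in augmented_dataset.records:
            assert cfg.lb_range_hz[0] <= rec["lb_hz"] <= cfg.lb_range_hz[1]
            assert cfg.noise_fraction_range[0] <= rec["noise_fraction"] <= cfg.noise_fraction_range[1]
            assert all(abs(s) <= cfg.shift_max_ppb for s in rec["shift_ppb"])
            assert len(rec["interference"]) <= cfg.max_interference_singlets

    def test_dataset_save_load_round_trip(self, clean_dataset, tmp_path):
        clean_dataset.save(tmp_path / "ds")
        from nmrquant.simulator import SpectralDataset

        back = SpectralDataset.load(tmp_path / "ds")
        np.testing.assert_allclose(back.intensities, clean_dataset.intensities)
        np.testing.assert_allclose(back.truth_mM, clean_dataset.truth_mM)
        np.testing.assert_array_equal(back.train_idx, clean_dataset.train_idx)

    def test_nnls_recovers_clean_concentrations(self, small_library, clean_dataset):
        """With augmentation off, NNLS on the library is exact to <0.1%."""
        est = nnls_concentrations(small_library, clean_dataset.intensities)
        rel = np.abs(est - clean_dataset.truth_mM) / clean_dataset.truth_mM
        assert rel.max() < 1e-3
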