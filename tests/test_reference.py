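"""Reference-library tests: grids, multiplet synthesis, anomers, file IO."""

import numpy as np
import pytest

from nmrquant.reference import (
    DEFAULT_GRID,
    MetaboliteLibrary,
    MultipletSpec,
    combine_anomers,
    default_library,
    load_reference,
    make_ppm_grid,
    save_reference,
    synth_reference,
    tsp_reference,
)


class TestPpmGrid:
    @pytest.mark.parametrize(
        "lo,hi,n,first,last,spacing",
        [
            (-0.32, 10.21, 46000, -0.32, 10.21, (10.21 + 0.32) / 45999),
            (0.0, 1.0, 2, 0.0, 1.0, 1.0),
            (0.0, 10.0, 11, 0.0, 10.0, 1.0),
        ],
    )
    def test_endpoints_and_spacing(self, lo, hi, n, first, last, spacing):
        grid = make_ppm_grid(lo, hi, n)
        assert grid.ppm[0] == first
        assert grid.ppm[-1] == last
        assert grid.n_points == n
        assert grid.spacing == pytest.approx(spacing)
        assert np.all(np.diff(grid.ppm) > 0)

    @pytest.mark.parametrize("lo,hi,n", [(1.0, 0.0, 10), (0.0, 1.0, 1), (2.0, 2.0, 5)])
    def test_rejects_bad_bounds(self, lo, hi, n):
        with pytest.raises(ValueError):
            make_ppm_grid(lo, hi, n)


class TestSynthReference:
    def test_tsp_singlet_area_and_position(self, small_grid):
        ref = tsp_reference(small_grid, 400.0)
        assert ref.integral() == pytest.approx(9.0, rel=0.01)
        assert small_grid.ppm[np.argmax(ref.intensity)] == pytest.approx(0.0, abs=small_grid.spacing)

    def test_doublet_splitting_is_J_over_field(self, small_grid):
        """Two equal-area lines separated by J/field ppm."""
        m = MultipletSpec(center=5.0, n_protons=1, pattern="doublet", J=7.0)
        ref = synth_reference("x", [m], small_grid, 400.0)
        ppm = small_grid.ppm
        # the two maxima straddle the center
        left = ppm[ppm < 5.0][np.argmax(ref.intensity[ppm < 5.0])]
        right = ppm[ppm >= 5.0][np.argmax(ref.intensity[ppm >= 5.0])]
        assert right - left == pytest.approx(7.0 / 400.0, abs=small_grid.spacing)

    @pytest.mark.parametrize("field,factor", [(100.0, 8.0), (800.0, 1.0)])
    def test_splitting_scales_inversely_with_field(self, small_grid, field, factor):
        sep_at = {}
        for f in (field, 800.0):
            m = MultipletSpec(center=5.0, n_protons=1, pattern="doublet", J=20.0)
            ref = synth_reference("x", [m], small_grid, f)
            ppm = small_grid.ppm
            left = ppm[ppm < 5.0][np.argmax(ref.intensity[ppm < 5.0])]
            right = ppm[ppm >= 5.0][np.argmax(ref.intensity[ppm >= 5.0])]
            sep_at[f] = right - left
        assert sep_at[field] / sep_at[800.0] == pytest.approx(factor, rel=0.05)

    def test_area_proportional_to_proton_count(self, small_grid):
        """Integral ratios equal proton-count ratios within 1%."""
        refs = [
            synth_reference(
                f"m{n}", [MultipletSpec(center=4.0, n_protons=n, pattern="triplet", J=6.0)],
                small_grid, 400.0,
            )
            for n in (1, 3, 6)
        ]
        base = refs[0].integral()
        for n, ref in zip((1, 3, 6), refs):
            assert ref.integral() / base == pytest.approx(n, rel=0.01)

    def test_line_outside_grid_truncated_with_warning(self, small_grid):
        m = MultipletSpec(center=11.5, n_protons=2, pattern="singlet")
        with pytest.warns(UserWarning, match="truncated"):
            ref = synth_reference("oob", [m], small_grid, 400.0)
        assert ref.integral() == pytest.approx(0.0, abs=1e-12)

    def test_empty_multiplets_zero_spectrum_with_warning(self, small_grid):
        with pytest.warns(UserWarning, match="zero reference"):
            ref = synth_reference("empty", [], small_grid, 400.0)
        assert np.all(ref.intensity == 0)

    def test_negative_protons_rejected(self):
        with pytest.raises(ValueError):
            MultipletSpec(center=1.0, n_protons=0)


class TestCombineAnomers:
    def test_equal_inputs_are_identity(self, small_grid):
        a = tsp_reference(small_grid, 400.0)
        out = combine_anomers(a, a)
        np.testing.assert_allclose(out.intensity, a.intensity)

    def test_default_weights_recovered_by_regression(self, small_grid):
        """Least squares on non-collinear anomers returns (0.36, 0.64)."""
        alpha = synth_reference(
            "alpha", [MultipletSpec(5.22, 1, "doublet", J=3.8)], small_grid, 400.0
        )
        beta = synth_reference(
            "beta", [MultipletSpec(4.63, 1, "doublet", J=8.0)], small_grid, 400.0
        )
        combined = combine_anomers(alpha, beta)
        A = np.stack([alpha.intensity, beta.intensity], axis=1)
        coef, *_ = np.linalg.lstsq(A, combined.intensity, rcond=None)
        np.testing.assert_allclose(coef, [0.36, 0.64], atol=1e-9)

    def test_complementary_weights_are_order_independent(self, small_grid):
        alpha = synth_reference("a", [MultipletSpec(5.2, 1)], small_grid, 400.0)
        beta = synth_reference("b", [MultipletSpec(4.6, 1)], small_grid, 400.0)
        ab = combine_anomers(alpha, beta, 0.36)
        ba = combine_anomers(beta, alpha, 0.64)
        np.testing.assert_allclose(ab.intensity, ba.intensity)

    def test_grid_mismatch_rejected(self, small_grid):
        other = make_ppm_grid(-0.32, 10.21, 2300)
        a = tsp_reference(small_grid, 400.0)
        b = tsp_reference(other, 400.0)
        with pytest.raises(ValueError, match="grid"):
            combine_anomers(a, b)


class TestLoadReference:
    def test_round_trip(self, small_grid, tmp_path):
        ref = tsp_reference(small_grid, 400.0)
        save_reference(ref, tmp_path / "tsp.csv")
        back = load_reference(tmp_path / "tsp.csv", small_grid)
        np.testing.assert_allclose(back.intensity, ref.intensity, rtol=1e-10)

    def test_partial_coverage_zero_padded(self, small_grid, tmp_path):
        p = tmp_path / "part.csv"
        p.write_text("ppm,intensity\n0.0,1.0\n2.5,1.0\n5.0,1.0\n")
        ref = load_reference(p, small_grid)
        ppm = small_grid.ppm
        assert np.all(ref.intensity[ppm < -0.001] == 0)
        assert np.all(ref.intensity[ppm > 5.001] == 0)
        assert ref.intensity[small_grid.index_of(2.5)] == pytest.approx(1.0, rel=1e-3)

    def test_two_rows_interpolate_linearly(self, tmp_path):
        grid = make_ppm_grid(0.0, 1.0, 11)
        p = tmp_path / "ramp.csv"
        p.write_text("ppm,intensity\n0.0,0.0\n1.0,10.0\n")
        ref = load_reference(p, grid)
        np.testing.assert_allclose(ref.intensity, np.linspace(0, 10, 11), atol=1e-12)

    def test_non_monotone_rejected_with_line(self, small_grid, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ppm,intensity\n0.0,1.0\n2.0,1.0\n1.0,1.0\n")
        with pytest.raises(ValueError, match="monotone"):
            load_reference(p, small_grid)

    def test_non_numeric_rejected_with_line(self, small_grid, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ppm,intensity\n0.0,1.0\nfoo,2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            load_reference(p, small_grid)


class TestDefaultLibrary:
    def test_deterministic_for_seed(self, small_grid):
        a = default_library(8, 400.0, seed=1, grid=small_grid)
        b = default_library(8, 400.0, seed=1, grid=small_grid)
        np.testing.assert_array_equal(a.matrix(), b.matrix())
        assert a.names == b.names

    @pytest.mark.parametrize("n", [8, 44])
    def test_panel_sizes_and_tsp(self, small_grid, n):
        lib = default_library(n, 400.0, seed=2, grid=small_grid)
        assert lib.n_analytes == n
        assert len(set(lib.names)) == n
        assert lib.tsp is not None
        assert lib.tsp.name not in lib.names  # TSP is a non-analyte entry

    def test_contains_overlapping_pair(self, small_library):
        """For panels >= 8, two metabolites share a resonance region."""
        m0 = small_library.multiplet_table[small_library.names[0]][0]
        m1 = small_library.multiplet_table[small_library.names[1]][0]
        assert abs(m0.center - m1.center) < 0.05

    def test_library_save_load_round_trip(self, small_library, tmp_path):
        small_library.save(tmp_path / "lib")
        back = MetaboliteLibrary.load(tmp_path / "lib")
        assert back.names == small_library.names
        np.testing.assert_allclose(back.matrix(), small_library.matrix(), rtol=1e-10)
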