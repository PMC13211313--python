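"""Spectrum containers, normalization, rendering and HSQC reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmr2struct.spectra import (
    Nucleus,
    PeakList1D,
    PeakListHSQC,
    PpmGrid,
    Spectrum1D,
    normalize_instance,
    reconstruct_hsqc,
    render_peaklist_1d,
    zero_windows,
)


def spec1d(values, nucleus=Nucleus.H1):
    grid = PpmGrid(0.0, 10.0, len(values))
    return Spectrum1D(nucleus, grid, np.asarray(values, dtype=float))


class TestPpmGrid:
    def test_values_are_evenly_spaced_with_inclusive_endpoints(self):
        g = PpmGrid(-2.0, 12.0, 8)
        v = g.values()
        assert v[0] == -2.0 and v[-1] == 12.0
        assert np.allclose(np.diff(v), g.step)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            PpmGrid(0.0, 1.0, 1)
        with pytest.raises(ValueError):
            PpmGrid(2.0, 2.0, 10)

    def test_index_of_nearest(self):
        g = PpmGrid(0.0, 10.0, 11)
        assert g.index_of(3.2) == 3
        assert g.index_of(-5.0) == 0
        assert g.index_of(99.0) == 10


class TestNormalize:
    def test_linear_rescale(self):
        out = normalize_instance(spec1d([0.0, 2.0, 4.0]))
        assert np.allclose(out.intensities, [0.0, 0.5, 1.0])
        assert out.normalized

    def test_idempotent(self):
        out = normalize_instance(spec1d([0.0, 0.5, 1.0]))
        assert np.allclose(out.intensities, [0.0, 0.5, 1.0])

    def test_constant_spectrum_maps_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_instance(spec1d([7.0, 7.0, 7.0]))
        assert np.all(out.intensities == 0.0)

    @given(
        a=st.floats(0.1, 100.0),
        b=st.floats(-50.0, 50.0),
        data=st.lists(st.floats(-10, 10), min_size=3, max_size=30),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positive_affine_invariance(self, a, b, data):
        x = np.asarray(data)
        if np.ptp(x) < 1e-6:
            return
        base = normalize_instance(spec1d(x)).intensities
        scaled = normalize_instance(spec1d(a * x + b)).intensities
        assert np.allclose(base, scaled, atol=1e-9)


class TestRender1D:
    def test_single_peak_peaks_at_nearest_grid_point(self):
        grid = PpmGrid(0.0, 10.0, 1001)
        out = render_peaklist_1d(PeakList1D(Nucleus.H1, [(2.0, 1.0)]), grid, 0.05)
        assert out.intensities.argmax() == grid.index_of(2.0)
        assert out.intensities.max() == 1.0

    def test_two_equal_distant_peaks_give_two_unit_maxima(self):
        grid = PpmGrid(0.0, 10.0, 2001)
        out = render_peaklist_1d(
            PeakList1D(Nucleus.H1, [(2.0, 1.0), (8.0, 1.0)]), grid, 0.05
        )
        i1, i2 = grid.index_of(2.0), grid.index_of(8.0)
        assert out.intensities[i1] == pytest.approx(1.0)
        assert out.intensities[i2] == pytest.approx(1.0)
        assert out.intensities[grid.index_of(5.0)] < 1e-6

    def test_matches_brute_force_double_loop(self):
        # close peaks, checked pointwise against an independent O(NP) sum
        grid = PpmGrid(0.5, 1.5, 401)
        peaks = [(1.0, 1.0), (1.001, 1.0)]
        sigma = 0.01
        out = render_peaklist_1d(PeakList1D(Nucleus.H1, peaks), grid, sigma)
        expected = np.zeros(grid.n_points)
        for j in range(grid.n_points):
            d = grid.start_ppm + j * grid.step
            for shift, inten in peaks:
                expected[j] += inten * np.exp(-((d - shift) ** 2) / (2 * sigma**2))
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(out.intensities, expected, atol=1e-12)

    def test_empty_peaklist_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            out = render_peaklist_1d(PeakList1D(Nucleus.H1, []), PpmGrid(0, 10, 50), 0.1)
        assert np.all(out.intensities == 0.0) and not out.normalized

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            render_peaklist_1d(PeakList1D(Nucleus.H1, [(1, 1)]), PpmGrid(0, 10, 50), 0.0)


class TestReconstructHSQC:
    h_grid = PpmGrid(0.0, 12.0, 64)
    c_grid = PpmGrid(0.0, 200.0, 64)

    def test_single_peak_populates_one_carbon_column(self):
        out = reconstruct_hsqc(
            PeakListHSQC([(3.0, 50.0, 1.0)]), self.h_grid, self.c_grid,
            h_sigma=0.2, power=1.0,
        )
        col = self.c_grid.index_of(50.0)
        nonzero_cols = np.where(out.intensities.max(axis=0) > 1e-9)[0]
        assert list(nonzero_cols) == [col]
        profile = out.intensities[:, col]
        assert profile.max() == pytest.approx(1.0)
        assert profile.argmax() == self.h_grid.index_of(3.0)

    def test_power_compression_ratio(self):
        # distinct columns: pre-normalization maxima scale as I^0.3
        out = reconstruct_hsqc(
            PeakListHSQC([(3.0, 50.0, 1.0), (7.0, 150.0, 0.001)]),
            self.h_grid, self.c_grid, h_sigma=0.2, power=0.3,
        )
        strong = out.intensities[:, self.c_grid.index_of(50.0)].max()
        weak = out.intensities[:, self.c_grid.index_of(150.0)].max()
        assert weak / strong == pytest.approx(0.001**0.3, rel=1e-6)

    def test_power_one_is_identity_rescaling(self):
        peaks = PeakListHSQC([(2.0, 30.0, 0.5), (5.0, 120.0, 2.0)])
        a = reconstruct_hsqc(peaks, self.h_grid, self.c_grid, 0.2, power=1.0)
        raw = np.zeros((64, 64))
        hv = self.h_grid.values()
        for h, c, inten in peaks.peaks:
            raw[:, self.c_grid.index_of(c)] += inten * np.exp(
                -((hv - h) ** 2) / (2 * 0.2**2)
            )
        raw = raw / raw.max()
        assert np.allclose(a.intensities, raw, atol=1e-12)

    def test_power_preserves_intensity_ranking(self):
        peaks = PeakListHSQC([(2.0, 30.0, 0.5), (5.0, 120.0, 2.0), (8.0, 80.0, 1.0)])
        p1 = reconstruct_hsqc(peaks, self.h_grid, self.c_grid, 0.2, power=1.0)
        p03 = reconstruct_hsqc(peaks, self.h_grid, self.c_grid, 0.2, power=0.3)
        order1 = np.argsort(p1.intensities.ravel())
        order03 = np.argsort(p03.intensities.ravel())
        assert np.array_equal(
            p1.intensities.ravel()[order1] > 0, p03.intensities.ravel()[order03] > 0
        )
        # rank correlation of positive cells is exact
        pos = p1.intensities.ravel() > 0
        r1 = np.argsort(np.argsort(p1.intensities.ravel()[pos]))
        r03 = np.argsort(np.argsort(p03.intensities.ravel()[pos]))
        assert np.array_equal(r1, r03)

    def test_out_of_range_peak_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            out = reconstruct_hsqc(
                PeakListHSQC([(50.0, 500.0, 1.0)]), self.h_grid, self.c_grid, 0.2
            )
        assert np.all(out.intensities == 0.0)

    def test_empty_list_gives_zero_matrix(self):
        with pytest.warns(UserWarning, match="empty"):
            out = reconstruct_hsqc(PeakListHSQC([]), self.h_grid, self.c_grid, 0.2)
        assert np.all(out.intensities == 0.0)


def test_zero_windows_removes_solvent_region():
    grid = PpmGrid(0.0, 10.0, 1001)
    out = render_peaklist_1d(
        PeakList1D(Nucleus.H1, [(7.26, 1.0), (2.0, 1.0)]), grid, 0.01
    )
    cleaned = zero_windows(out)
    assert cleaned.intensities[grid.index_of(7.26)] == 0.0
    assert cleaned.intensities[grid.index_of(2.0)] > 0.9


def test_negative_peak_intensity_rejected():
    with pytest.raises(ValueError, match="intensity"):
        PeakList1D(Nucleus.H1, [(1.0, -0.5)])
    with pytest.raises(ValueError, match="intensity"):
        PeakListHSQC([(1.0, 10.0, -1.0)])
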