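import numpy as np
import pytest

from orthofusion.degrade import (
    DegradeSpec,
    lanczos_kernel,
    make_orthogonal_clinical_set,
    reslice_lanczos,
    simulate_clinical,
)
from orthofusion.grid import VoxelGrid, Volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def hr_volume(values=None, n=60, spacing=0.6):
    grid = VoxelGrid((8, 8, n), (spacing, spacing, spacing))
    if values is None:
        values = np.full(grid.shape, 800.0)
    return Volume(grid, values)


class TestSimulateClinical:
    def test_constant_volume_preserved(self):
        out = simulate_clinical(hr_volume(), DegradeSpec(through_axis=2))
        assert out.grid.shape[:2] == (8, 8)
        np.testing.assert_allclose(out.values, 800.0, rtol=1e-9)

    def test_slice_center_counting_oracle(self):
        """60 slices at 0.6 mm span 35.4 mm -> floor(35.4/3)+1 = 12 slices."""
        out = simulate_clinical(hr_volume(n=60), DegradeSpec(target_thickness=3.0))
        assert out.grid.shape == (8, 8, 12)
        assert out.grid.spacing == (0.6, 0.6, 3.0)

    def test_impulse_profile_matches_gaussian_oracle(self):
        """A single bright slice maps to normalized exp(-d^2/2s^2) weights."""
        n, spacing, thickness = 60, 0.6, 3.0
        values = np.zeros((8, 8, n))
        values[:, :, 30] = 1.0
        spec = DegradeSpec(target_thickness=thickness)
        out = simulate_clinical(hr_volume(values, n=n), spec)
        sigma = thickness * FWHM_TO_SIGMA
        src = np.arange(n) * spacing
        centers = np.arange(out.grid.shape[2]) * thickness
        expected = []
        for c in centers:
            w = np.exp(-((src - c) ** 2) / (2 * sigma**2))
            expected.append(w[30] / w.sum())
        np.testing.assert_allclose(out.values[3, 3, :], expected, rtol=1e-9)

    def test_values_stay_within_source_range(self, rng):
        values = rng.uniform(-100, 1500, (8, 8, 60))
        out = simulate_clinical(hr_volume(values), DegradeSpec())
        assert out.values.min() >= values.min() - 1e-9
        assert out.values.max() <= values.max() + 1e-9

    def test_mean_intensity_preserved_on_periodic_texture(self, rng):
        """Energy check: blur+decimate keeps the mean of a periodic texture."""
        z = np.sin(2 * np.pi * np.arange(60) / 10.0)
        values = 300.0 + 50.0 * np.broadcast_to(z, (8, 8, 60)).copy()
        out = simulate_clinical(hr_volume(values), DegradeSpec())
        assert abs(out.values.mean() - values.mean()) / abs(values.mean()) < 0.01

    def test_thinner_than_source_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            simulate_clinical(hr_volume(spacing=3.0), DegradeSpec(target_thickness=1.0))

    def test_equal_thickness_with_no_blur_is_identity(self, rng):
        values = rng.normal(size=(8, 8, 20))
        spec = DegradeSpec(target_thickness=0.6, blur_fwhm=0.0)
        out = simulate_clinical(hr_volume(values, n=20), spec)
        np.testing.assert_allclose(out.values, values, atol=1e-12)


class TestResliceLanczos:
    def clin(self, values=None, n=12):
        grid = VoxelGrid((8, 8, n), (0.6, 0.6, 3.0))
        if values is None:
            values = np.full(grid.shape, 800.0)
        return Volume(grid, values)

    def test_kernel_is_interpolating(self):
        x = np.arange(-5, 6)
        np.testing.assert_allclose(lanczos_kernel(x, 3), (x == 0).astype(float), atol=1e-12)

    def test_source_slice_centers_unchanged(self, rng):
        values = rng.normal(size=(8, 8, 12))
        out = reslice_lanczos(self.clin(values), DegradeSpec(reslice_spacing=0.6))
        # every 5th output slice coincides with a source slice center
        np.testing.assert_allclose(out.values[:, :, ::5], values, atol=1e-12)

    def test_constant_preserved_despite_boundary(self):
        out = reslice_lanczos(self.clin(), DegradeSpec(reslice_spacing=0.6))
        np.testing.assert_allclose(out.values, 800.0, rtol=1e-9)

    def test_midpoint_matches_brute_force_kernel_sum(self, rng):
        """Mid-slice samples equal the oracle sum of sinc(x)sinc(x/a) taps."""
        profile = rng.normal(size=12)
        values = np.broadcast_to(profile, (8, 8, 12)).copy()
        spec = DegradeSpec(reslice_spacing=1.5, lanczos_a=3)
        out = reslice_lanczos(self.clin(values), spec)
        # output slice 1 sits at 1.5 mm = source index 0.5 (a midpoint)
        s = 0.5
        taps = np.arange(int(np.ceil(s - 3)), int(np.floor(s + 3)) + 1)
        taps = taps[(taps >= 0) & (taps < 12)]
        w = np.sinc(s - taps) * np.sinc((s - taps) / 3)
        oracle = float(np.dot(w, profile[taps]) / w.sum())
        assert out.values[4, 4, 1] == pytest.approx(oracle, rel=1e-9)

    def test_overshoot_bounded_by_kernel_l1_mass(self, rng):
        """Negative lobes may overshoot, but no further than the kernel allows."""
        values = np.zeros((8, 8, 12))
        values[:, :, 6:] = 1000.0  # step edge along z
        out = reslice_lanczos(self.clin(values), DegradeSpec(reslice_spacing=0.6))
        l1 = max(
            np.abs(w).sum() / w.sum()
            for off in np.linspace(0.0, 1.0, 21)
            for w in [lanczos_kernel(np.arange(-4, 5, dtype=float) + off, 3)]
        )
        bound = 1000.0 * (l1 + 1) / 2  # max step response of a renormalized kernel
        assert out.values.max() <= bound + 1e-9
        assert out.values.min() >= 1000.0 - bound - 1e-9

    def test_coarser_than_source_rejected(self):
        with pytest.raises(ValueError, match="reslice"):
            reslice_lanczos(self.clin(), DegradeSpec(reslice_spacing=4.0))


class TestOrthogonalSet:
    def test_constant_volume_permuted_spacings(self):
        grid = VoxelGrid((40, 40, 40), (0.6, 0.6, 0.6))
        hr = Volume(grid, np.full(grid.shape, 250.0))
        out = make_orthogonal_clinical_set(hr, DegradeSpec())
        spacings = [v.grid.spacing for v in out]
        assert spacings[0] == (3.0, 0.6, 0.6)
        assert spacings[1] == (0.6, 3.0, 0.6)
        assert spacings[2] == (0.6, 0.6, 3.0)
        for v in out:
            np.testing.assert_allclose(v.values, 250.0, rtol=1e-9)

    def test_matches_direct_per_axis_calls(self, rng):
        from dataclasses import replace

        grid = VoxelGrid((30, 30, 30), (0.6, 0.6, 0.6))
        hr = Volume(grid, rng.normal(500, 100, grid.shape))
        spec = DegradeSpec()
        out = make_orthogonal_clinical_set(hr, spec)
        for axis in range(3):
            direct = simulate_clinical(hr, replace(spec, through_axis=axis))
            np.testing.assert_array_equal(out[axis].values, direct.values)

    def test_shapes_match_counting_oracle_per_axis(self):
        grid = VoxelGrid((31, 45, 60), (0.6, 0.6, 0.6))
        hr = Volume(grid, np.zeros(grid.shape))
        out = make_orthogonal_clinical_set(hr, DegradeSpec(target_thickness=3.0))
        for axis in range(3):
            span = (grid.shape[axis] - 1) * 0.6
            expected = int(np.floor(span / 3.0 + 1e-9)) + 1
            assert out[axis].grid.shape[axis] == expected
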