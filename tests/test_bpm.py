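"""Split-step propagator: identities, oracles, conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sheetwave.bpm import PropagatorConfig, free_space_step, phase_screen_step, propagate
from sheetwave.fields import PupilSpec, SourceSpec, make_field
from sheetwave.grid import ComplexField, Grid3D, RefractiveVolume
from sheetwave.oracles import direct_diffraction, gaussian_beam_fwhm
from sheetwave.phantoms import make_perlin_tissue

from conftest import fwhm_1d, vacuum_volume


def gaussian_field(grid, w0, wavelength):
    y = grid.y_coords()[:, None]
    x = grid.x_coords()[None, :]
    return ComplexField(
        values=np.exp(-(x**2 + y**2) / w0**2),
        dx=grid.dx,
        dy=grid.dy,
        wavelength=wavelength,
    )


class TestFreeSpaceStep:
    def test_zero_distance_is_identity(self):
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        out = free_space_step(f, 0.0, 1.0)
        np.testing.assert_array_equal(out.values, f.values)

    def test_plane_wave_eigenmode(self):
        """An on-axis plane wave keeps uniform intensity and advances in
        phase by n0*k0*dz."""
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = ComplexField(
            values=np.ones(grid.transverse_shape, dtype=complex),
            dx=grid.dx,
            dy=grid.dy,
            wavelength=0.5,
        )
        dz, n0 = 3.7, 1.4
        out = free_space_step(f, dz, n0)
        expected = np.exp(1j * n0 * f.k0 * dz)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_gaussian_beam_width_matches_closed_form(self):
        """Beam expansion over ~1 Rayleigh range follows
        w(z) = w0 sqrt(1+(z/zR)^2) within 2%."""
        wavelength, w0 = 0.5, 2.0
        grid = Grid3D(nx=128, ny=128, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, w0, wavelength)
        out = free_space_step(f, 20.0, 1.0)
        measured = fwhm_1d(np.abs(out.values[64]) ** 2, grid.dx)
        expected = gaussian_beam_fwhm(w0, wavelength, 1.0, 20.0)
        assert abs(measured - expected) / expected < 0.02

    def test_matches_rayleigh_sommerfeld_oracle(self):
        """Angular-spectrum step equals the direct spherical-wave sum on
        a 64^2 grid to < 1e-3 relative L2."""
        grid = Grid3D(nx=64, ny=64, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        z = 20.0
        a = free_space_step(f, z, 1.0)
        b = direct_diffraction(f, z, 1.0)
        err = np.linalg.norm(a.values - b.values) / np.linalg.norm(b.values)
        assert err < 1e-3

    def test_invalid_inputs(self):
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        with pytest.raises(ValueError):
            free_space_step(f, 1.0, -1.0)
        bad = f.copy()
        bad.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            free_space_step(bad, 1.0, 1.0)

    @settings(max_examples=10, deadline=None)
    @given(
        dz1=st.floats(0.1, 5.0),
        dz2=st.floats(0.1, 5.0),
        n0=st.floats(1.0, 1.5),
    )
    def test_composition_and_band_power(self, dz1, dz2, n0):
        """Two steps compose into one, and power in the propagating band
        is conserved to 1e-10."""
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 1.5, 0.5)
        two = free_space_step(free_space_step(f, dz1, n0), dz2, n0)
        one = free_space_step(f, dz1 + dz2, n0)
        assert np.linalg.norm(two.values - one.values) <= 1e-10 * np.linalg.norm(
            one.values
        )
        # band-limit once, then power must be conserved exactly
        f_band = free_space_step(f, 0.1, n0)
        stepped = free_space_step(f_band, dz1, n0)
        assert abs(stepped.power() - f_band.power()) <= 1e-10 * f_band.power()


class TestPhaseScreen:
    def test_reference_index_is_identity(self):
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        out = phase_screen_step(f, np.full(f.shape, 1.4), 1.4, 0.7)
        np.testing.assert_array_equal(out.values, f.values)

    def test_uniform_slab_accumulates_exact_phase(self):
        """A dn=0.05 slab (the m=1.05 contrast regime) accumulated over
        many steps delays the on-axis phase by exactly k0*dn*d."""
        grid = Grid3D(nx=16, ny=16, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = ComplexField(
            values=np.ones(grid.transverse_shape, dtype=complex),
            dx=grid.dx,
            dy=grid.dy,
            wavelength=0.5,
        )
        dn, dz, steps = 0.05, 0.1, 40
        out = f
        for _ in range(steps):
            out = phase_screen_step(out, np.full(f.shape, 1.33 + dn), 1.33, dz)
        accumulated = np.angle(out.values[0, 0] / f.values[0, 0])
        expected = (f.k0 * dn * dz * steps) % (2 * np.pi)
        expected = expected if expected <= np.pi else expected - 2 * np.pi
        assert abs(accumulated - expected) < 1e-12

    def test_absorbing_slice_scales_beer_lambert(self):
        grid = Grid3D(nx=16, ny=16, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 1.0, 0.5)
        kappa, dz = 2e-3, 0.4
        out = phase_screen_step(f, np.full(f.shape, 1.33 + 1j * kappa), 1.33, dz)
        ratio = np.abs(out.values) / np.abs(f.values)
        np.testing.assert_allclose(ratio, np.exp(-f.k0 * kappa * dz), rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        grid = Grid3D(nx=16, ny=16, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 1.0, 0.5)
        with pytest.raises(ValueError):
            phase_screen_step(f, np.ones((8, 8)), 1.33, 0.1)


class TestPropagate:
    def test_homogeneous_volume_reduces_to_free_space(self):
        """Propagation through a uniform volume is bitwise the chain of
        half-step diffraction kernels (phase screens are exactly 1)."""
        grid = Grid3D(nx=32, ny=32, nz=10, dx=0.25, dy=0.25, dz=0.25)
        vol = vacuum_volume(grid, 1.33)
        f = gaussian_field(grid, 2.0, 0.5)
        res = propagate(f, vol, PropagatorConfig(n_ref_mode="global"))
        chained = f
        for _ in range(grid.nz):
            chained = free_space_step(chained, grid.dz / 2, 1.33)
            chained = free_space_step(chained, grid.dz / 2, 1.33)
        np.testing.assert_array_equal(res.final.values, chained.values)

    def test_pitch_mismatch_rejected(self):
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        f.dx = 0.3
        with pytest.raises(ValueError):
            propagate(f, vacuum_volume(grid))

    def test_unitarity_in_lossless_scattering_volume(self):
        """On a grid whose whole Fourier plane is propagating, power is
        conserved through a lossless scattering medium to 1e-10/step."""
        grid = Grid3D(nx=64, ny=64, nz=48, dx=0.3, dy=0.3, dz=0.3)
        vol = make_perlin_tissue(
            grid, mean_n=1.36, amplitude=0.03, correlation_length=1.0, seed=2,
            n_ambient=1.36,
        ).refractive
        f = make_field(
            SourceSpec(
                kind="plane_wave",
                pupil=PupilSpec(na=1e-6, wavelength=0.5, n0=1.36),
            ),
            grid,
        )
        res = propagate(f, vol, PropagatorConfig(n_ref_mode="per_slice_mean"))
        drift = np.abs(res.plane_power - res.plane_power[0]) / res.plane_power[0]
        assert drift.max() < 1e-10

    def test_paraxial_limit_matches_fresnel_kernel(self):
        """For an NA<=0.05 beam the exact propagator and the Fresnel
        (paraxial) kernel agree to 1e-4 over 100 um."""
        from scipy import fft as sp_fft

        grid = Grid3D(nx=128, ny=128, nz=8, dx=1.0, dy=1.0, dz=1.0)
        w0 = 0.5 / (np.pi * 0.02)  # NA ~ 0.02 Gaussian
        f = gaussian_field(grid, w0, 0.5)
        exact = free_space_step(f, 100.0, 1.0)
        k = f.k0
        ky = 2 * np.pi * sp_fft.fftfreq(grid.ny, d=grid.dy)[:, None]
        kx = 2 * np.pi * sp_fft.fftfreq(grid.nx, d=grid.dx)[None, :]
        H = np.exp(1j * 100.0 * (k - (kx**2 + ky**2) / (2 * k)))
        fresnel = sp_fft.ifft2(H * sp_fft.fft2(f.values))
        err = np.linalg.norm(exact.values - fresnel) / np.linalg.norm(fresnel)
        assert err < 1e-4

    def test_reciprocity(self):
        """Forward-propagate, conjugate, propagate back through the
        flipped volume: recovers the conjugate start field (the basis of
        guide-star conjugation)."""
        grid = Grid3D(nx=64, ny=64, nz=32, dx=0.3, dy=0.3, dz=0.3)
        vol = make_perlin_tissue(
            grid, mean_n=1.36, amplitude=0.02, correlation_length=1.0, seed=1,
            n_ambient=1.36,
        ).refractive
        f = make_field(
            SourceSpec(
                kind="point_source",
                pupil=PupilSpec(na=0.5, wavelength=0.5, n0=1.36),
                focus_position=(0.0, 0.0, 4.0),
            ),
            grid,
        )
        fwd = propagate(f, vol).final
        back_in = ComplexField(
            values=np.conj(fwd.values), dx=grid.dx, dy=grid.dy, wavelength=0.5
        )
        rev = RefractiveVolume(grid=grid, n=vol.n[::-1].copy(), n_ambient=vol.n_ambient)
        rec = np.conj(propagate(back_in, rev).final.values)
        err = np.linalg.norm(rec - f.values) / np.linalg.norm(f.values)
        assert err < 1e-6

    def test_absorbing_frame_removes_power(self):
        grid = Grid3D(nx=64, ny=64, nz=16, dx=0.25, dy=0.25, dz=0.25)
        vol = vacuum_volume(grid)
        y = grid.y_coords()[:, None]
        x = grid.x_coords()[None, :]
        # off-center beam headed into the frame
        f = ComplexField(
            values=np.exp(-((x - 5.0) ** 2 + y**2) / 4.0),
            dx=grid.dx,
            dy=grid.dy,
            wavelength=0.5,
        )
        res = propagate(
            f, vol, PropagatorConfig(boundary="absorbing", absorb_width=12)
        )
        assert res.plane_power[-1] < 0.999 * res.plane_power[0]

    def test_absorbing_width_validated(self):
        grid = Grid3D(nx=32, ny=32, nz=8, dx=0.25, dy=0.25, dz=0.25)
        f = gaussian_field(grid, 2.0, 0.5)
        with pytest.raises(ValueError):
            propagate(
                f, vacuum_volume(grid), PropagatorConfig(boundary="absorbing", absorb_width=16)
            )
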