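"""Light-sheet image formation: excitation, spatially varying
convolution, stack simulation, geometric distortion."""

import numpy as np
import pytest

from sheetwave.bpm import PropagatorConfig
from sheetwave.fields import PupilSpec, SourceSpec
from sheetwave.grid import FluorophoreVolume, Grid3D, RefractiveVolume
from sheetwave.imaging import excitation_volume, render_camera_image, simulate_stack
from sheetwave.oracles import focus_fwhm_axial, sequential_psf
from sheetwave.phantoms import Phantom, SphereSpec, make_embryo, make_perlin_tissue, make_spheres
from sheetwave.psf import TileLayout, compute_psf_set

from conftest import brute_force_render, fwhm_1d, vacuum_volume

WAVELENGTH = 0.5
N0 = 1.33


def sheet_spec(na=0.15, wavelength=0.488):
    return SourceSpec(
        kind="cylindrical_sheet", pupil=PupilSpec(na=na, wavelength=wavelength, n0=N0)
    )


def detect_pupil(na=0.6, softness=0.3):
    return PupilSpec(na=na, wavelength=WAVELENGTH, n0=N0, softness=softness)


class TestExcitationVolume:
    def test_sheet_peaks_at_requested_plane_with_vacuum_waist(self):
        g = Grid3D(nx=64, ny=48, nz=96, dx=0.25, dy=0.25, dz=0.25)
        exc, _ = excitation_volume(vacuum_volume(g, N0), sheet_spec(), sheet_z=12.0)
        prof = exc.mean(axis=(1, 2))
        z_peak = g.z_coords()[int(np.argmax(prof))]
        assert abs(z_peak - 12.0) <= g.dz
        # thickness at the focus column vs 1D slit-focus width
        mid = exc[:, g.ny // 2, g.nx // 2]
        k_na = 2 * np.pi / 0.488 * 0.15
        expected = 2 * 1.39156 / k_na
        assert abs(fwhm_1d(mid, g.dz) - expected) / expected < 0.10

    def test_absorbing_medium_follows_beer_lambert(self):
        g = Grid3D(nx=48, ny=48, nz=48, dx=0.25, dy=0.25, dz=0.25)
        kappa = 1e-3
        vol = RefractiveVolume(
            grid=g, n=np.full(g.shape, N0 + 1j * kappa), n_ambient=N0
        )
        exc, _ = excitation_volume(vol, sheet_spec(), sheet_z=6.0)
        per_x = exc.sum(axis=(0, 1))  # total excitation vs illumination depth
        k0 = 2 * np.pi / 0.488
        ratios = per_x[1:] / per_x[:-1]
        np.testing.assert_allclose(ratios, np.exp(-2 * k0 * kappa * g.dx), rtol=1e-6)

    def test_incoherent_set_averages_intensities(self):
        g = Grid3D(nx=48, ny=48, nz=48, dx=0.25, dy=0.25, dz=0.25)
        s1 = sheet_spec()
        exc1, _ = excitation_volume(vacuum_volume(g, N0), s1, sheet_z=6.0)
        exc2, _ = excitation_volume(vacuum_volume(g, N0), [s1, s1], sheet_z=6.0)
        np.testing.assert_allclose(exc1, exc2, rtol=1e-12)


class TestRenderCameraImage:
    @staticmethod
    def _setup(nx=64, tiles=2, nz=32):
        g = Grid3D(nx=nx, ny=nx, nz=nz, dx=0.3, dy=0.3, dz=0.3)
        layout = TileLayout(
            tile_nx=tiles, tile_ny=tiles, tile_size=nx // tiles, guard_margin=4
        )
        pset = compute_psf_set(
            vacuum_volume(g, N0), g.nz * g.dz / 2, layout, detect_pupil()
        )
        return g, layout, pset

    def test_delta_emitter_reproduces_psf_slice(self):
        g, layout, pset = self._setup()
        cx, cy = layout.center_pixels(g)
        jz = int(round(pset.plane_z / g.dz))
        fl = np.zeros(g.shape)
        fl[jz, int(cy[0]), int(cx[0])] = 3.0
        img = render_camera_image(
            np.ones(g.shape), FluorophoreVolume(grid=g, density=fl), pset, blend="nearest"
        )
        zoff = (jz + 0.5) * g.dz - pset.plane_z
        pi = int(round((zoff - pset.z_offsets[0]) / g.dz))
        expected = np.zeros(g.transverse_shape)
        rows, cols = layout.tile_slices(g, 0, 0)
        expected[rows, cols] = 3.0 * pset.raw(0, 0)[pi]
        np.testing.assert_allclose(img.values, expected, atol=1e-12 * expected.max())

    def test_zero_fluorophore_gives_zero_image(self):
        g, layout, pset = self._setup()
        img = render_camera_image(
            np.ones(g.shape), FluorophoreVolume(grid=g, density=np.zeros(g.shape)), pset
        )
        assert img.values.sum() == 0.0

    def test_matches_brute_force_superposition(self):
        """FFT-based spatially varying convolution equals the direct
        triple-loop sum on a 32^3 instance to 1e-10."""
        g = Grid3D(nx=32, ny=32, nz=32, dx=0.3, dy=0.3, dz=0.3)
        layout = TileLayout(tile_nx=2, tile_ny=2, tile_size=16, guard_margin=3)
        vol = make_perlin_tissue(
            g, mean_n=N0, amplitude=0.005, correlation_length=3.0, seed=7, n_ambient=N0
        ).refractive
        pset = compute_psf_set(vol, g.nz * g.dz / 2, layout, detect_pupil(na=0.5))
        rng = np.random.default_rng(0)
        emitted = rng.uniform(size=g.shape)
        img = render_camera_image(
            emitted, FluorophoreVolume(grid=g, density=np.ones(g.shape)), pset, blend="nearest"
        )
        oracle = brute_force_render(emitted, pset, blend="nearest")
        err = np.linalg.norm(img.values - oracle) / np.linalg.norm(oracle)
        assert err < 1e-10

    def test_linearity_in_fluorophore(self):
        g, layout, pset = self._setup()
        rng = np.random.default_rng(1)
        exc = np.ones(g.shape)
        f1 = rng.uniform(size=g.shape)
        f2 = rng.uniform(size=g.shape)
        i1 = render_camera_image(exc, FluorophoreVolume(grid=g, density=f1), pset).values
        i2 = render_camera_image(exc, FluorophoreVolume(grid=g, density=f2), pset).values
        i12 = render_camera_image(
            exc, FluorophoreVolume(grid=g, density=f1 + f2), pset
        ).values
        np.testing.assert_allclose(i12, i1 + i2, rtol=1e-9, atol=1e-12)

    def test_energy_bounded_by_emitted_energy(self):
        g, layout, pset = self._setup()
        rng = np.random.default_rng(2)
        emitted = rng.uniform(size=g.shape)
        # restrict emission to the PSF refocus band so nothing is dropped
        z_emit = g.z_coords() - pset.plane_z
        emitted[(z_emit < pset.z_offsets[0]) | (z_emit > pset.z_offsets[-1])] = 0.0
        img = render_camera_image(
            emitted, FluorophoreVolume(grid=g, density=np.ones(g.shape)), pset
        )
        # each emitter contributes at most (its weight) x (largest raw
        # PSF plane sum); equality would need every emitter on the
        # brightest plane of the brightest tile
        plane_sums = (pset.psfs * pset.norm[:, :, None, None, None]).sum(axis=(3, 4))
        assert img.values.sum() <= emitted.sum() * plane_sums.max() * (1 + 1e-6)

    def test_blend_modes_converge_with_tile_count(self):
        """Nearest and bilinear blends agree better as the tile lattice
        refines on a smoothly aberrating phantom."""
        # the aberration field must vary on a scale longer than the
        # coarsest tile pitch, else adjacent-tile PSFs are already
        # decorrelated and refining the lattice cannot help
        g = Grid3D(nx=128, ny=128, nz=32, dx=0.3, dy=0.3, dz=0.3)
        vol = make_perlin_tissue(
            g, mean_n=N0, amplitude=0.02, correlation_length=30.0, seed=3, n_ambient=N0
        ).refractive
        rng = np.random.default_rng(5)
        # emission confined to a thin slab around the focal plane so
        # every layout sees the same (un-truncated) emitters
        density = np.zeros(g.shape)
        density[14:18] = rng.uniform(size=(4, g.ny, g.nx))
        fl = FluorophoreVolume(grid=g, density=density)
        exc = np.ones(g.shape)
        gaps = []
        for tiles in (2, 4, 8):
            layout = TileLayout(
                tile_nx=tiles, tile_ny=tiles, tile_size=128 // tiles, guard_margin=3
            )
            pset = compute_psf_set(
                vol, g.nz * g.dz / 2, layout, detect_pupil(na=0.5), psf_nz=9
            )
            a = render_camera_image(exc, fl, pset, blend="nearest").values
            b = render_camera_image(exc, fl, pset, blend="bilinear").values
            gaps.append(np.linalg.norm(a - b) / np.linalg.norm(b))
        assert gaps[0] > gaps[1] > gaps[2]


class TestSimulateStack:
    def test_point_emitters_reproduce_axial_focus_width(self):
        """Vacuum phantom with point emitters: the through-stack axial
        response matches the scalar axial focus width within 10%."""
        g = Grid3D(nx=48, ny=48, nz=48, dx=0.25, dy=0.25, dz=0.25)
        fl = np.zeros(g.shape)
        fl[24, 24, 24] = 1.0
        phantom = Phantom(
            refractive=vacuum_volume(g, N0),
            fluor=FluorophoreVolume(grid=g, density=fl),
            truth={},
        )
        layout = TileLayout(tile_nx=1, tile_ny=1, tile_size=48, guard_margin=4)
        z_positions = (np.arange(16) + 16.5) * g.dz
        stack = simulate_stack(
            phantom,
            sheet_spec(na=0.1),
            detect_pupil(na=0.5, softness=0.0),
            layout,
            z_positions,
            psf_nz=9,
        )
        arr = stack.as_array()
        axial = arr[:, 24, 24]
        measured = fwhm_1d(axial, g.dz)
        # optical sectioning = sheet excitation profile x detection
        # axial profile; combine widths in the Gaussian approximation
        f_det = focus_fwhm_axial(0.5, WAVELENGTH, N0)
        f_sheet = 2 * 1.39156 / (2 * np.pi / 0.488 * 0.1)
        expected = 1.0 / np.sqrt(f_det**-2 + f_sheet**-2)
        assert abs(measured - expected) / expected < 0.10

    def test_far_side_of_embryo_loses_contrast(self):
        """Imaging through the embryo: planes whose detection path
        crosses the organism show lower nuclear contrast."""
        g = Grid3D(nx=64, ny=64, nz=64, dx=0.4, dy=0.4, dz=0.4)
        phantom = make_embryo(g, seed=6, n_nuclei=18)
        layout = TileLayout(tile_nx=2, tile_ny=2, tile_size=32, guard_margin=4)
        near, far = 0.75 * g.nz * g.dz, 0.25 * g.nz * g.dz
        frames = {}
        for z in (near, far):
            stack = simulate_stack(
                phantom, sheet_spec(na=0.1), detect_pupil(), layout, [z], psf_nz=9
            )
            frames[z] = stack.frames[0].values
        def contrast(img):
            return img.std() / max(img.mean(), 1e-30)
        # detection path for the deep (low-z is far from camera at high z...)
        # camera sits at high z: plane at 0.25 L traverses most tissue
        assert contrast(frames[far]) < contrast(frames[near])

    def test_widefield_ball_lens_magnification_matches_ray_optics(self):
        """A ball lens in the detection path displaces off-axis emitters
        laterally; the measured magnification matches the paraxial
        thick-lens (ABCD) prediction within 10%."""
        nl, R = 1.43, 6.0
        g = Grid3D(nx=128, ny=128, nz=160, dx=0.25, dy=0.25, dz=0.25)
        z_lens, z_obj = 20.0, 8.0
        ph = make_spheres(
            g, [SphereSpec(center=(0.0, 0.0, z_lens), radius=R, n=nl)], n_ambient=N0
        )
        def trace(y0, th):
            z1, z2 = z_lens - R, z_lens + R
            zexit = g.nz * g.dz
            y = y0 + th * (z1 - z_obj)
            th = (N0 / nl) * th + (N0 - nl) / (nl * R) * y
            y = y + th * (2 * R)
            th = (nl / N0) * th + (nl - N0) / (N0 * (-R)) * y
            y = y + th * (zexit - z2)
            return y - th * (zexit - z_obj)  # ideal refocus to object plane
        pupil = PupilSpec(na=0.45, wavelength=0.52, n0=N0, gaussian_sigma=0.35)
        slopes_meas, slopes_ray = [], []
        for x0 in (1.0, 2.0, 3.0):
            ths = np.linspace(-0.2, 0.2, 41) / N0
            slopes_ray.append(np.mean([trace(x0, t) for t in ths]) / x0)
            psf = sequential_psf(
                ph.refractive, (x0, 0.0, z_obj), pupil,
                (slice(0, 128), slice(0, 128)), psf_nz=1,
            )
            plane = psf[0]
            iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
            # centroid refinement around the peak
            win = plane[iy - 2 : iy + 3, ix - 2 : ix + 3]
            xs = g.x_coords()[ix - 2 : ix + 3]
            x_meas = float((win.sum(axis=0) * xs).sum() / win.sum())
            slopes_meas.append(x_meas / x0)
        m_ray = np.mean(slopes_ray)
        m_meas = np.mean(slopes_meas)
        assert abs(m_meas - m_ray) / (m_ray - 1.0) < 0.10 or abs(m_meas - m_ray) < 0.02
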