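import math

import numpy as np
import pytest
from scipy import ndimage

from phunlattice import (
    GeometryError,
    LatticeSpec,
    NoiseSpec,
    ParameterError,
    TiltScheme,
    index_lattice,
    make_missing_cone_volume,
    make_subunit_motif,
    make_subunit_phantom,
    missing_cone_mask,
    preset_spec,
    project_volume,
    render_lattice_image,
    render_multi_patch_micrograph,
)
from phunlattice.io_formats import DensityVolume


class TestSubunitPhantom:
    def test_seed_determinism(self):
        a = make_subunit_phantom(seed=5)
        b = make_subunit_phantom(seed=5)
        assert np.array_equal(a.grid, b.grid)

    def test_asymmetry_under_rotation(self):
        """No internal 2-fold: correlation with the 180°-rotated copy < 0.8."""
        vol = make_subunit_phantom(seed=3).grid
        rot = np.rot90(vol, 2, axes=(1, 2))  # 180° about z
        a = vol - vol.mean()
        b = rot - rot.mean()
        corr = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
        assert corr < 0.8

    def test_grid_size_from_extent(self):
        vol = make_subunit_phantom(seed=0, extent=60.0, voxel_size=2.0)
        assert min(vol.grid.shape) >= 30

    def test_coarse_voxel_rejected(self):
        with pytest.raises(ParameterError):
            make_subunit_phantom(seed=0, extent=60.0, voxel_size=10.0)

    def test_small_extent_rejected(self):
        with pytest.raises(ParameterError):
            make_subunit_motif(seed=0, extent=10.0)


class TestLatticeRendering:
    def test_noiseless_rendering_deterministic(self, motif):
        spec = preset_spec("p2-invitro")
        img1, _ = render_lattice_image(spec, motif, 512, 4.0, noise=None)
        img2, _ = render_lattice_image(spec, motif, 512, 4.0, noise=None)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_seeded_noise_deterministic(self, motif):
        spec = preset_spec("p2-invitro")
        img1, _ = render_lattice_image(spec, motif, 512, 4.0, NoiseSpec(0.3, 9))
        img2, _ = render_lattice_image(spec, motif, 512, 4.0, NoiseSpec(0.3, 9))
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_p2_autocorrelation_peaks_at_cell_vectors(self, motif):
        """The in vitro p2 cell (120 Å, 100°) leaves autocorrelation peaks
        at ±a and ±b."""
        spec = preset_spec("p2-invitro")
        img, truth = render_lattice_image(spec, motif, 1024, 4.0, noise=None)
        pix = img.pixels - img.pixels.mean()
        F = np.fft.rfft2(pix)
        ac = np.fft.fftshift(np.fft.irfft2(np.abs(F) ** 2, s=pix.shape))
        c = np.array(ac.shape)[::-1] // 2
        far = ac[ac.shape[0] // 4:, :].std()
        for vec in (truth.a_vec, truth.b_vec, -truth.a_vec, -truth.b_vec):
            px = np.round(vec / 4.0).astype(int) + c
            window = ac[px[1] - 2: px[1] + 3, px[0] - 2: px[0] + 3]
            assert window.max() > 5 * far

    @pytest.mark.parametrize(
        "preset,angle,min_corr",
        [("p4-invitro", 90.0, 0.95), ("p2-invitro", 180.0, 0.99)],
    )
    def test_plane_group_symmetry_of_rendering(self, motif, preset, angle,
                                               min_corr):
        """Noiseless renderings are invariant under their group generator
        about a symmetry point of the lattice."""
        spec = preset_spec(preset)
        img, truth = render_lattice_image(spec, motif, 768, 4.0, noise=None)
        a, b = truth.a_vec / 4.0, truth.b_vec / 4.0
        # symmetry points: p4 axis on the lattice node; the p2 axis sits a
        # quarter cell from the node (motif at node, partner at center)
        frac = np.array([0.0, 0.0]) if angle == 90.0 else np.array([0.25, 0.25])
        B = np.column_stack([a, b])
        nmid = (np.array(img.pixels.shape[::-1]) - 1) / 2.0
        n_ij = np.round(np.linalg.solve(B, nmid - B @ frac))
        center = B @ (n_ij + frac)  # (x, y) px of an axis near the middle
        # rotate about that point: shift the axis onto the array rotation
        # center ((n-1)/2 for ndimage.rotate), rotate, compare central crop
        shift = nmid[::-1] - center[::-1]
        moved = ndimage.shift(img.pixels.astype(float), shift, order=3)
        rot = ndimage.rotate(moved, angle, reshape=False, order=3)
        h = img.pixels.shape[0] // 4
        sl = slice(img.pixels.shape[0] // 2 - h, img.pixels.shape[0] // 2 + h)
        x = moved[sl, sl] - moved[sl, sl].mean()
        y = rot[sl, sl] - rot[sl, sl].mean()
        corr = (x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum())
        assert corr > min_corr

    def test_p4_requires_square_cell(self):
        with pytest.raises(ParameterError):
            LatticeSpec("p4", 120.0, 110.0, 90.0)

    def test_cell_must_fit_five_times(self, motif):
        spec = preset_spec("p2-invitro")
        with pytest.raises(GeometryError):
            render_lattice_image(spec, motif, 64, 4.0)


class TestMultiPatch:
    def test_single_patch_single_label(self, motif):
        region = np.array([[200, 200], [1800, 200], [1800, 1800], [200, 1800]])
        img, table = render_multi_patch_micrograph(
            [(preset_spec("p2-invitro"), region)], 512, 4.0, motif=motif
        )
        assert len(table) > 0
        assert set(table.frame["symmetry_label"]) == {"p2"}

    def test_two_patches_partition_by_region(self, motif):
        left = np.array([[100, 100], [950, 100], [950, 1900], [100, 1900]])
        right = np.array([[1100, 100], [1950, 100], [1950, 1900], [1100, 1900]])
        img, table = render_multi_patch_micrograph(
            [(preset_spec("p2-invitro"), left),
             (preset_spec("p4-invitro"), right)],
            512, 4.0, motif=motif,
        )
        p2 = table.frame[table.frame["symmetry_label"] == "p2"]
        p4 = table.frame[table.frame["symmetry_label"] == "p4"]
        assert len(p2) and len(p4)
        assert p2["x"].max() < 1000
        assert p4["x"].min() > 1000

    def test_overlapping_regions_rejected(self, motif):
        a = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])
        b = np.array([[500, 500], [1500, 500], [1500, 1500], [500, 1500]])
        with pytest.raises(GeometryError):
            render_multi_patch_micrograph(
                [(preset_spec("p2-invitro"), a), (preset_spec("p4-invitro"), b)],
                512, 4.0, motif=motif,
            )

    def test_per_patch_orientations_recoverable(self, motif):
        """Three patches at distinct in-plane rotations index to three
        distinct lattice orientations."""
        regions = [
            np.array([[50, 50], [1300, 50], [1300, 2650], [50, 2650]]),
            np.array([[1400, 50], [2650, 50], [2650, 2650], [1400, 2650]]),
        ]
        rots = [0.0, 30.0]
        img, table = render_multi_patch_micrograph(
            [
                (preset_spec("p2-invitro", in_plane_rotation=r), reg)
                for r, reg in zip(rots, regions)
            ],
            672, 4.0, motif=motif,
        )
        angles = []
        for reg in regions:
            x0, y0 = (reg[0] / 4).astype(int) + 8
            x1, y1 = (reg[2] / 4).astype(int) - 8
            crop = img.pixels[y0:y1, x0:x1]
            from phunlattice import MicrographImage

            m = index_lattice(MicrographImage(crop, 4.0))
            angles.append(math.degrees(math.atan2(m.a_vec[1], m.a_vec[0])) % 180)
        diff = abs(angles[0] - angles[1]) % 180
        assert min(diff, 180 - diff) == pytest.approx(30.0, abs=2.0)


class TestMissingCone:
    def test_cone_half_angle_geometry(self):
        """Max tilt 60° leaves a 30° half-angle cone: the zeroed fraction
        within the Nyquist sphere matches the solid-angle formula."""
        mask = missing_cone_mask((64, 64, 64), 60.0)
        f = np.fft.fftfreq(64)
        r = np.sqrt(
            f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
        )
        ball = r <= 0.5
        frac = mask[ball].mean()
        expected = 1.0 - math.cos(math.radians(30.0))
        assert frac == pytest.approx(expected, rel=0.02)

    def test_full_tilt_is_identity(self, sphere_volume):
        full, h1, h2 = make_missing_cone_volume(
            sphere_volume, 90.0, NoiseSpec(snr=1e12, seed=0)
        )
        assert np.allclose(full.grid, sphere_volume.grid, atol=1e-4)

    def test_half_maps_have_independent_noise(self, sphere_volume):
        full, h1, h2 = make_missing_cone_volume(
            sphere_volume, 60.0, NoiseSpec(snr=3.0, seed=5)
        )
        conv = 0.5 * (h1.grid + h2.grid)  # estimate of the common signal
        n1 = h1.grid - full.grid
        n2 = h2.grid - full.grid
        # the two half-map noise components are anti-correlated with each
        # other through the mean; use the raw realizations instead
        r1 = h1.grid - sphere_volume.grid
        r2 = h2.grid - sphere_volume.grid
        F1 = np.fft.fftn(r1)
        F2 = np.fft.fftn(r2)
        f = np.fft.fftfreq(64)
        r = np.sqrt(
            f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
        ) * 64
        shell = (r > 20) & (r < 30)  # beyond the signal band
        num = (F1[shell] * np.conj(F2[shell])).real.sum()
        den = np.sqrt(
            (np.abs(F1[shell]) ** 2).sum() * (np.abs(F2[shell]) ** 2).sum()
        )
        assert abs(num / den) < 0.05

    def test_bad_tilt_rejected(self, sphere_volume):
        with pytest.raises(ParameterError):
            make_missing_cone_volume(sphere_volume, 0.0, NoiseSpec(1.0, 0))

    def test_tilt_scheme_bounds(self):
        TiltScheme()  # collection tilts 0–60° are valid
        with pytest.raises(ParameterError):
            TiltScheme(tilt_angles=(0.0, 80.0))


class TestProjection:
    def test_zero_tilt_is_z_sum(self, sphere_volume):
        proj = project_volume(sphere_volume, 0.0, 0.0)
        expected = sphere_volume.grid.sum(axis=0) * sphere_volume.voxel_size
        assert np.allclose(proj.pixels, expected, rtol=1e-5, atol=1e-5)

    def test_sphere_projection_orientation_invariant(self, sphere_volume):
        p0 = project_volume(sphere_volume, 0.0, 0.0).pixels
        p1 = project_volume(sphere_volume, 40.0, 25.0).pixels
        rel = np.linalg.norm(p1 - p0) / np.linalg.norm(p0)
        assert rel < 0.01

    def test_fourier_slice_theorem(self):
        """FT of the projection equals the central slice of the volume FT
        at the projection orientation (2% relative error; the slice is
        evaluated by exact discrete Fourier sums, no interpolation)."""
        n = 33
        rng = np.random.default_rng(0)
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n] - (n - 1) / 2
        grid = np.zeros((n, n, n))
        for _ in range(6):  # smooth random blob phantom
            c = rng.uniform(-6, 6, 3)
            s = rng.uniform(2.0, 4.0)
            grid += np.exp(
                -((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
                / (2 * s**2)
            )
        vol = DensityVolume(grid, 2.0)
        tilt, rot = 30.0, 40.0
        proj = project_volume(vol, tilt, rot)
        P = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(proj.pixels)))
        th_z, th_t = math.radians(rot), math.radians(tilt)
        Rz = np.array(
            [[1, 0, 0],
             [0, math.cos(th_z), -math.sin(th_z)],
             [0, math.sin(th_z), math.cos(th_z)]]
        )
        Ry = np.array(
            [[math.cos(th_t), 0, -math.sin(th_t)],
             [0, 1, 0],
             [math.sin(th_t), 0, math.cos(th_t)]]
        )
        R = Ry @ Rz  # index-space rotation used by project_volume
        c = (n - 1) / 2
        ky, kx = np.mgrid[0:n, 0:n] - c
        band = np.sqrt(kx**2 + ky**2) < n / 3
        kpts = np.stack(
            [np.zeros_like(kx)[band], ky[band], kx[band]]
        ).astype(float)
        q = R.T @ kpts  # slice plane rotated into the volume frame
        coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()])
        phase = -2j * np.pi * (q.T @ coords) / n
        slice_ = (np.exp(phase) @ grid.ravel()) * vol.voxel_size
        rel = np.linalg.norm(P[band] - slice_) / np.linalg.norm(slice_)
        assert rel < 0.02

    def test_non_cubic_rejected(self):
        vol = DensityVolume(np.zeros((8, 8, 16)), 1.0)
        with pytest.raises(GeometryError):
            project_volume(vol, 0.0)
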