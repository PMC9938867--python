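"""Synthetic lattice micrographs, tilt-limited projections and
missing-cone volumes with known ground truth.

These generators emulate the experimental inputs of the pipeline: 2D
crystals of an asymmetric ~60 × 40 Å protein motif arranged with p1/p2/p4
plane-group symmetry at the measured unit-cell parameters, micrographs with
several lattice patches of distinct orientation, projections at the
collection tilt angles (0–60°), and 3D maps whose Fourier transform lacks a
cone of half-angle (90° − max tilt) about the z axis — the signature of
tilt-limited data collection.

Projections are CTF-free and noise is white Gaussian parameterized by SNR
(signal variance over noise variance); both choices are documented in the
methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io_formats import (
    DensityVolume,
    GeometryError,
    MicrographImage,
    ParameterError,
    ParticleTable,
)
from .lattice_indexing import LatticeModel

__all__ = [
    "LatticeSpec",
    "NoiseSpec",
    "TiltScheme",
    "PAPER_TILT_ANGLES",
    "PAPER_PIXEL_SIZE",
    "PRESETS",
    "preset_spec",
    "GaussianMotif",
    "make_subunit_motif",
    "make_subunit_phantom",
    "make_smooth_phantom",
    "render_lattice_image",
    "render_multi_patch_micrograph",
    "make_missing_cone_volume",
    "project_volume",
]

#: Collection tilt series used for the real data (degrees).
PAPER_TILT_ANGLES = (0.0, 15.0, 30.0, 35.0, 40.0, 45.0, 50.0, 60.0)

#: Physical detector pixel size of the real collections (Å/px).
PAPER_PIXEL_SIZE = 0.835

#: Default synthetic sampling: 4 Å/px for micrographs, 2 Å/voxel for volumes.
DEFAULT_PIXEL_SIZE = 4.0
DEFAULT_VOXEL_SIZE = 2.0


@dataclass
class LatticeSpec:
    """Plane group plus 2D unit-cell geometry of a synthetic crystal patch."""

    plane_group: str
    a_len: float
    b_len: float
    gamma: float  # inter-axis angle, degrees
    in_plane_rotation: float = 0.0
    patch_polygon: np.ndarray | None = None  # Å vertices, (N, 2)
    distortion_amplitude: float = 0.0

    def __post_init__(self):
        if self.plane_group not in ("p1", "p2", "p4"):
            raise ParameterError(f"unsupported plane group {self.plane_group!r}")
        if not (self.a_len > 0 and self.b_len > 0):
            raise ParameterError("cell lengths must be > 0")
        if not (0.0 < self.gamma < 180.0):
            raise ParameterError("gamma must lie in (0°, 180°)")
        if self.plane_group == "p4" and (
            abs(self.a_len - self.b_len) > 1e-6 * self.a_len
            or abs(self.gamma - 90.0) > 1e-9
        ):
            raise ParameterError("p4 requires a square cell (a = b, gamma = 90°)")

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell basis vectors in Å, including the in-plane rotation."""
        rho = math.radians(self.in_plane_rotation)
        g = math.radians(self.gamma)
        a = self.a_len * np.array([math.cos(rho), math.sin(rho)])
        b = self.b_len * np.array([math.cos(rho + g), math.sin(rho + g)])
        return a, b


@dataclass
class NoiseSpec:
    """Additive white Gaussian noise level: snr = var(signal) / var(noise)."""

    snr: float
    seed: int = 0

    def __post_init__(self):
        if not self.snr > 0:
            raise ParameterError("snr must be > 0")


@dataclass
class TiltScheme:
    """Collection tilts about a fixed in-plane axis, degrees."""

    tilt_angles: tuple = PAPER_TILT_ANGLES

    def __post_init__(self):
        for t in self.tilt_angles:
            if not -70.0 <= t <= 70.0:
                raise ParameterError(f"tilt {t}° outside [-70°, 70°]")


#: Named unit-cell presets: the in vitro p2 (120 Å, 100°) and p4 (120 Å, 90°)
#: cells and the cells measured on isolated shell fragments, p2 (120 Å, 120°)
#: and p4 (110 Å, 90°).
PRESETS: dict[str, tuple[str, float, float, float]] = {
    "p2-invitro": ("p2", 120.0, 120.0, 100.0),
    "p4-invitro": ("p4", 120.0, 120.0, 90.0),
    "p2-fragment": ("p2", 120.0, 120.0, 120.0),
    "p4-fragment": ("p4", 110.0, 110.0, 90.0),
}


def preset_spec(name: str, **kw) -> LatticeSpec:
    """Build the LatticeSpec for a named preset."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    group, a, b, gamma = PRESETS[name]
    return LatticeSpec(plane_group=group, a_len=a, b_len=b, gamma=gamma, **kw)


# ---------------------------------------------------------------------------
# subunit phantom
# ---------------------------------------------------------------------------

@dataclass
class GaussianMotif:
    """An analytic motif: a seeded set of 3D Gaussian blobs.

    Carrying the blob parameters (rather than only a rasterized grid) lets
    the lattice renderer place symmetry-related copies exactly — rotations
    act on blob centers in the continuum, so the plane-group symmetry of a
    rendered image is limited only by pixel sampling, not by interpolation.
    """

    centers: np.ndarray  # (n, 3) Å, motif frame (x, y, z)
    amplitudes: np.ndarray  # (n,)
    sigmas: np.ndarray  # (n,) Å

    def projected_blobs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(xy centers, 2D amplitudes, sigmas) of the z line-integral."""
        amp2d = self.amplitudes * np.sqrt(2.0 * math.pi) * self.sigmas
        return self.centers[:, :2].copy(), amp2d, self.sigmas.copy()

    def rasterize(self, extent: float, voxel_size: float) -> DensityVolume:
        n = int(round(extent / voxel_size))
        coords = (np.mgrid[0:n, 0:n, 0:n] + 0.5) * voxel_size - extent / 2.0
        grid = np.zeros((n, n, n))
        for c, a, s in zip(self.centers, self.amplitudes, self.sigmas):
            d2 = (
                (coords[2] - c[0]) ** 2  # x varies fastest
                + (coords[1] - c[1]) ** 2
                + (coords[0] - c[2]) ** 2
            )
            grid += a * np.exp(-0.5 * d2 / s**2)
        return DensityVolume(grid=grid, voxel_size=voxel_size)


def make_subunit_motif(seed: int, extent: float = 60.0) -> GaussianMotif:
    """Seeded analytic motif: hierarchical Gaussian blobs in a ~60 × 40 Å
    ellipsoid.

    The motif mimics a protein projection at micrograph sampling: a handful
    of broad "domain" lumps, each decorated with sharper sub-blobs
    (secondary-structure-scale detail).  The sparse domain layout keeps the
    motif asymmetric — its projection correlates well below 0.8 with its own
    180°-rotated copy — while the sub-blobs populate reflections out to the
    sampling limit, which is what plane-group scoring discriminates on.
    """
    if extent < 20.0:
        raise ParameterError("extent must be >= 20 Å")
    rng = np.random.default_rng(seed)
    semi = np.array([0.38, 0.28, 0.20]) * extent  # x, y, z semi-axes, Å
    domains = []
    while len(domains) < 10:
        p = rng.uniform(-1.0, 1.0, size=3) * semi
        if np.sum((p / semi) ** 2) <= 1.0:
            domains.append(p)
    centers, amps, sigmas = [], [], []
    for d in domains:
        centers.append(d)
        amps.append(rng.uniform(0.4, 0.6))
        sigmas.append(rng.uniform(0.06, 0.075) * extent)
        for _ in range(4):
            centers.append(d + rng.normal(0.0, 0.05 * extent, 3))
            amps.append(rng.uniform(0.6, 1.2))
            sigmas.append(rng.uniform(0.025, 0.04) * extent)
    return GaussianMotif(
        centers=np.array(centers),
        amplitudes=np.array(amps),
        sigmas=np.array(sigmas),
    )


def make_subunit_phantom(
    seed: int, extent: float = 60.0, voxel_size: float = DEFAULT_VOXEL_SIZE
) -> DensityVolume:
    """Rasterized subunit phantom (see :func:`make_subunit_motif`).

    Non-negative, compact, asymmetric, reproducible from the seed.
    """
    if voxel_size > extent / 8.0:
        raise ParameterError(
            f"voxel_size {voxel_size} Å too coarse to resolve a {extent} Å motif"
        )
    return make_subunit_motif(seed, extent).rasterize(extent, voxel_size)


def _motif_patch(motif, pixel_size: float) -> np.ndarray:
    """Project / resample a motif to a 2D patch at the target pixel size."""
    if isinstance(motif, DensityVolume):
        img = motif.grid.sum(axis=0) * motif.voxel_size
        src_px = motif.voxel_size
    elif isinstance(motif, MicrographImage):
        img = motif.pixels.astype(float)
        src_px = motif.pixel_size
    else:
        raise ParameterError("motif must be a DensityVolume or MicrographImage")
    zoom = src_px / pixel_size
    if abs(zoom - 1.0) > 1e-9:
        img = ndimage.zoom(img, zoom, order=1)
    return img


# ---------------------------------------------------------------------------
# lattice rendering
# ---------------------------------------------------------------------------

def _symmetry_copies(spec: LatticeSpec):
    """(fractional offset in the cell, motif rotation °) per symmetry copy."""
    if spec.plane_group == "p1":
        return [((0.0, 0.0), 0.0)]
    if spec.plane_group == "p2":
        # motif on the lattice node, 180°-rotated partner at the cell center
        return [((0.0, 0.0), 0.0), ((0.5, 0.5), 180.0)]
    # p4: four 90°-rotated copies around the 4-fold axis at the origin
    d = np.array([0.27, 0.11])
    copies = []
    for k in range(4):
        th = math.radians(90.0 * k)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        frac = R @ d
        copies.append(((float(frac[0]), float(frac[1])), 90.0 * k))
    return copies


def _splat_comb(shape, pts_px: np.ndarray) -> np.ndarray:
    """Bilinearly splat unit deltas at subpixel positions (x, y) px."""
    ny, nx = shape
    comb = np.zeros((ny, nx))
    x, y = pts_px[:, 0], pts_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dy in (0, 1):
        for dx in (0, 1):
            w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xi, yi = x0 + dx, y0 + dy
            ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
            np.add.at(comb, (yi[ok], xi[ok]), w[ok])
    return comb


def _lattice_nodes(spec: LatticeSpec, width: float, height: float, rng=None):
    """All lattice node positions (Å) whose cell intersects the field of view,
    with the optional smooth distortion field applied."""
    a, b = spec.basis
    B = np.column_stack([a, b])
    corners = np.array([[0, 0], [width, 0], [0, height], [width, height]], dtype=float)
    fr = np.linalg.solve(B, corners.T).T
    pad = 2
    i0, i1 = int(np.floor(fr[:, 0].min())) - pad, int(np.ceil(fr[:, 0].max())) + pad
    j0, j1 = int(np.floor(fr[:, 1].min())) - pad, int(np.ceil(fr[:, 1].max())) + pad
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    n = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    pts = n @ B.T
    if spec.distortion_amplitude > 0:
        # smooth low-order displacement field with bounded gradient
        amp = spec.distortion_amplitude * spec.a_len
        kx, ky = 2 * math.pi / max(width, 1), 2 * math.pi / max(height, 1)
        phase = 0.0 if rng is None else rng.uniform(0, 2 * math.pi)
        pts = pts + amp * np.column_stack(
            [
                np.sin(ky * pts[:, 1] + phase),
                np.sin(kx * pts[:, 0] + 0.5 * phase),
            ]
        )
    return pts


def _rasterize_gaussians(
    canvas: np.ndarray, pts_px: np.ndarray, amp: float, sigma_px: float
) -> None:
    """Accumulate exact 2D Gaussians of one width at subpixel centers."""
    ny, nx = canvas.shape
    W = int(math.ceil(4.0 * sigma_px))
    off = np.arange(-W, W + 1)
    x0 = np.round(pts_px[:, 0]).astype(int)
    y0 = np.round(pts_px[:, 1]).astype(int)
    keep = (x0 > -W) & (x0 < nx + W) & (y0 > -W) & (y0 < ny + W)
    if not keep.any():
        return
    x0, y0, pts = x0[keep], y0[keep], pts_px[keep]
    dx = x0[:, None] + off[None, :] - pts[:, 0:1]
    dy = y0[:, None] + off[None, :] - pts[:, 1:2]
    gx = np.exp(-0.5 * (dx / sigma_px) ** 2)
    gy = np.exp(-0.5 * (dy / sigma_px) ** 2)
    patch = amp * gy[:, :, None] * gx[:, None, :]  # (n, y, x)
    xi = np.broadcast_to(x0[:, None, None] + off[None, None, :], patch.shape)
    yi = np.broadcast_to(y0[:, None, None] + off[None, :, None], patch.shape)
    ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
    np.add.at(canvas, (yi[ok], xi[ok]), patch[ok])


#: Detector/optics blur added in quadrature when rendering, as a fraction of
#: the pixel size; keeps the sampled image band-limited so the plane-group
#: symmetry is exact to well below the noise floor.
RENDER_PSF_FRACTION = 0.7


def render_lattice_image(
    spec: LatticeSpec,
    motif,
    image_size: int = 1024,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: NoiseSpec | None = None,
) -> tuple[MicrographImage, LatticeModel]:
    """Render a plane-group lattice micrograph and return its ground truth.

    The motif is tiled over the lattice with the symmetry copies of the
    requested plane group: p2 adds a 180°-rotated partner at the cell
    center, p4 four 90°-rotated copies about the 4-fold axis.  A
    :class:`GaussianMotif` is rendered analytically (rotations act on blob
    centers, so symmetry is exact up to pixel sampling); a rasterized motif
    falls back to interpolation-based placement.  White Gaussian noise is
    added at the stated SNR (variance ratio).
    """
    width = height = image_size * pixel_size
    if min(width / spec.a_len, height / spec.b_len) < 5:
        raise GeometryError("unit cell must fit at least 5 times across the image")
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    nodes = _lattice_nodes(spec, width, height, rng)
    canvas = np.zeros((image_size, image_size))
    a, b = spec.basis
    B = np.column_stack([a, b])
    psf2 = (RENDER_PSF_FRACTION * pixel_size) ** 2
    if isinstance(motif, GaussianMotif):
        xy, amps, sigmas = motif.projected_blobs()
        for (frac, angle) in _symmetry_copies(spec):
            offset = B @ np.array(frac)
            th = math.radians(angle + spec.in_plane_rotation)
            R = np.array(
                [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
            )
            for p, amp, s in zip(xy, amps, sigmas):
                pos = (nodes + offset + (R @ p)) / pixel_size
                s_eff = math.sqrt(s**2 + psf2) / pixel_size
                _rasterize_gaussians(canvas, pos, float(amp), s_eff)
    else:
        patch = _motif_patch(motif, pixel_size)
        for (frac, angle) in _symmetry_copies(spec):
            offset = B @ np.array(frac)
            rot = ndimage.rotate(
                patch, angle + spec.in_plane_rotation, reshape=True, order=1,
                mode="constant",
            )
            comb = _splat_comb(canvas.shape, (nodes + offset) / pixel_size)
            canvas += signal.fftconvolve(comb, rot, mode="same")
    truth = LatticeModel.from_basis(a, b, assigned_group=spec.plane_group)
    if noise is not None:
        sigma = math.sqrt(float(canvas.var()) / noise.snr)
        canvas = canvas + rng.normal(0.0, sigma, size=canvas.shape)
    return MicrographImage(pixels=canvas, pixel_size=pixel_size), truth


def render_multi_patch_micrograph(
    patches: list[tuple[LatticeSpec, np.ndarray]],
    image_size: int = 1024,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    motif=None,
    noise: NoiseSpec | None = None,
    micrograph_id: str = "synthetic",
) -> tuple[MicrographImage, ParticleTable]:
    """Render a micrograph with several non-overlapping lattice patches.

    Each patch is a (LatticeSpec, polygon) pair with the polygon given as
    (N, 2) Å vertices; the region is tiled with its own lattice and every
    lattice node inside it becomes a particle record labeled with the true
    plane group and patch index.
    """
    from matplotlib.path import Path as MplPath
    from shapely.geometry import Polygon

    polys = [Polygon(np.asarray(region, dtype=float)) for _, region in patches]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            inter = polys[i].intersection(polys[j]).area
            if inter > 1e-9 * max(polys[i].area, polys[j].area, 1.0):
                raise GeometryError(f"patch regions {i} and {j} overlap")

    if motif is None:
        motif = make_subunit_motif(seed=0)
    canvas = np.zeros((image_size, image_size))
    records = []
    width = height = image_size * pixel_size
    yy, xx = (np.mgrid[0:image_size, 0:image_size] + 0.5) * pixel_size
    pix_pts = np.column_stack([xx.ravel(), yy.ravel()])
    for idx, (spec, region) in enumerate(patches):
        img, _ = render_lattice_image(spec, motif, image_size, pixel_size, noise=None)
        path = MplPath(np.asarray(region, dtype=float))
        mask = path.contains_points(pix_pts).reshape(canvas.shape)
        canvas[mask] += img.pixels[mask]
        nodes = _lattice_nodes(spec, width, height)
        inside = path.contains_points(nodes)
        for x, y in nodes[inside]:
            if 0 <= x < width and 0 <= y < height:
                records.append((x, y, f"patch{idx}", spec.plane_group, micrograph_id))
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        sigma = math.sqrt(float(canvas.var()) / noise.snr) if canvas.var() > 0 else 1.0
        canvas = canvas + rng.normal(0.0, sigma, size=canvas.shape)
    table = (
        ParticleTable.from_records(records) if records else ParticleTable.empty()
    )
    return MicrographImage(pixels=canvas, pixel_size=pixel_size), table


def make_smooth_phantom(
    seed: int, n: int = 64, voxel_size: float = DEFAULT_VOXEL_SIZE
) -> DensityVolume:
    """Seeded smooth compact body for missing-cone evaluation.

    A randomly sized, offset and profiled spheroid — isotropic by
    construction, so any z/x elongation of a degraded copy is entirely the
    missing-cone artifact.  Radius 30–45 Å, center within ±8 Å, profile
    exponent 1.5–2.5.
    """
    rng = np.random.default_rng(seed)
    radius = rng.uniform(30.0, 45.0)
    center = rng.uniform(-8.0, 8.0, 3)
    power = rng.uniform(1.5, 2.5)
    ext = n * voxel_size
    zz, yy, xx = (np.mgrid[0:n, 0:n, 0:n] + 0.5) * voxel_size - ext / 2.0
    r = np.sqrt(
        (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    )
    grid = np.clip(1.0 - (r / radius) ** 2, 0.0, None) ** power
    return DensityVolume(grid=grid, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# missing-cone volumes and projections
# ---------------------------------------------------------------------------

def missing_cone_mask(shape, max_tilt: float) -> np.ndarray:
    """Boolean mask of Fourier voxels inside the missing cone (True = lost).

    A maximum tilt θ_max about an in-plane axis leaves a double cone of
    half-angle (90° − θ_max) about the z axis unsampled; θ_max = 90° means
    full sampling (empty mask).
    """
    if not 0.0 < max_tilt <= 90.0:
        raise ParameterError("max_tilt must lie in (0°, 90°]")
    half_angle = 90.0 - max_tilt
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    kperp = np.sqrt(kx**2 + ky**2)
    tan = math.tan(math.radians(half_angle))
    inside = kperp < np.abs(kz) * tan
    inside[0, 0, 0] = False  # keep the DC term (mean is measured at 0° tilt)
    return inside


def make_missing_cone_volume(
    volume: DensityVolume, max_tilt: float, noise: NoiseSpec
) -> tuple[DensityVolume, DensityVolume, DensityVolume]:
    """Apply a missing Fourier cone and emit a full map plus two half-maps.

    Fourier amplitudes inside the cone of half-angle (90° − max_tilt) about
    z are zeroed; the two half-maps add independent white Gaussian noise
    realizations (seeds ``seed`` and ``seed + 1``) at the stated SNR, and
    the full map is their average.
    """
    inside = missing_cone_mask(volume.shape, max_tilt)
    F = np.fft.fftn(volume.grid.astype(float))
    F[inside] = 0.0
    conv = np.fft.ifftn(F).real
    sigma = math.sqrt(float(conv.var()) / noise.snr)
    halves = []
    for k in (0, 1):
        rng = np.random.default_rng(noise.seed + k)
        halves.append(conv + rng.normal(0.0, sigma, size=conv.shape))
    full = 0.5 * (halves[0] + halves[1])
    mk = lambda g: DensityVolume(
        grid=g, voxel_size=volume.voxel_size, origin=volume.origin.copy()
    )
    return mk(full), mk(halves[0]), mk(halves[1])


def project_volume(
    volume: DensityVolume, tilt: float, in_plane_rotation: float = 0.0
) -> MicrographImage:
    """Line-integral projection of a cubic volume along z after rotation.

    The volume is first rotated by ``in_plane_rotation`` about z, then
    tilted about the y axis, and summed along z (times the voxel size, so
    the projection is a true line integral in density·Å).  By the Fourier
    slice theorem the transform of the projection equals the central slice
    of the volume transform at that orientation.
    """
    nz, ny, nx = volume.shape
    if not (nz == ny == nx):
        raise GeometryError("projection requires a cubic volume")
    th_z = math.radians(in_plane_rotation)
    th_t = math.radians(tilt)
    Rz = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(th_z), -math.sin(th_z)],
            [0.0, math.sin(th_z), math.cos(th_z)],
        ]
    )  # acts on (z, y, x) index vectors: rotation about the z index axis
    Ry = np.array(
        [
            [math.cos(th_t), 0.0, -math.sin(th_t)],
            [0.0, 1.0, 0.0],
            [math.sin(th_t), 0.0, math.cos(th_t)],
        ]
    )  # tilt about the y index axis
    R = Ry @ Rz
    center = (np.array(volume.shape) - 1) / 2.0
    rotated = ndimage.affine_transform(
        volume.grid.astype(float),
        R.T,  # output->input mapping uses the inverse rotation
        offset=center - R.T @ center,
        order=3,
        mode="constant",
        cval=0.0,
        prefilter=True,
    )
    proj = rotated.sum(axis=0) * volume.voxel_size
    return MicrographImage(pixels=proj, pixel_size=volume.voxel_size)
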