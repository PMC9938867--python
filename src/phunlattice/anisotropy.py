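"""Global and directional Fourier shell correlation (FSC).

Tilt-limited 2D-crystal data leaves a missing cone in Fourier space, so the
reconstruction's resolution is direction dependent.  The directional FSC
restricts the usual half-map shell correlation

    FSC(s) = Re Σ F₁ F₂* / sqrt(Σ|F₁|² Σ|F₂|²)

to Fourier voxels inside an angular cone about each sampled direction,
giving one curve per direction — a direct representation of preferred
orientation that later drives the transfer-function (OTF) construction for
deconvolution.

Conventions: shells are one Fourier voxel wide up to Nyquist; directions
sample the upper hemisphere on a Fibonacci spiral (Friedel symmetry makes
the lower hemisphere redundant); voxels belong to every cone that contains
them, with each Friedel pair counted once; empty cone∩shell bins are
undefined (NaN), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DensityVolume, GeometryError, ParameterError

__all__ = [
    "FSCCurve",
    "DirectionalFSCResult",
    "ResolutionEstimate",
    "fibonacci_hemisphere",
    "global_fsc",
    "directional_fsc",
    "resolution_at_threshold",
]


@dataclass
class FSCCurve:
    """FSC values over Fourier shells.

    ``freqs`` are shell-center spatial frequencies in 1/Å; undefined shells
    hold NaN.
    """

    freqs: np.ndarray
    values: np.ndarray
    shell_width: float  # 1/Å

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise GeometryError("freqs and values must have the same shape")

    @property
    def n_shells(self) -> int:
        return len(self.freqs)


@dataclass
class DirectionalFSCResult:
    directions: np.ndarray  # (n, 3) unit vectors, upper hemisphere
    cone_half_angle: float  # degrees
    curves: list[FSCCurve]
    global_curve: FSCCurve
    counts: np.ndarray = field(default=None)  # (n, n_shells) voxels per bin


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the upper hemisphere (z >= 0)."""
    k = np.arange(n)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = (k + 0.5) / n  # uniform in z on (0, 1] -> uniform in solid angle
    phi = 2.0 * math.pi * k / golden
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _check_pair(half1: DensityVolume, half2: DensityVolume):
    if half1.grid.shape != half2.grid.shape:
        raise GeometryError(
            f"half-map shapes differ: {half1.grid.shape} vs {half2.grid.shape}"
        )
    if abs(half1.voxel_size - half2.voxel_size) > 1e-6:
        raise GeometryError("half-map voxel sizes differ")
    n = half1.grid.shape[0]
    if half1.grid.shape != (n, n, n):
        raise GeometryError("FSC requires cubic volumes")


def _shell_geometry(n: int, voxel_size: float):
    """Per-voxel shell index (one-voxel-wide shells) and k unit vectors."""
    f = np.fft.fftfreq(n)  # cycles per voxel
    kz = f[:, None, None]
    ky = f[None, :, None]
    kx = f[None, None, :]
    r = np.sqrt(kx**2 + ky**2 + kz**2) * n  # radius in Fourier voxels
    shell = np.rint(r).astype(int)
    return shell, (kx, ky, kz), r


def global_fsc(half1: DensityVolume, half2: DensityVolume) -> FSCCurve:
    """FSC between two half-maps over one-voxel-wide shells up to Nyquist."""
    _check_pair(half1, half2)
    n = half1.grid.shape[0]
    F1 = np.fft.fftn(half1.grid.astype(float))
    F2 = np.fft.fftn(half2.grid.astype(float))
    shell, _, _ = _shell_geometry(n, half1.voxel_size)
    n_shells = n // 2 + 1
    sel = shell < n_shells
    s = shell[sel]
    num = np.bincount(s, weights=(F1[sel] * np.conj(F2[sel])).real, minlength=n_shells)
    d1 = np.bincount(s, weights=np.abs(F1[sel]) ** 2, minlength=n_shells)
    d2 = np.bincount(s, weights=np.abs(F2[sel]) ** 2, minlength=n_shells)
    denom = np.sqrt(d1 * d2)
    values = np.divide(num, denom, out=np.full(n_shells, np.nan), where=denom > 0)
    shell_width = 1.0 / (n * half1.voxel_size)
    freqs = np.arange(n_shells) * shell_width
    return FSCCurve(freqs=freqs, values=values, shell_width=shell_width)


def directional_fsc(
    half1: DensityVolume,
    half2: DensityVolume,
    cone_half_angle: float = 20.0,
    n_directions: int = 48,
) -> DirectionalFSCResult:
    """Per-direction FSC restricted to angular cones on the hemisphere.

    Every Fourier voxel contributes to every cone containing it (cones
    overlap); each Friedel pair is counted once by folding k to the upper
    hemisphere.  Bins with an empty cone∩shell intersection are NaN.
    """
    if not 10.0 <= cone_half_angle <= 45.0:
        raise ParameterError("cone_half_angle must lie in [10°, 45°]")
    _check_pair(half1, half2)
    n = half1.grid.shape[0]
    F1 = np.fft.fftn(half1.grid.astype(float))
    F2 = np.fft.fftn(half2.grid.astype(float))
    shell, (kx, ky, kz), r = _shell_geometry(n, half1.voxel_size)
    n_shells = n // 2 + 1

    # Friedel fold: keep one representative of each +/-k pair
    kz_b = np.broadcast_to(kz, r.shape)
    ky_b = np.broadcast_to(ky, r.shape)
    kx_b = np.broadcast_to(kx, r.shape)
    hemi = (kz_b > 0) | (
        (kz_b == 0) & ((ky_b > 0) | ((ky_b == 0) & (kx_b > 0)))
    )
    sel = hemi & (shell < n_shells) & (r > 0)

    kvec = np.column_stack([kx_b[sel], ky_b[sel], kz_b[sel]])
    kvec /= np.linalg.norm(kvec, axis=1, keepdims=True)
    s_idx = shell[sel]
    t1 = F1[sel]
    t2 = F2[sel]
    prod = (t1 * np.conj(t2)).real
    p1 = np.abs(t1) ** 2
    p2 = np.abs(t2) ** 2

    dirs = fibonacci_hemisphere(n_directions)
    cos_cone = math.cos(math.radians(cone_half_angle))
    curves = []
    counts = np.zeros((n_directions, n_shells), dtype=int)
    shell_width = 1.0 / (n * half1.voxel_size)
    freqs = np.arange(n_shells) * shell_width
    for i, d in enumerate(dirs):
        # cone about ±d (Friedel): |cos| of the angle to the direction
        inc = np.abs(kvec @ d) >= cos_cone
        s = s_idx[inc]
        num = np.bincount(s, weights=prod[inc], minlength=n_shells)
        d1 = np.bincount(s, weights=p1[inc], minlength=n_shells)
        d2 = np.bincount(s, weights=p2[inc], minlength=n_shells)
        cnt = np.bincount(s, minlength=n_shells)
        counts[i] = cnt
        denom = np.sqrt(d1 * d2)
        vals = np.divide(
            num, denom, out=np.full(n_shells, np.nan), where=(denom > 0) & (cnt > 0)
        )
        vals[cnt == 0] = np.nan
        curves.append(FSCCurve(freqs=freqs.copy(), values=vals, shell_width=shell_width))
    return DirectionalFSCResult(
        directions=dirs,
        cone_half_angle=cone_half_angle,
        curves=curves,
        global_curve=global_fsc(half1, half2),
        counts=counts,
    )


def autocorrelation_width(volume: DensityVolume, axis: int) -> float:
    """FWHM (in voxels, interpolated) of the volume's autocorrelation
    profile through the origin along one axis (0=z, 1=y, 2=x)."""
    F = np.fft.fftn(volume.grid.astype(float) - float(volume.grid.mean()))
    ac = np.fft.ifftn(np.abs(F) ** 2).real
    ac = np.fft.fftshift(ac)
    n = volume.grid.shape[axis]
    center = [s // 2 for s in volume.grid.shape]
    idx = list(center)
    prof = np.empty(n)
    for i in range(n):
        idx[axis] = i
        prof[i] = ac[tuple(idx)]
    prof = prof / prof.max()
    c = n // 2
    half = 0.5
    right = c
    while right + 1 < n and prof[right + 1] >= half:
        right += 1
    if right + 1 >= n:
        return float(n)
    frac = (prof[right] - half) / (prof[right] - prof[right + 1])
    left = c
    while left - 1 >= 0 and prof[left - 1] >= half:
        left -= 1
    if left == 0:
        return float(n)
    frac_l = (prof[left] - half) / (prof[left] - prof[left - 1])
    return float((right + frac) - (left - frac_l))


def elongation_ratio(volume: DensityVolume) -> float:
    """z/x autocorrelation-width ratio; > 1 signals missing-cone stretching."""
    return autocorrelation_width(volume, 0) / autocorrelation_width(volume, 2)


@dataclass
class ResolutionEstimate:
    frequency: float  # 1/Å at the threshold crossing
    resolution: float  # Å
    crossed: bool  # False when the curve never drops below the threshold


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = 0.143
) -> ResolutionEstimate:
    """First crossing of the FSC curve below ``threshold``.

    Linear interpolation between the last shell above and the first shell
    below the threshold.  A curve that never crosses returns Nyquist with
    ``crossed=False``.  NaN (undefined) shells are skipped.
    """
    freqs = curve.freqs
    vals = curve.values
    ok = np.isfinite(vals)
    f = freqs[ok]
    v = vals[ok]
    if len(v) == 0:
        raise ParameterError("curve has no defined shells")
    for i in range(1, len(v)):
        if v[i] < threshold <= v[i - 1]:
            # linear interpolation in frequency
            t = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            fc = f[i - 1] + t * (f[i] - f[i - 1])
            return ResolutionEstimate(
                frequency=float(fc), resolution=float(1.0 / fc), crossed=True
            )
    fn = float(f[-1])
    return ResolutionEstimate(
        frequency=fn, resolution=float(1.0 / fn) if fn > 0 else math.inf, crossed=False
    )
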