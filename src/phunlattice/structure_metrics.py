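"""Model- and map-comparison metrics for lattice assemblies.

The operations here quantify the structural claims made about the shell
lattice: how similar the two subunits of the asymmetric dimer are (Kabsch
superposition and selection-wise RMSD), how well a tetramer model explains
a density map (rigid-body fitting with a masked real-space correlation),
the geometry of the channels through the lattice (corner-to-corner
diagonals), the quaternary rotation relating two tetramer assemblies, the
residue contacts that form the four lattice interfaces, and protein mass
from sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import (
    Atom,
    AtomicModel,
    Chain,
    DensityVolume,
    GeometryError,
    ParameterError,
    Residue,
)

__all__ = [
    "RigidTransform",
    "FitResult",
    "superpose_kabsch",
    "rmsd_on_selection",
    "simulate_density",
    "fit_model_in_map",
    "expand_lattice_assembly",
    "channel_geometry",
    "inter_assembly_rotation",
    "RotationResult",
    "contact_map",
    "Contact",
    "sequence_mass",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
]


# ---------------------------------------------------------------------------
# rigid transforms and superposition
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper (det = 1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("rotation columns must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def superpose_kabsch(
    coords_ref: np.ndarray, coords_mov: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the transform mapping ``coords_mov`` onto ``coords_ref`` and
    the RMSD after applying it.  Degenerate (collinear or duplicate) sets
    raise GeometryError.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("coordinate sets must be matched (n, 3) arrays")
    if len(P) < 3:
        raise GeometryError("need at least 3 paired points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: second singular value of either centered set
    if min(np.linalg.svd(P0, compute_uv=False)[1],
           np.linalg.svd(Q0, compute_uv=False)[1]) < 1e-8:
        raise GeometryError("degenerate (collinear/duplicate) coordinates")
    Hm = Q0.T @ P0
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    tr = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(((tr.apply(Q) - P) ** 2).sum(axis=1).mean()))
    return tr, rmsd


def _resolve_selection(model: AtomicModel, selection):
    """A selection is a region name, an inclusive (start, end) residue
    range, or a list of residue numbers."""
    if isinstance(selection, str):
        if selection not in model.regions:
            raise ParameterError(f"unknown region {selection!r}")
        lo, hi = model.regions[selection]
        return set(range(lo, hi + 1))
    if isinstance(selection, tuple) and len(selection) == 2:
        return set(range(selection[0], selection[1] + 1))
    return set(selection)


def _paired_ca(chain_a: Chain, chain_b: Chain, residues: set[int] | None):
    """Cα pairs present in both chains (matched by residue number)."""
    ca_a = {r.seqid: a.xyz for r in chain_a.residues for a in r.atoms if a.name == "CA"}
    ca_b = {r.seqid: a.xyz for r in chain_b.residues for a in r.atoms if a.name == "CA"}
    common = sorted(set(ca_a) & set(ca_b))
    if residues is not None:
        common = [s for s in common if s in residues]
    if not common:
        raise ParameterError("empty selection: no shared Cα in both chains")
    return (
        np.array([ca_a[s] for s in common]),
        np.array([ca_b[s] for s in common]),
    )


def rmsd_on_selection(
    model: AtomicModel,
    chain_pair: tuple[str, str],
    align_selection,
    report_selections: dict,
) -> dict:
    """Align two chains on one Cα selection, report RMSD over others.

    The superposition is computed from ``align_selection`` only and then
    applied unchanged when evaluating each entry of ``report_selections``
    (mapping name -> selection).
    """
    ca, cb = (model.chain(c) for c in chain_pair)
    ref, mov = _paired_ca(ca, cb, _resolve_selection(model, align_selection))
    tr, _ = superpose_kabsch(ref, mov)
    out = {}
    for name, sel in report_selections.items():
        ref_s, mov_s = _paired_ca(ca, cb, _resolve_selection(model, sel))
        out[name] = float(
            np.sqrt(((tr.apply(mov_s) - ref_s) ** 2).sum(axis=1).mean())
        )
    return out


# ---------------------------------------------------------------------------
# simulated density and rigid-body map fitting
# ---------------------------------------------------------------------------

#: Approximate atomic numbers used as Gaussian weights.
_ELEMENT_WEIGHT = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0,
                   "SE": 34.0, "FE": 26.0, "MG": 12.0, "ZN": 30.0}


def _gaussian_sigma(resolution: float) -> float:
    # FT of exp(-r²/2σ²) falls to 1/2 at s = 1/resolution:
    # exp(-2π²σ²s²) = 0.5  =>  σ = resolution·sqrt(ln2/2)/π
    return resolution * math.sqrt(math.log(2.0) / 2.0) / math.pi


def simulate_density(
    model: AtomicModel,
    resolution: float,
    voxel_size: float | None = None,
    grid_like: DensityVolume | None = None,
    pad: float = 10.0,
) -> DensityVolume:
    """Render an atomic model as a sum of per-atom Gaussians.

    The Gaussian width is calibrated so the Fourier amplitude envelope
    falls to one half at spatial frequency 1/resolution.  Either sample on
    the grid of ``grid_like`` or on a new cubic-voxel grid enclosing the
    model with ``pad`` Å margin.
    """
    coords = model.all_coords()
    if len(coords) == 0:
        raise ParameterError("model has no atoms")
    if grid_like is not None:
        voxel = grid_like.voxel_size
        origin = grid_like.origin
        shape = grid_like.grid.shape
    else:
        voxel = voxel_size if voxel_size is not None else resolution / 3.0
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        shape = tuple(
            max(2, int(math.ceil((hi[i] - lo[i]) / voxel))) for i in (2, 1, 0)
        )
        origin = lo
    if resolution < 2.0 * voxel:
        raise ParameterError(
            f"resolution {resolution} Å unsupported at voxel {voxel} Å"
        )
    sigma = _gaussian_sigma(resolution)
    grid = np.zeros(shape)
    nz, ny, nx = shape
    cutoff = 4.0 * sigma
    weights = []
    for ch in model.chains:
        for res in ch.residues:
            for at in res.atoms:
                weights.append(
                    (_ELEMENT_WEIGHT.get(at.element.upper(), 6.0) * at.occupancy,
                     at.xyz)
                )
    for w, xyz in weights:
        # local window in voxel indices (x, y, z)
        ijk = (xyz - origin) / voxel
        lo_i = np.maximum(np.floor(ijk - cutoff / voxel).astype(int), 0)
        hi_i = np.minimum(
            np.ceil(ijk + cutoff / voxel).astype(int) + 1, [nx, ny, nz]
        )
        if np.any(lo_i >= hi_i):
            continue
        xs = (np.arange(lo_i[0], hi_i[0]) + 0.0) * voxel + origin[0]
        ys = (np.arange(lo_i[1], hi_i[1]) + 0.0) * voxel + origin[1]
        zs = (np.arange(lo_i[2], hi_i[2]) + 0.0) * voxel + origin[2]
        gx = np.exp(-0.5 * ((xs - xyz[0]) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - xyz[1]) / sigma) ** 2)
        gz = np.exp(-0.5 * ((zs - xyz[2]) / sigma) ** 2)
        grid[lo_i[2]:hi_i[2], lo_i[1]:hi_i[1], lo_i[0]:hi_i[0]] += (
            w * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    return DensityVolume(grid=grid, voxel_size=voxel, origin=np.asarray(origin, float))


@dataclass
class FitResult:
    transform: RigidTransform
    masked_cc: float
    converged: bool = True
    n_evaluations: int = 0


def _masked_cc(map_grid, sim_grid, mask):
    w = mask.reshape(-1)
    a = map_grid.reshape(-1).astype(float)
    b = sim_grid.reshape(-1).astype(float)
    wsum = w.sum()
    if wsum <= 0:
        raise ParameterError("empty mask")
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    num = (w * (a - am) * (b - bm)).sum()
    den = math.sqrt((w * (a - am) ** 2).sum() * (w * (b - bm) ** 2).sum())
    return num / den if den > 0 else 0.0


def soft_mask_from_model(
    model: AtomicModel,
    grid_like: DensityVolume,
    resolution: float,
    threshold_sigma: float = 1.0,
    edge_voxels: int = 6,
) -> np.ndarray:
    """Soft fit mask: simulated model density thresholded at
    ``threshold_sigma`` standard deviations, with a cosine edge."""
    from scipy import ndimage

    sim = simulate_density(model, resolution, grid_like=grid_like)
    hard = sim.grid > sim.grid.mean() + threshold_sigma * sim.grid.std()
    if not hard.any():
        raise ParameterError("empty mask")
    dist = ndimage.distance_transform_edt(~hard)
    soft = 0.5 * (1.0 + np.cos(np.pi * np.clip(dist / edge_voxels, 0.0, 1.0)))
    return soft


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(v).as_matrix()


def fit_model_in_map(
    model: AtomicModel,
    density: DensityVolume,
    mask: np.ndarray | None = None,
    resolution: float = 10.0,
    global_search: bool = False,
    coarse_rot_deg: float = 10.0,
    max_coarse_deg: float = 25.0,
) -> FitResult:
    """Rigid-body fit maximizing the masked real-space correlation.

    Candidate orientations (identity plus, optionally, a coarse grid of
    axis rotations up to ``max_coarse_deg``) are scored after an FFT
    translation search; the best pose is refined over all six degrees of
    freedom with Powell's method.  The mask defaults to a soft mask built
    from the model's own simulated density.
    """
    from scipy import optimize, signal

    if mask is None:
        mask = soft_mask_from_model(model, density, resolution)
    if np.asarray(mask).sum() <= 0:
        raise ParameterError("empty mask")

    center = model.all_coords().mean(axis=0)
    n_eval = 0

    def pose_model(rotvec, shift):
        R = _rotvec_to_matrix(rotvec)
        t = np.asarray(shift) + center - R @ center
        return model.transformed(R, t)

    def score(rotvec, shift):
        nonlocal n_eval
        n_eval += 1
        sim = simulate_density(pose_model(rotvec, shift), resolution,
                               grid_like=density)
        return _masked_cc(density.grid, sim.grid, mask)

    def best_translation(rotvec):
        # FFT cross-correlation between the map and the posed model density
        sim = simulate_density(pose_model(rotvec, np.zeros(3)), resolution,
                               grid_like=density)
        a = (density.grid * mask).astype(float)
        b = sim.grid.astype(float)
        cc = np.fft.ifftn(np.fft.fftn(a) * np.conj(np.fft.fftn(b))).real
        shift_vox = np.array(np.unravel_index(np.argmax(cc), cc.shape))
        shift_vox = (shift_vox + np.array(cc.shape) // 2) % np.array(cc.shape) - (
            np.array(cc.shape) // 2
        )
        return shift_vox[::-1] * density.voxel_size  # (x, y, z) Å

    candidates = [np.zeros(3)]
    if global_search:
        axes = np.vstack([np.eye(3), -np.eye(3),
                          [[1, 1, 0], [1, 0, 1], [0, 1, 1]]]).astype(float)
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        mags = np.arange(coarse_rot_deg, max_coarse_deg + 1e-9, coarse_rot_deg)
        for ax in axes:
            for m in mags:
                candidates.append(np.radians(m) * ax)
    best = (-2.0, None, None)
    for rv in candidates:
        sh = best_translation(rv)
        sc = score(rv, sh)
        if sc > best[0]:
            best = (sc, rv, sh)
    _, rv0, sh0 = best

    x0 = np.concatenate([rv0, sh0])
    scale = np.array([0.1, 0.1, 0.1, 2.0, 2.0, 2.0])

    def neg(x):
        return -score(x[:3] * scale[:3] + 0.0, x[3:] * scale[3:])

    res = optimize.minimize(
        neg, np.concatenate([rv0 / scale[:3], sh0 / scale[3:]]),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 600},
    )
    rv = res.x[:3] * scale[:3]
    sh = res.x[3:] * scale[3:]
    R = _rotvec_to_matrix(rv)
    t = sh + center - R @ center
    return FitResult(
        transform=RigidTransform(rotation=R, translation=t),
        masked_cc=float(-res.fun),
        converged=bool(res.success),
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# lattice expansion and channel geometry
# ---------------------------------------------------------------------------

def expand_lattice_assembly(
    tetramer: AtomicModel,
    a_vec: np.ndarray,
    b_vec: np.ndarray,
    n: int = 2,
    m: int = 2,
    clash_cutoff: float = 1.5,
    clash_warn_fraction: float = 0.05,
) -> AtomicModel:
    """Tile ``n × m`` copies of a tetramer by integer lattice translations.

    The basis vectors live in the lattice plane (z = 0 when given as 2D).
    Chains of copy (i, j) are renamed ``<chain>_<i>_<j>`` (copy (0, 0)
    keeps bare names).  A clash warning is emitted when more than
    ``clash_warn_fraction`` of heavy atoms approach another copy within
    ``clash_cutoff`` Å.
    """
    a3 = np.zeros(3)
    b3 = np.zeros(3)
    a3[: len(np.atleast_1d(a_vec))] = np.asarray(a_vec, dtype=float)
    b3[: len(np.atleast_1d(b_vec))] = np.asarray(b_vec, dtype=float)
    if np.linalg.norm(np.cross(a3, b3)) < 1e-9:
        raise GeometryError("degenerate lattice basis")
    chains = []
    for i in range(n):
        for j in range(m):
            shift = i * a3 + j * b3
            for ch in tetramer.chains:
                name = ch.chain_id if (i, j) == (0, 0) else f"{ch.chain_id}_{i}_{j}"
                residues = [
                    Residue(
                        r.seqid, r.name, r.icode,
                        [Atom(a.name, a.element, a.xyz + shift, a.b,
                              a.occupancy, a.het) for a in r.atoms],
                    )
                    for r in ch.residues
                ]
                chains.append(Chain(name, residues))
    out = AtomicModel(chains=chains, regions=dict(tetramer.regions))
    # clash check across copies
    per_copy = len(tetramer.chains)
    coords, copy_id = [], []
    for k, ch in enumerate(out.chains):
        c = ch.atom_coords(heavy_only=True)
        coords.append(c)
        copy_id.extend([k // per_copy] * len(c))
    coords = np.vstack(coords)
    copy_id = np.array(copy_id)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(clash_cutoff, output_type="ndarray")
    if len(pairs):
        cross = copy_id[pairs[:, 0]] != copy_id[pairs[:, 1]]
        frac = len(np.unique(pairs[cross])) / len(coords)
        if frac > clash_warn_fraction:
            warnings.warn(
                f"{frac:.1%} of heavy atoms clash across lattice copies",
                stacklevel=2,
            )
    return out


def channel_geometry(
    assembly: AtomicModel, corners: list
) -> tuple[float, float]:
    """Corner-to-corner diagonals of a channel.

    ``corners`` are four (chain_id, selection) pairs in cyclic order; each
    corner is represented by the centroid of its Cα atoms.  Returns the two
    diagonals (shorter, longer) in Å.
    """
    if len(corners) != 4:
        raise ParameterError("a channel needs exactly 4 corner selections")
    pts = []
    for chain_id, sel in corners:
        ch = assembly.chain(chain_id)
        res = _resolve_selection(assembly, sel)
        ca = np.array(
            [a.xyz for r in ch.residues if r.seqid in res
             for a in r.atoms if a.name == "CA"]
        )
        if len(ca) == 0:
            raise ParameterError(f"corner selection empty on chain {chain_id}")
        pts.append(ca.mean(axis=0))
    d1 = float(np.linalg.norm(pts[0] - pts[2]))
    d2 = float(np.linalg.norm(pts[1] - pts[3]))
    return (min(d1, d2), max(d1, d2))


# ---------------------------------------------------------------------------
# inter-assembly rotation
# ---------------------------------------------------------------------------

@dataclass
class RotationResult:
    angle: float  # degrees, full rotation between corresponding subunits
    axis: np.ndarray  # unit rotation axis
    out_of_plane: float  # degrees between the axis and the lattice normal (z)


def inter_assembly_rotation(
    assembly1: AtomicModel,
    assembly2: AtomicModel,
    anchor_chain: str,
    probe_chain: str | None = None,
) -> RotationResult:
    """Residual rotation between two assemblies after anchoring one chain.

    Assembly 2 is superposed onto assembly 1 using the anchor chain's Cα
    set; the rotation relating the corresponding probe chains afterwards
    measures how the quaternary arrangement differs.  ``angle`` is
    arccos((tr R − 1)/2); ``out_of_plane`` reports the angle between the
    rotation axis and the z axis (the lattice normal), so an in-plane
    reorientation gives 0° and a flip about an in-plane axis gives 90°.
    """
    chains2 = [c.chain_id for c in assembly2.chains]
    if anchor_chain not in chains2 or anchor_chain not in [
        c.chain_id for c in assembly1.chains
    ]:
        raise ParameterError(f"anchor chain {anchor_chain!r} missing")
    if probe_chain is None:
        others = [c for c in chains2 if c != anchor_chain]
        if not others:
            raise ParameterError("no probe chain available")
        probe_chain = others[0]
    ref_a, mov_a = _paired_ca(
        assembly1.chain(anchor_chain), assembly2.chain(anchor_chain), None
    )
    tr_anchor, _ = superpose_kabsch(ref_a, mov_a)
    ref_p, mov_p = _paired_ca(
        assembly1.chain(probe_chain), assembly2.chain(probe_chain), None
    )
    tr_probe, _ = superpose_kabsch(ref_p, tr_anchor.apply(mov_p))
    R = tr_probe.rotation
    angle = float(np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))))
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    cosz = abs(axis[2])
    out_of_plane = float(np.degrees(np.arccos(np.clip(cosz, 0.0, 1.0))))
    return RotationResult(angle=angle, axis=axis, out_of_plane=out_of_plane)


# ---------------------------------------------------------------------------
# interface contacts
# ---------------------------------------------------------------------------

@dataclass
class Contact:
    chain1: str
    res1: int
    region1: str | None
    chain2: str
    res2: int
    region2: str | None
    distance: float
    interface: str


#: Region-pair -> interface classification.  The four lattice interfaces:
#: the Diamond channel is threaded by the N-terminal tail domain swap,
#: hairpin–hairpin lateral contacts close a channel (Closed Hairpin),
#: hairpin-to-C-terminal-exit contacts keep it open (Open Hairpin), and
#: the large flexible loops meet at the Loop interface.
DEFAULT_INTERFACE_RULES: dict[frozenset, str] = {
    frozenset(["beta_hairpin"]): "closed_hairpin",
    frozenset(["beta_hairpin", "structured_loop"]): "closed_hairpin",
    frozenset(["beta_hairpin", "C_tail"]): "open_hairpin",
    frozenset(["loop"]): "loop",
    frozenset(["N_tail"]): "diamond",
    frozenset(["N_tail", None]): "diamond",
}


def _region_of(model: AtomicModel, seqid: int) -> str | None:
    for name, (lo, hi) in model.regions.items():
        if lo <= seqid <= hi:
            return name
    return None


def contact_map(
    model: AtomicModel,
    cutoff: float = 4.5,
    rules: dict | None = None,
) -> list[Contact]:
    """Inter-chain heavy-atom residue contacts within ``cutoff`` Å.

    Each contact is tagged with the annotated regions of both partners and
    classified into a named interface by region-pair rules (unmatched
    pairs are labeled "other").  The contact list holds one entry per
    residue pair at its minimal atom distance.
    """
    if not 3.0 <= cutoff <= 6.0:
        raise ParameterError("cutoff must lie in [3, 6] Å")
    if len(model.chains) < 2:
        raise ParameterError("contacts need at least two chains")
    rules = DEFAULT_INTERFACE_RULES if rules is None else rules
    atoms = []
    for ch in model.chains:
        for res in ch.residues:
            for at in res.atoms:
                if at.element.upper() != "H":
                    atoms.append((ch.chain_id, res.seqid, at.xyz))
    coords = np.array([a[2] for a in atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple, float] = {}
    for i, j in pairs:
        ci, ri, _ = atoms[i]
        cj, rj, _ = atoms[j]
        if ci == cj:
            continue
        key = (ci, ri, cj, rj) if (ci, ri) <= (cj, rj) else (cj, rj, ci, ri)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < best.get(key, math.inf):
            best[key] = d
    out = []
    for (c1, r1, c2, r2), d in sorted(best.items()):
        reg1, reg2 = _region_of(model, r1), _region_of(model, r2)
        iface = rules.get(frozenset([reg1, reg2]))
        if iface is None:
            iface = rules.get(frozenset([reg1])) if reg1 == reg2 else None
        out.append(
            Contact(c1, r1, reg1, c2, r2, reg2, d, iface or "other")
        )
    return out


# ---------------------------------------------------------------------------
# sequence mass
# ---------------------------------------------------------------------------

#: Average residue masses (Da) of amino acids in peptide linkage.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "U": 103.1388,  # selenocysteine treated by sulfur analogy
}

WATER_MASS = 18.01528


def sequence_mass(sequence: str) -> float:
    """Average molecular mass of a protein sequence in kDa.

    Sum of average residue masses plus one water.  Unknown letters raise a
    ParameterError naming the offending character.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ParameterError("empty sequence")
    total = WATER_MASS
    for ch in seq:
        if ch not in AVERAGE_RESIDUE_MASS:
            raise ParameterError(f"unknown amino-acid letter {ch!r}")
        total += AVERAGE_RESIDUE_MASS[ch]
    return total / 1000.0
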