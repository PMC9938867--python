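"""File formats, domain containers, configuration and logging.

Everything downstream works in one internal unit system: ångströms for
lengths, degrees for angles.  Volumes and images carry their sampling
(voxel/pixel size in Å) with them so no operation ever needs a global
pixel-size setting.

Formats handled here:

* MRC2014 volumes and images (mode 2, 32-bit float) through :mod:`gemmi`.
* PDB / mmCIF atomic models through :mod:`gemmi`.
* STAR-like whitespace-delimited particle tables (a small clean-room
  schema: one ``data_`` block with a ``loop_`` header naming the columns).
* TIFF micrographs through :mod:`tifffile` (single-page grayscale only).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "FormatError",
    "UnsupportedFormatError",
    "SchemaError",
    "GeometryError",
    "ParameterError",
    "DensityVolume",
    "MicrographImage",
    "ParticleTable",
    "Atom",
    "Residue",
    "Chain",
    "AtomicModel",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "read_model",
    "read_particles",
    "write_particles",
    "load_config",
    "setup_logging",
    "SYMMETRY_LABELS",
]

logger = logging.getLogger("phunlattice")

SYMMETRY_LABELS = ("p1", "p2", "p4", "unassigned")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class UnsupportedFormatError(FormatError):
    """The file parses but uses a variant this package does not support."""


class SchemaError(FormatError):
    """A table is missing required columns or contains illegal labels."""


class GeometryError(ValueError):
    """Shapes, grids or coordinates are inconsistent."""


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


# ---------------------------------------------------------------------------
# configuration & logging
# ---------------------------------------------------------------------------

def load_config(path: str | os.PathLike) -> dict:
    """Load a structured key/value (YAML) configuration file.

    Returns a plain nested dict; an empty file yields ``{}``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def setup_logging(level: int | str = "INFO") -> logging.Logger:
    """Configure the package logger once; repeated calls only adjust the level."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


# ---------------------------------------------------------------------------
# gridded densities
# ---------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """A 3D gridded density map.

    Attributes
    ----------
    grid:
        float32 array indexed ``(z, y, x)``.
    voxel_size:
        Isotropic sampling in Å per voxel.
    origin:
        Å offset of the first voxel, ``(x, y, z)``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise GeometryError("volume grid must be 3D with all dimensions >= 2")
        if not self.voxel_size > 0:
            raise ParameterError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy_with(self, grid: np.ndarray) -> "DensityVolume":
        return replace(self, grid=np.asarray(grid, dtype=np.float32))


@dataclass
class MicrographImage:
    """A 2D micrograph-scale image with its pixel size in Å."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise GeometryError("micrograph must be a 2D array")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("micrograph contains non-finite pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in Å."""
        ny, nx = self.pixels.shape
        return nx * self.pixel_size, ny * self.pixel_size


# ---------------------------------------------------------------------------
# MRC through gemmi
# ---------------------------------------------------------------------------

def _read_ccp4(path) -> "gemmi.Ccp4Map":
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
        # normalize axis permutations (mapcrs) to x-fastest storage
        m.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read MRC map {path}: {exc}") from exc
    return m


def read_volume(path: str | os.PathLike) -> DensityVolume:
    """Read an MRC2014 volume.

    The voxel size must be isotropic (to 1e-3 Å); the MRC ``ORIGIN`` words are
    carried through.  Axis permutations declared by ``mapcrs`` are normalized
    at read so ``grid`` is always stored z-slowest.
    """
    m = _read_ccp4(path)
    spac = np.array(m.grid.spacing, dtype=float)
    if spac.min() <= 0:
        raise FormatError(f"{path}: non-positive voxel size in header")
    if spac.max() - spac.min() > 1e-3:
        raise UnsupportedFormatError(
            f"{path}: anisotropic voxel sizes {spac} are not supported"
        )
    arr = np.array(m.grid, copy=True)
    if np.isnan(arr).any():
        raise FormatError(f"{path}: map contains NaN after setup (truncated data?)")
    # gemmi exposes the grid x-fastest as arr[x, y, z]; transpose to (z, y, x)
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    return DensityVolume(grid=grid, voxel_size=float(spac.mean()), origin=origin)


def write_volume(vol: DensityVolume, path: str | os.PathLike) -> None:
    """Write a mode-2 MRC2014 volume with cell = voxel_size × dimensions."""
    import gemmi

    nz, ny, nx = vol.grid.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(vol.grid.transpose(2, 1, 0), dtype=np.float32)
    )
    v = vol.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), vol.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


def read_image(path: str | os.PathLike, pixel_size: float | None = None) -> MicrographImage:
    """Read a 2D micrograph from MRC or TIFF.

    MRC files carry their own pixel size; for TIFF, ``pixel_size`` must be
    given explicitly.
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise UnsupportedFormatError(f"{path}: only single-page 2D TIFF supported")
        if pixel_size is None:
            raise ParameterError("pixel_size required for TIFF micrographs")
        return MicrographImage(pixels=arr.astype(np.float32), pixel_size=pixel_size)
    m = _read_ccp4(path)
    arr = np.array(m.grid, copy=True)
    grid = arr.transpose(2, 1, 0)
    if grid.shape[0] != 1:
        raise UnsupportedFormatError(f"{path}: expected a single-section image")
    spac = np.array(m.grid.spacing, dtype=float)
    return MicrographImage(
        pixels=grid[0].astype(np.float32), pixel_size=float(spac[:2].mean())
    )


def write_image(img: MicrographImage, path: str | os.PathLike) -> None:
    """Write a micrograph as a single-section mode-2 MRC."""
    import gemmi

    ny, nx = img.pixels.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(img.pixels[None].transpose(2, 1, 0), dtype=np.float32)
    )
    v = img.pixel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, v, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

_PARTICLE_COLUMNS = ("x", "y", "class_label", "symmetry_label", "micrograph_id")


@dataclass
class ParticleTable:
    """Particle records: position (Å, image origin lower-left), class,
    plane-group symmetry label and source micrograph id.

    Backed by a pandas DataFrame with columns
    ``x, y, class_label, symmetry_label, micrograph_id``.
    """

    frame: "pandas.DataFrame"

    def __post_init__(self):
        import pandas as pd

        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame, columns=list(_PARTICLE_COLUMNS))
        for col in _PARTICLE_COLUMNS:
            if col not in self.frame.columns:
                raise SchemaError(f"particle table missing required column '{col}'")
        bad = set(self.frame["symmetry_label"].astype(str)) - set(SYMMETRY_LABELS)
        if bad:
            raise SchemaError(f"illegal symmetry labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def xy(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @classmethod
    def from_records(cls, records) -> "ParticleTable":
        import pandas as pd

        return cls(pd.DataFrame(list(records), columns=list(_PARTICLE_COLUMNS)))

    @classmethod
    def empty(cls) -> "ParticleTable":
        import pandas as pd

        return cls(pd.DataFrame({c: [] for c in _PARTICLE_COLUMNS}))


def read_particles(path: str | os.PathLike) -> ParticleTable:
    """Read a STAR-like particle table.

    The format is one ``data_`` block containing a ``loop_`` whose header
    lines name the columns (``_x``, ``_y``, ``_class_label``,
    ``_symmetry_label``, ``_micrograph_id``), followed by whitespace-
    delimited rows.
    """
    import pandas as pd

    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                columns = []
                continue
            if line.startswith("_"):
                if not in_loop:
                    raise FormatError(f"line {ln}: column tag outside loop_")
                columns.append(line.split()[0].lstrip("_"))
                continue
            if not columns:
                raise FormatError(f"line {ln}: data row before any loop_ header")
            fields_ = line.split()
            if len(fields_) != len(columns):
                raise FormatError(
                    f"line {ln}: expected {len(columns)} fields, got {len(fields_)}"
                )
            rows.append(fields_)
    if not columns:
        raise FormatError(f"{path}: no loop_ header block found")
    for col in _PARTICLE_COLUMNS:
        if col not in columns:
            raise SchemaError(f"particle table missing required column '{col}'")
    frame = pd.DataFrame(rows, columns=columns)
    for col in ("x", "y"):
        frame[col] = frame[col].astype(float)
    frame["class_label"] = frame["class_label"].astype(str)
    frame["symmetry_label"] = frame["symmetry_label"].astype(str)
    frame["micrograph_id"] = frame["micrograph_id"].astype(str)
    return ParticleTable(frame[list(_PARTICLE_COLUMNS)])


def write_particles(table: ParticleTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("data_particles\n\nloop_\n")
        for i, col in enumerate(_PARTICLE_COLUMNS, start=1):
            fh.write(f"_{col} #{i}\n")
        for rec in table.frame.itertuples(index=False):
            fh.write(
                f"{rec.x:.4f} {rec.y:.4f} {rec.class_label} "
                f"{rec.symmetry_label} {rec.micrograph_id}\n"
            )


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Å
    b: float = 0.0
    occupancy: float = 1.0
    het: bool = False


@dataclass
class Residue:
    seqid: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def atom_coords(
        self,
        atom_names: set[str] | None = None,
        residue_range: tuple[int, int] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        out = []
        for res in self.residues:
            if residue_range and not (residue_range[0] <= res.seqid <= residue_range[1]):
                continue
            for at in res.atoms:
                if atom_names and at.name not in atom_names:
                    continue
                if heavy_only and at.element.upper() == "H":
                    continue
                out.append(at.xyz)
        return np.array(out, dtype=float).reshape(-1, 3)

    def ca_coords(self, residue_range: tuple[int, int] | None = None) -> np.ndarray:
        return self.atom_coords(atom_names={"CA"}, residue_range=residue_range)


@dataclass
class AtomicModel:
    """Chains → residues → atoms with named region annotations.

    ``regions`` maps a region name to an inclusive residue-number range that
    applies to every chain (the lattice subunits are identical in sequence).
    """

    chains: list[Chain] = field(default_factory=list)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for ch in self.chains:
            for res in ch.residues:
                for at in res.atoms:
                    key = (ch.chain_id, res.seqid, res.icode, at.name)
                    if key in seen:
                        raise FormatError(f"duplicate atom key {key}")
                    seen.add(key)
                    if not np.all(np.isfinite(at.xyz)):
                        raise FormatError(f"non-finite coordinates at {key}")

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def all_coords(self, heavy_only: bool = False) -> np.ndarray:
        parts = [c.atom_coords(heavy_only=heavy_only) for c in self.chains]
        parts = [p for p in parts if len(p)]
        return np.vstack(parts) if parts else np.zeros((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_chains = []
        for ch in self.chains:
            residues = []
            for res in ch.residues:
                atoms = [
                    Atom(a.name, a.element, R @ a.xyz + t, a.b, a.occupancy, a.het)
                    for a in res.atoms
                ]
                residues.append(Residue(res.seqid, res.name, res.icode, atoms))
            new_chains.append(Chain(ch.chain_id, residues))
        return AtomicModel(chains=new_chains, regions=dict(self.regions))


#: Flexible-element annotations of the shell protein (residue numbering of
#: the full-length subunit): N-terminal tail, lateral β-hairpin, large loop,
#: structured loop near the closed interface, and C-terminal tail.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "N_tail": (1, 37),
    "beta_hairpin": (111, 126),
    "loop": (272, 291),
    "structured_loop": (245, 258),
    "C_tail": (556, 602),
}


def read_model(path: str | os.PathLike, regions: dict | None = None) -> AtomicModel:
    """Read a PDB or mmCIF atomic model (first model only).

    Insertion codes are preserved and heteroatoms flagged.  Chain iteration
    order follows file order.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse model {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    st.setup_entities()
    chains = []
    for gch in st[0]:
        residues = []
        for gres in gch:
            het = gres.het_flag == "H"
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    b=ga.b_iso,
                    occupancy=ga.occ,
                    het=het,
                )
                for ga in gres
            ]
            icode = gres.seqid.icode.strip()
            residues.append(Residue(gres.seqid.num, gres.name, icode, atoms))
        chains.append(Chain(gch.name, residues))
    return AtomicModel(chains=chains, regions=dict(regions or DEFAULT_REGIONS))
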