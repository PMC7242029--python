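"""Density-map and atomic-model I/O and shared coordinate conventions.

All physical coordinates are in Angstrom in a right-handed frame.
Density lattices are 0-based and indexed ``values[ix, iy, iz]`` in
physical x, y, z order; the physical position of a voxel is
``origin + index * voxel_size`` (voxel-corner convention, matching
MRC2014 practice).  Maps read from disk are normalized to this axis
order regardless of the MAPC/MAPR/MAPS permutation stored in the header.

Hydrogens are ignored everywhere: the channel models this package
targets are cryo-EM structures deposited without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "AtomRecord",
    "StructureModel",
    "ChannelAxis",
    "MapFormatError",
    "StructureFormatError",
    "DegenerateGeometryError",
    "read_density_map",
    "write_density_map",
    "read_structure",
    "assign_vdw_radii",
    "load_vdw_table",
    "default_vdw_table",
    "principal_channel_axis",
    "rotational_symmetry_rmsd",
]


class MapFormatError(ValueError):
    """Raised for malformed or unsupported density-map files."""


class StructureFormatError(ValueError):
    """Raised for unparsable or empty coordinate files."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation receives degenerate input."""


@dataclass(frozen=True)
class DensityMap:
    """A 3D scalar density lattice with physical metadata.

    Parameters
    ----------
    values : ndarray
        Density values, shape ``(nx, ny, nz)``, indexed in physical
        x, y, z order.  Units are arbitrary map units.
    voxel_size : ndarray
        Per-axis voxel spacing in Angstrom, shape ``(3,)``.
    origin : ndarray
        Physical position of lattice index ``(0, 0, 0)`` in Angstrom.
    axis_order : tuple
        Permutation mapping lattice axes to physical x, y, z.  Maps
        held in memory are always normalized to ``(0, 1, 2)``; the
        field records that convention explicitly.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_order: tuple = (0, 1, 2)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float32))
        object.__setattr__(self, "voxel_size", np.asarray(self.voxel_size, dtype=float).reshape(3))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        if self.values.ndim != 3:
            raise MapFormatError(f"density lattice must be 3D, got ndim={self.values.ndim}")
        if np.any(self.voxel_size <= 0):
            raise MapFormatError(f"voxel_size must be positive, got {self.voxel_size}")
        if min(self.values.shape) < 1:
            raise MapFormatError(f"lattice dimensions must be >= 1, got {self.values.shape}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def index_to_position(self, index) -> np.ndarray:
        """Physical position (A) of a (possibly fractional) lattice index."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def position_to_index(self, position) -> np.ndarray:
        """Fractional lattice index of a physical position (A)."""
        return (np.asarray(position, dtype=float) - self.origin) / self.voxel_size

    def with_values(self, values: np.ndarray) -> "DensityMap":
        """A copy of this map carrying new values on the same lattice."""
        return replace(self, values=np.asarray(values, dtype=np.float32))


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position and assigned radii.

    ``vdw_radius`` is NaN until assigned via :func:`assign_vdw_radii`.
    Insertion codes are retained in ``icode`` so that residue identity
    is ``(chain_id, residue_number, icode)``.
    """

    element: str
    atom_name: str
    chain_id: str
    residue_number: int
    residue_name: str
    position: np.ndarray
    vdw_radius: float = float("nan")
    b_factor: float = 0.0
    icode: str = ""

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")


@dataclass
class StructureModel:
    """An ordered collection of atoms forming one coordinate model."""

    atoms: list
    label: str = ""
    _coords: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def chains(self) -> set:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Atom positions as an (N, 3) array (cached; treat model as immutable)."""
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)
        return self._coords

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def select(self, chain=None, res_range=None, atom_name=None) -> "StructureModel":
        """Subset of atoms by chain id, inclusive residue-number range and atom name."""
        out = []
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if res_range is not None and not (res_range[0] <= a.residue_number <= res_range[1]):
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            out.append(a)
        return StructureModel(out, label=self.label)

    def transformed(self, rotation=None, translation=None) -> "StructureModel":
        """A rigidly transformed copy: ``x -> R x + t``."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return StructureModel(atoms, label=self.label)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class ChannelAxis:
    """The channel symmetry axis defining the ion-conduction path.

    ``intracellular_sign`` (+1 or -1) marks which direction along
    ``direction`` points toward the intracellular side; axial (z)
    coordinates reported by the profiling operations are signed so
    that +z is intracellular.
    """

    point: np.ndarray
    direction: np.ndarray
    intracellular_sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise DegenerateGeometryError("axis direction must be a nonzero vector")
        object.__setattr__(self, "direction", d / n)
        if self.intracellular_sign not in (+1, -1):
            raise ValueError("intracellular_sign must be +1 or -1")

    def basis(self) -> np.ndarray:
        """Right-handed orthonormal basis (u, v, w) with w = direction, rows stacked."""
        w = self.direction
        seed = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(seed, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return np.stack([u, v, w])

    def to_axis_frame(self, coords: np.ndarray) -> np.ndarray:
        """Map physical coordinates into the (u, v, z) axis frame.

        z is signed by ``intracellular_sign`` so that +z is intracellular.
        """
        B = self.basis()
        rel = np.atleast_2d(coords) - self.point
        out = rel @ B.T
        out[:, 2] *= self.intracellular_sign
        return out


# ---------------------------------------------------------------------------
# Density-map I/O (MRC2014 / CCP4, via gemmi)

def read_density_map(path) -> DensityMap:
    """Read an MRC2014/CCP4 map, normalizing axis order to physical x, y, z.

    The voxel size is derived from the header cell and sampling; the
    origin is taken from the ORIGIN header words, falling back to
    NXSTART/NYSTART/NZSTART times the voxel size when ORIGIN is zero
    (the CCP4 convention).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot parse {path.name} as MRC/CCP4: {exc}") from exc
    nstart = [m.header_i32(w) for w in (5, 6, 7)]
    origin_words = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    # setup() re-indexes the grid so that axes follow crystallographic
    # x, y, z irrespective of the file's MAPC/MAPR/MAPS permutation.
    m.setup(float("nan"))
    values = np.array(m.grid, copy=True)
    if values.ndim != 3:
        raise MapFormatError(f"{path.name}: expected 3D data, got ndim={values.ndim}")
    voxel = np.array(m.grid.spacing, dtype=float)
    if np.any(voxel <= 0) or not np.all(np.isfinite(voxel)):
        raise MapFormatError(
            f"{path.name}: non-positive voxel size in header cell "
            f"(CELLA={m.grid.unit_cell.parameters[:3]})"
        )
    if np.any(origin_words != 0):
        origin = origin_words
    else:
        origin = np.array(nstart, dtype=float) * voxel
    return DensityMap(values=values, voxel_size=voxel, origin=origin)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode-2 (float32), readable by :func:`read_density_map`."""
    if not np.all(np.isfinite(dmap.values)):
        raise ValueError("map values must be finite for writing")
    nx, ny, nz = dmap.values.shape
    grid = gemmi.FloatGrid(np.asfortranarray(dmap.values, dtype=np.float32))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    cell = gemmi.UnitCell(
        nx * dmap.voxel_size[0], ny * dmap.voxel_size[1], nz * dmap.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    grid.set_unit_cell(cell)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(val))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Structure I/O (PDB / mmCIF, via gemmi)

def read_structure(path, format: str = None) -> StructureModel:
    """Read a coordinate file into a :class:`StructureModel`.

    One :class:`AtomRecord` is produced per atom of the first model.
    Alternate locations other than blank/'A' are dropped; hydrogens
    (and deuterium) are skipped; insertion codes are retained.

    Parameters
    ----------
    format : {'pdb', 'mmcif', None}
        Force a format; ``None`` auto-detects from the file content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[format if format is None else format.lower()]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path.name}: {exc}") from exc
    atoms = []
    if len(st) > 0:
        for chain in st[0]:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("\x00", "", "A"):
                        continue
                    el = atom.element.name.upper()
                    if el in ("H", "D"):
                        continue
                    if el in ("X", ""):
                        raise StructureFormatError(
                            f"{path.name}: unknown element for atom "
                            f"{chain.name}/{residue.seqid.num}/{atom.name}"
                        )
                    atoms.append(
                        AtomRecord(
                            element=el,
                            atom_name=atom.name,
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            residue_name=residue.name,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            b_factor=atom.b_iso,
                            icode=(residue.seqid.icode or "").strip(),
                        )
                    )
    if not atoms:
        raise StructureFormatError(f"{path.name}: no atoms (empty model)")
    return StructureModel(atoms, label=path.stem)


def write_structure(model: StructureModel, path) -> None:
    """Write a model as PDB (used for synthetic fixtures)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chains = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        chain = chains[a.chain_id]
        if (len(chain) == 0 or chain[-1].seqid.num != a.residue_number
                or chain[-1].name != a.residue_name):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.icode or " ")
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.b_iso = a.b_factor
        at.occ = 1.0
        res.add_atom(at)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Van der Waals radii

def load_vdw_table(path) -> dict:
    """Load an element -> radius (A) table from two-column text."""
    table = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed vdW table line: {line!r}")
        table[parts[0].upper()] = float(parts[1])
    return table


def default_vdw_table() -> dict:
    """The Bondi-style radius table bundled with the package."""
    with resources.as_file(resources.files("porelume.data") / "vdw_radii.txt") as p:
        return load_vdw_table(p)


def assign_vdw_radii(model: StructureModel, table: dict = None, default: float = None) -> StructureModel:
    """Return a copy of *model* with van der Waals radii assigned per element.

    Elements missing from *table* fall back to *default*; with no
    default a lookup error naming the element is raised.  The input
    model is not modified.
    """
    if table is None:
        table = default_vdw_table()
    table = {k.upper(): float(v) for k, v in table.items()}
    atoms = []
    for a in model.atoms:
        r = table.get(a.element.upper(), default)
        if r is None:
            raise KeyError(f"no vdW radius for element {a.element!r} and no default configured")
        if r <= 0:
            raise ValueError(f"non-positive vdW radius {r} for element {a.element!r}")
        atoms.append(replace(a, vdw_radius=float(r)))
    return StructureModel(atoms, label=model.label)


# ---------------------------------------------------------------------------
# Channel axis

def principal_channel_axis(
    model: StructureModel,
    symmetry_order: int = None,
    intracellular_sign: int = 1,
) -> ChannelAxis:
    """Locate the rotational pseudo-symmetry axis of a ring-channel model.

    The axis passes through the atom centroid.  Its direction is the
    inertia eigenvector whose eigenvalue is most isolated from the
    other two: for an n-fold symmetric body (n >= 3) the two moments
    perpendicular to the symmetry axis are equal, so the symmetry axis
    carries the distinct eigenvalue.  When *symmetry_order* is given,
    the candidate eigenvectors are instead ranked by self-superposition
    RMSD under a 2*pi/n rotation, which is robust for bodies whose
    moments are nearly degenerate.

    The direction sign is fixed deterministically (largest-magnitude
    component positive); orient it physically by passing the proper
    ``intracellular_sign`` or by flipping the returned axis.
    """
    coords = model.coords
    if len(coords) < 3:
        raise DegenerateGeometryError("need at least 3 atoms to define an axis")
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    cov = rel.T @ rel / len(rel)
    evals, evecs = np.linalg.eigh(cov)
    scale = float(np.max(evals))
    if scale <= 0 or np.sum(evals > 1e-9 * scale) < 2:
        raise DegenerateGeometryError("atom set is collinear; axis undefined")
    if symmetry_order is not None:
        rmsds = [
            rotational_symmetry_rmsd(model, ChannelAxis(centroid, evecs[:, k]), symmetry_order)
            for k in range(3)
        ]
        best = int(np.argmin(rmsds))
    else:
        # isolation = distance to the nearest other eigenvalue
        iso = [min(abs(evals[k] - evals[j]) for j in range(3) if j != k) for k in range(3)]
        best = int(np.argmax(iso))
    direction = evecs[:, best]
    k = int(np.argmax(np.abs(direction)))
    if direction[k] < 0:
        direction = -direction
    return ChannelAxis(point=centroid, direction=direction, intracellular_sign=intracellular_sign)


def rotational_symmetry_rmsd(
    model: StructureModel, axis: ChannelAxis, n: int, max_atoms: int = 4000
) -> float:
    """Nearest-neighbor RMSD of the model onto itself after a 2*pi/n rotation.

    A small value validates *axis* as the n-fold symmetry axis.  Large
    models are subsampled deterministically for speed.
    """
    from scipy.spatial import cKDTree
    from scipy.spatial.transform import Rotation

    coords = model.coords
    if len(coords) > max_atoms:
        step = int(np.ceil(len(coords) / max_atoms))
        coords = coords[::step]
    R = Rotation.from_rotvec(axis.direction * (2 * np.pi / n)).as_matrix()
    rotated = (coords - axis.point) @ R.T + axis.point
    tree = cKDTree(model.coords)
    d, _ = tree.query(rotated, k=1)
    return float(np.sqrt(np.mean(d**2)))
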