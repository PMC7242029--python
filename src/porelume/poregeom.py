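"""HOLE-style pore-radius profiling and assembly geometry.

At each axial station z the pore radius is the radius of the largest
sphere centered in the plane normal to the channel axis that touches
no atom's van der Waals surface:

    R(z) = max_{p in plane(z)}  min_i ( |p - c_i| - r_i )

with atom centers ``c_i`` and vdW radii ``r_i``, clamped below at 0.
Restricting sphere centers to the axis-normal plane (rather than the
Monte-Carlo connectivity walk of the original HOLE) is appropriate for
axially pseudo-symmetric ring channels, whose published profiles plot
radius against position on the symmetry axis.

The in-plane maximization is multi-start: a coarse grid seeds a fine
local grid and a derivative-free polish, all bounded to a disc around
the axis.  The objective is piecewise-smooth (a min of cone functions)
and multi-modal, so single-start local optimization is not reliable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structio import ChannelAxis, StructureModel

__all__ = [
    "PoreStation",
    "PoreProfile",
    "ResidueClassification",
    "CoverageError",
    "compute_pore_profile",
    "min_constriction",
    "entrance_diameters",
    "pore_lining_residues",
    "assembly_dimensions",
    "hydrophobic_membrane_band",
    "load_residue_classes",
    "default_residue_classes",
]


class CoverageError(ValueError):
    """Profile does not span the z-range required by the operation."""


@dataclass(frozen=True)
class PoreStation:
    """One axial station: z (A, +z intracellular), inscribed-sphere radius and center."""

    z: float
    radius: float
    center_xy: tuple
    open_plane: bool = False


@dataclass
class PoreProfile:
    """Ordered pore-radius stations along the channel axis."""

    stations: list
    axis: ChannelAxis
    step: float

    def __post_init__(self):
        zs = self.zs
        if len(zs) > 1 and np.any(np.diff(zs) <= 0):
            raise ValueError("station z-values must be strictly increasing")

    @property
    def zs(self) -> np.ndarray:
        return np.array([s.z for s in self.stations])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.stations])

    @property
    def open_station_zs(self) -> list:
        return [s.z for s in self.stations if s.open_plane]

    def to_tsv(self, path) -> None:
        lines = ["z_A\tradius_A\tcenter_x_A\tcenter_y_A"]
        for s in self.stations:
            lines.append(f"{s.z:.4f}\t{s.radius:.4f}\t{s.center_xy[0]:.4f}\t{s.center_xy[1]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path) -> None:
        payload = {
            "step_A": self.step,
            "stations": [
                {"z_A": s.z, "radius_A": s.radius,
                 "center_x_A": s.center_xy[0], "center_y_A": s.center_xy[1],
                 "open_plane": s.open_plane}
                for s in self.stations
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class ResidueClassification:
    """A pore-lining residue with its 4-class chemical label."""

    chain_id: str
    residue_number: int
    residue_name: str
    res_class: str
    min_distance_to_pore_surface: float
    icode: str = ""
    station_z: float = float("nan")


# ---------------------------------------------------------------------------
# Objective evaluation

class _ClearanceField:
    """min_i (|p - c_i| - r_i) evaluated over batches of in-plane points.

    Atoms are grouped by identical radius so each group can use a 3D
    KD-tree nearest-neighbor query; vdW sets contain only a handful of
    distinct radii, so this stays near O(log N) per point.
    """

    def __init__(self, coords_frame: np.ndarray, radii: np.ndarray):
        if np.any(~np.isfinite(radii)):
            raise ValueError("all atoms need assigned vdW radii (found NaN)")
        self.coords = coords_frame
        self.radii = radii
        uniq = np.unique(radii)
        if len(uniq) <= 32:
            self.groups = [
                (cKDTree(coords_frame[radii == r]), float(r)) for r in uniq
            ]
        else:
            self.groups = None

    def __call__(self, pts_uv: np.ndarray, z: float) -> np.ndarray:
        pts_uv = np.atleast_2d(pts_uv)
        if self.groups is not None:
            q = np.column_stack([pts_uv, np.full(len(pts_uv), z)])
            best = np.full(len(pts_uv), np.inf)
            for tree, r in self.groups:
                d, _ = tree.query(q, k=1)
                np.minimum(best, d - r, out=best)
            return best
        # fallback: direct evaluation in chunks
        best = np.full(len(pts_uv), np.inf)
        dz2 = (self.coords[:, 2] - z) ** 2
        for i in range(0, len(pts_uv), 1024):
            chunk = pts_uv[i:i + 1024]
            d2 = ((chunk[:, None, :] - self.coords[None, :, :2]) ** 2).sum(axis=2) + dz2
            best[i:i + len(chunk)] = np.min(np.sqrt(d2) - self.radii, axis=1)
        return best


def _disc_grid(bound: float, step: float, with_rim: bool = False) -> np.ndarray:
    ax = np.arange(-bound, bound + step / 2, step)
    U, V = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([U.ravel(), V.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= bound]
    if with_rim and bound > 0:
        theta = np.arange(0, 2 * np.pi, step / bound)
        rim = bound * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.vstack([pts, rim])
    return pts


def _clamp_to_disc(p: np.ndarray, bound: float) -> np.ndarray:
    n = np.hypot(p[0], p[1])
    return p if n <= bound else p * (bound / n)


def compute_pore_profile(
    model: StructureModel,
    axis: ChannelAxis,
    z_range: tuple,
    step: float = 1.0,
    search_radius: float = 80.0,
    coarse_step: float = 1.0,
    n_seeds: int = 6,
    connectivity: bool = True,
) -> PoreProfile:
    """Compute the inscribed-sphere radius profile along the channel axis.

    Parameters
    ----------
    z_range : (zmin, zmax)
        Axial interval in A, in axis-frame coordinates (+z intracellular).
    step : float
        Station spacing in A.
    search_radius : float
        Bound (A) of the in-plane disc over which sphere centers are
        searched.  Stations whose optimum escapes to the bound are
        flagged ``open_plane`` rather than failing.
    connectivity : bool
        With connectivity (the default), each station's sphere must
        overlap the previous station's sphere, and the first station's
        sphere is anchored to the axis point.  This keeps the walk
        inside the lumen: at a conical or funnel-shaped mouth the
        unconstrained planar optimum can jump to the open space
        *outside* the channel wall, which is not the conduction path.
        Disable for a pure per-plane global maximization over the disc.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    zmin, zmax = float(z_range[0]), float(z_range[1])
    if not zmax > zmin:
        raise ValueError("z_range must be a non-empty interval")
    if len(model) == 0:
        raise ValueError("model has no atoms")
    frame = axis.to_axis_frame(model.coords)
    radii = model.radii
    fieldf = _ClearanceField(frame, radii)
    inplane_extent = float(np.hypot(frame[:, 0], frame[:, 1]).max())
    bound = min(search_radius, inplane_extent + radii.max())
    coarse = _disc_grid(bound, coarse_step, with_rim=True)
    zs = zmin + step * np.arange(int(np.floor((zmax - zmin) / step + 1e-9)) + 1)

    stations = []
    prev_center = np.zeros(2)
    prev_radius = None
    for z in zs:
        if connectivity:
            anchor_r = prev_radius if prev_radius is not None \
                else max(float(fieldf(prev_center[None, :], z)[0]), step)
            reach = anchor_r + step + 1.0  # overlapping-sphere condition, with slack
        else:
            reach = np.inf
        allowed = coarse if not connectivity else \
            coarse[np.hypot(coarse[:, 0] - prev_center[0], coarse[:, 1] - prev_center[1]) <= reach]
        if len(allowed) == 0:
            allowed = prev_center[None, :]
        vals = fieldf(allowed, z)
        order = np.argsort(vals)[::-1]
        # keep the best seeds, suppressing near-duplicates
        seeds = []
        for idx in order:
            p = allowed[idx]
            if all(np.hypot(*(p - q)) > 1.5 * coarse_step for q in seeds):
                seeds.append(p)
            if len(seeds) >= n_seeds:
                break
        best_p, best_v = None, -np.inf
        for seed in seeds:
            # fine local grid, then simplex polish; out-of-disc points are
            # projected onto the rim so the objective stays continuous and
            # rim maxima remain reachable
            local = np.array([_clamp_to_disc(p, bound) for p in seed + _disc_grid(0.75 * coarse_step, 0.1)])
            lv = fieldf(local, z)
            p0 = local[int(np.argmax(lv))]

            def neg(p):
                p = _clamp_to_disc(np.asarray(p, dtype=float), bound)
                if connectivity and np.hypot(p[0] - prev_center[0], p[1] - prev_center[1]) > reach:
                    return 1e9
                return -float(fieldf(p[None, :], z)[0])

            res = minimize(neg, p0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200})
            if -res.fun > best_v:
                best_v, best_p = -res.fun, _clamp_to_disc(res.x, bound)
        open_plane = np.hypot(*best_p) > bound - 1.5 * coarse_step
        prev_center = np.asarray(best_p, dtype=float)
        prev_radius = max(float(best_v), step)
        stations.append(PoreStation(
            z=float(z),
            radius=float(max(best_v, 0.0)),
            center_xy=(float(best_p[0]), float(best_p[1])),
            open_plane=bool(open_plane),
        ))
    return PoreProfile(stations=stations, axis=axis, step=step)


def min_constriction(profile: PoreProfile) -> PoreStation:
    """The station of minimal radius; ties broken by smallest z."""
    if not profile.stations:
        raise ValueError("empty profile")
    best = profile.stations[0]
    for s in profile.stations[1:]:
        if s.radius < best.radius - 1e-12:
            best = s
    return best


def entrance_diameters(profile: PoreProfile, membrane_bounds: tuple) -> tuple:
    """Pore diameters (A) just outside the membrane span.

    Returns ``(extracellular, intracellular)`` where each value is
    twice the radius at the first station beyond the corresponding
    membrane bound (extracellular = lower z, since +z is intracellular).
    """
    lo, hi = float(membrane_bounds[0]), float(membrane_bounds[1])
    if not hi > lo:
        raise ValueError("membrane_bounds must be a non-empty interval")
    zs = profile.zs
    radii = profile.radii
    below = zs < lo
    above = zs > hi
    if not below.any() or not above.any():
        raise CoverageError(
            f"profile [{zs[0]:.1f}, {zs[-1]:.1f}] does not extend beyond "
            f"membrane bounds ({lo:.1f}, {hi:.1f})"
        )
    extra = 2.0 * radii[below][np.argmax(zs[below])]
    intra = 2.0 * radii[above][np.argmin(zs[above])]
    return float(extra), float(intra)


# ---------------------------------------------------------------------------
# Pore-lining residues

def load_residue_classes(path) -> dict:
    """Residue name -> class table from two-column text; unlisted = hydrophobic."""
    table = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        name, cls = line.split()
        if cls not in ("hydrophobic", "polar", "acidic", "basic"):
            raise ValueError(f"unknown residue class {cls!r}")
        table[name.upper()] = cls
    return table


def default_residue_classes() -> dict:
    with resources.as_file(resources.files("porelume.data") / "residue_classes.txt") as p:
        return load_residue_classes(p)


def classify_residue(residue_name: str, table: dict = None) -> str:
    table = default_residue_classes() if table is None else table
    return table.get(residue_name.upper(), "hydrophobic")


def pore_lining_residues(
    model: StructureModel,
    profile: PoreProfile,
    contact_cutoff: float = 1.5,
    class_table: dict = None,
) -> list:
    """Residues whose vdW surface approaches the pore surface.

    A residue lines the pore when any of its atoms has surface-to-surface
    gap <= *contact_cutoff* to some station sphere.  Each residue is
    labeled by the 4-class table (hydrophobic / polar / acidic / basic)
    and carries its minimal gap and the z of the closest station.
    """
    if class_table is None:
        class_table = default_residue_classes()
    frame = profile.axis.to_axis_frame(model.coords)
    radii = model.radii
    centers = np.array([[s.center_xy[0], s.center_xy[1], s.z] for s in profile.stations])
    sphere_r = profile.radii
    # gap(atom, station) = |c_atom - c_station| - R_station - r_atom
    best = {}
    for j in range(len(centers)):
        d = np.linalg.norm(frame - centers[j], axis=1) - sphere_r[j] - radii
        for i in np.nonzero(d <= contact_cutoff)[0]:
            a = model.atoms[i]
            key = (a.chain_id, a.residue_number, a.icode)
            if key not in best or d[i] < best[key][1]:
                best[key] = (a.residue_name, float(d[i]), float(centers[j][2]))
    out = []
    for (chain, resnum, icode), (resname, gap, z) in sorted(best.items()):
        out.append(ResidueClassification(
            chain_id=chain, residue_number=resnum, icode=icode,
            residue_name=resname,
            res_class=classify_residue(resname, class_table),
            min_distance_to_pore_surface=gap,
            station_z=z,
        ))
    return out


def hydrophobic_membrane_band(lining: list, band_width: float = 30.0) -> tuple:
    """Estimate the membrane span as the z-band of maximal hydrophobic lining density.

    Slides a window of *band_width* A over the station-z values of the
    hydrophobic lining residues and returns the (z_lo, z_hi) window
    containing the most of them (earliest such window on ties).
    """
    zs = np.sort([r.station_z for r in lining if r.res_class == "hydrophobic"])
    if len(zs) == 0:
        raise ValueError("no hydrophobic lining residues to locate the membrane")
    best_lo, best_count = zs[0], -1
    for z0 in zs:
        count = int(np.sum((zs >= z0) & (zs <= z0 + band_width)))
        if count > best_count:
            best_lo, best_count = z0, count
    return float(best_lo), float(best_lo + band_width)


def assembly_dimensions(model: StructureModel, axis: ChannelAxis, include_vdw: bool = False) -> tuple:
    """Channel height and maximal in-plane diameter (A).

    Height is the extent of atom positions projected on the axis;
    the diameter is twice the maximal radial atom distance from the
    axis.  With ``include_vdw=True`` both are measured on the vdW
    envelope instead of atom centers, which is the natural choice for
    quoting a protein's outer dimensions.
    """
    frame = axis.to_axis_frame(model.coords)
    radial = np.hypot(frame[:, 0], frame[:, 1])
    zs = frame[:, 2]
    if include_vdw:
        r = model.radii
        if np.any(~np.isfinite(r)):
            raise ValueError("include_vdw=True requires assigned radii")
        height = float((zs + r).max() - (zs - r).min())
        diameter = float(2.0 * (radial + r).max())
    else:
        height = float(zs.max() - zs.min())
        diameter = float(2.0 * radial.max())
    return height, diameter
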