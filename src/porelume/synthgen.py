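"""Synthetic fixtures with analytically known ground truth.

Every downstream analysis is testable without external data through
three generators:

* :func:`make_ring_channel` — pseudo-atom ring channels with exact
  n-fold symmetry and a *prescribed* inscribed-sphere radius profile.
  The wall is a surface of revolution built from the piecewise-linear
  lumen profile r(z): atom rings are placed at radius
  ``(r + vdw) / sqrt(1 - s^2)`` for local profile slope ``s`` (the
  offset that makes the perpendicular distance from an on-axis point
  to the wall equal ``r + vdw``), so the maximal inscribed sphere at a
  station on a plateau or on a linear cone segment has exactly the
  specified radius.  Slopes must stay below 1: an inscribed-sphere
  profile is 1-Lipschitz by construction, so steeper prescriptions are
  geometrically unrealizable.

* :func:`make_toy_bilayer` — two headgroup pseudo-atom sheets with a
  controlled headgroup-to-headgroup separation plus a sparser tail
  region, emulating the bilayer-like density observed inside wide
  channel lumens.

* :func:`make_conformer_pair` — a subunit-like helix bundle and a copy
  with one helix rotated by a known angle about a hinge, emulating the
  helix reorientation that converts a cylindrical pore into a conical
  one.

All generators are deterministic given their seed, and
:func:`make_fixture_suite` writes a canonical fixture set with a JSON
manifest carrying every ground-truth parameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import mapsim
from .structio import (
    AtomRecord,
    ChannelAxis,
    DensityMap,
    StructureModel,
    write_density_map,
    write_structure,
)

__all__ = [
    "ChannelSpec",
    "BilayerSpec",
    "make_ring_channel",
    "make_toy_bilayer",
    "make_conformer_pair",
    "make_ideal_helix",
    "make_channel_assembly",
    "make_fixture_suite",
    "CHAIN_IDS",
]

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class ChannelSpec:
    """Geometry of a synthetic ring channel.

    ``lumen_knots`` is a sequence of (z, radius) pairs (A) defining a
    piecewise-linear inscribed-sphere radius profile; +z is the
    intracellular direction.  A constant profile gives a cylindrical
    lumen, a single sloped segment a conical one.
    """

    n_subunits: int = 10
    lumen_knots: tuple = ((-45.0, 18.0), (45.0, 18.0))
    wall_atoms_per_ring: int = 40
    vdw: float = 2.0
    ring_spacing: float = 0.75
    overhang: float = 8.0
    seed: int = 0
    element: str = "C"
    residue_name: str = "LEU"

    def __post_init__(self):
        if self.n_subunits < 3:
            raise ValueError("n_subunits must be >= 3")
        knots = tuple((float(z), float(r)) for z, r in self.lumen_knots)
        if len(knots) < 2 or any(knots[i + 1][0] <= knots[i][0] for i in range(len(knots) - 1)):
            raise ValueError("lumen_knots must have strictly increasing z")
        if any(r <= 0 for _, r in knots):
            raise ValueError("lumen radii must be positive")
        for (z0, r0), (z1, r1) in zip(knots, knots[1:]):
            s = abs((r1 - r0) / (z1 - z0))
            if s >= 0.95:
                raise ValueError(
                    f"lumen profile slope {s:.2f} between z={z0} and z={z1} is too steep; "
                    "inscribed-sphere profiles are 1-Lipschitz"
                )
        object.__setattr__(self, "lumen_knots", knots)

    @property
    def height(self) -> float:
        return self.lumen_knots[-1][0] - self.lumen_knots[0][0]

    def lumen_radius(self, z) -> np.ndarray:
        zs = [k[0] for k in self.lumen_knots]
        rs = [k[1] for k in self.lumen_knots]
        return np.interp(z, zs, rs)


@dataclass(frozen=True)
class BilayerSpec:
    """A toy lumenal bilayer: two headgroup sheets plus a sparse tail slab.

    Headgroup sheets sit at z = +-separation/2.  In-plane placement is
    Poisson-disc (minimum spacing 4 A for headgroups, 3 A for tails);
    positions receive isotropic Gaussian jitter of ``jitter_sd``.
    Densities are in atoms/A^2 (sheets) and atoms/A^3 (tails) and must
    stay below the packing limit of the disc spacing.
    """

    headgroup_separation: float = 38.0
    sheet_extent: float = 30.0
    headgroup_atom_density: float = 0.12
    tail_atom_density: float = 0.02
    jitter_sd: float = 0.8
    seed: int = 0
    headgroup_spacing: float = 2.2
    tail_spacing: float = 2.0

    def __post_init__(self):
        if self.headgroup_separation <= 0:
            raise ValueError("headgroup_separation must be positive")
        if self.headgroup_atom_density < 0 or self.tail_atom_density < 0:
            raise ValueError("densities must be >= 0")


# ---------------------------------------------------------------------------
# Ring channels

def _segments_with_overhang(spec: ChannelSpec):
    """Lumen segments plus linear extrapolation by ``overhang`` at both ends."""
    knots = list(spec.lumen_knots)
    if spec.overhang > 0:
        (z0, r0), (z1, r1) = knots[0], knots[1]
        s = (r1 - r0) / (z1 - z0)
        knots.insert(0, (z0 - spec.overhang, r0 - s * spec.overhang))
        (z0, r0), (z1, r1) = knots[-2], knots[-1]
        s = (r1 - r0) / (z1 - z0)
        knots.append((z1 + spec.overhang, r1 + s * spec.overhang))
    return list(zip(knots, knots[1:]))


def make_ring_channel(spec: ChannelSpec) -> StructureModel:
    """Build the pseudo-atom wall of a ring channel.

    Atoms are arranged in rings with exact ``n_subunits``-fold symmetry
    about the z axis (the per-ring atom count is rounded up to a
    multiple of n).  Chains partition the wall into n angular sectors,
    one per subunit.  The construction guarantees that the
    inscribed-sphere radius at any station on a plateau or linear
    segment of the lumen profile equals ``spec.lumen_radius(z)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subunits
    m = int(np.ceil(spec.wall_atoms_per_ring / n)) * n
    sector = 2 * np.pi / n
    atoms = []
    res_counters = {}
    prev_end = None
    for (z0, r0), (z1, r1) in _segments_with_overhang(spec):
        s = (r1 - r0) / (z1 - z0)
        k = 1.0 / np.sqrt(1.0 - s * s)
        dz = spec.ring_spacing / k
        n_rings = max(1, int(np.ceil((z1 - z0) / dz)))
        ring_zs = np.linspace(z0, z1, n_rings + 1)
        if prev_end is not None and abs(ring_zs[0] - prev_end) < 1e-9:
            ring_zs = ring_zs[1:]  # avoid a duplicate ring at shared knots
        prev_end = z1
        for zr in ring_zs:
            r_lumen = r0 + s * (zr - z0)
            if r_lumen <= 0:
                continue
            rho = (r_lumen + spec.vdw) * k
            offset = rng.uniform(0, 2 * np.pi / m)
            angles = offset + 2 * np.pi * np.arange(m) / m
            for ang in angles:
                chain = CHAIN_IDS[int(ang % (2 * np.pi) // sector) % n]
                res_counters[chain] = res_counters.get(chain, 0) + 1
                atoms.append(AtomRecord(
                    element=spec.element,
                    atom_name=spec.element,
                    chain_id=chain,
                    residue_number=res_counters[chain],
                    residue_name=spec.residue_name,
                    position=np.array([rho * np.cos(ang), rho * np.sin(ang), zr]),
                    vdw_radius=spec.vdw,
                ))
    return StructureModel(atoms, label=f"ring{n}")


def channel_axis_of(spec_or_sign=1) -> ChannelAxis:
    """The construction axis of synthetic channels: +z, intracellular toward +z."""
    sign = spec_or_sign if isinstance(spec_or_sign, int) else 1
    return ChannelAxis(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                       intracellular_sign=sign)


# ---------------------------------------------------------------------------
# Bilayer

def _poisson_disc(rng, lo, hi, spacing, target):
    """Dart-throwing Poisson-disc sampling in the box [lo, hi] (any dimension)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    dim = len(lo)
    pts = np.empty((target, dim))
    n = 0
    max_attempts = 300 * max(target, 1)
    for _ in range(max_attempts):
        if n >= target:
            break
        p = rng.uniform(lo, hi)
        if n == 0 or np.min(np.einsum("ij,ij->i", pts[:n] - p, pts[:n] - p)) >= spacing**2:
            pts[n] = p
            n += 1
    return pts[:n]


def make_toy_bilayer(spec: BilayerSpec, center_z: float = 0.0) -> list:
    """Generate bilayer pseudo-atoms: two headgroup sheets and a tail slab.

    Headgroup atoms (element P) sit at ``center_z -+ separation/2``;
    tail atoms (element C) fill the region between the sheets at lower
    density.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    half = spec.headgroup_separation / 2.0
    n_head = int(round(spec.headgroup_atom_density * spec.sheet_extent**2))
    atoms = []
    resnum = 0
    e2 = spec.sheet_extent / 2
    for sheet_z in (center_z - half, center_z + half):
        xy = _poisson_disc(rng, (-e2, -e2), (e2, e2), spec.headgroup_spacing, n_head)
        for p in xy:
            resnum += 1
            pos = np.array([p[0], p[1], sheet_z]) + rng.normal(0, spec.jitter_sd, 3) \
                if spec.jitter_sd > 0 else np.array([p[0], p[1], sheet_z])
            atoms.append(AtomRecord(
                element="P", atom_name="P", chain_id="L",
                residue_number=resnum, residue_name="HGR",
                position=pos, vdw_radius=1.8,
            ))
    margin = 4.0
    z_lo, z_hi = center_z - half + margin, center_z + half - margin
    if z_hi > z_lo and spec.tail_atom_density > 0:
        n_tail = int(round(spec.tail_atom_density * spec.sheet_extent**2 * (z_hi - z_lo)))
        for p in _poisson_disc(rng, (-e2, -e2, z_lo), (e2, e2, z_hi), spec.tail_spacing, n_tail):
            resnum += 1
            pos = p + rng.normal(0, spec.jitter_sd, 3) if spec.jitter_sd > 0 else p
            atoms.append(AtomRecord(
                element="C", atom_name="C", chain_id="L",
                residue_number=resnum, residue_name="TAL",
                position=pos, vdw_radius=1.7,
            ))
    return atoms


# ---------------------------------------------------------------------------
# Helices and conformer pairs

def make_ideal_helix(
    n_res: int,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    chain: str = "A",
    start_res: int = 1,
    residue_name: str = "ALA",
    helix_radius: float = 2.3,
    rise: float = 1.5,
    twist_deg: float = 100.0,
) -> StructureModel:
    """An ideal C-alpha-only alpha-helix along an arbitrary direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(seed, d); u /= np.linalg.norm(u)
    v = np.cross(d, u)
    atoms = []
    for i in range(n_res):
        ang = np.radians(twist_deg) * i
        pos = (np.asarray(origin, dtype=float)
               + d * rise * i
               + helix_radius * (np.cos(ang) * u + np.sin(ang) * v))
        atoms.append(AtomRecord(
            element="C", atom_name="CA", chain_id=chain,
            residue_number=start_res + i, residue_name=residue_name,
            position=pos, vdw_radius=1.7,
        ))
    return StructureModel(atoms, label="helix")


def _merge(models) -> StructureModel:
    atoms = []
    for m in models:
        atoms.extend(m.atoms)
    return StructureModel(atoms)


def make_conformer_pair(
    rotation_deg: float,
    mobile_len: int = 26,
    hinge=None,
    apply_global_motion: bool = True,
    seed: int = 0,
) -> tuple:
    """A subunit-like bundle and a conformer with one helix swung by a known angle.

    The base model holds three parallel core helices, one tilted
    peripheral helix (70 deg from the bundle axis, mimicking the
    intracellular C-terminal helix) and one mobile helix.  The second
    conformer is identical except that the mobile helix is rotated by
    *rotation_deg* about an in-plane axis through *hinge* (default:
    the helix's first C-alpha), tipping it toward the bundle axis;
    optionally the whole second model additionally receives a random
    rigid-body motion, so that meaningful comparison requires a core
    superposition first.

    Returns ``(reference, conformer, info)`` where *info* lists the
    chain/residue ranges of the core, the mobile helix and the tilted
    helix, and the applied angle.
    """
    if not 0 <= rotation_deg < 180:
        raise ValueError("rotation_deg must be in [0, 180)")
    core = [
        make_ideal_helix(30, origin=(12.0, 0.0, 0.0), chain="A", start_res=101),
        make_ideal_helix(30, origin=(-6.0, 10.0, 0.0), chain="A", start_res=201),
        make_ideal_helix(30, origin=(-6.0, -10.0, 0.0), chain="A", start_res=301),
    ]
    tilt = np.radians(70.0)
    cth = make_ideal_helix(
        20, origin=(16.0, 8.0, -10.0),
        direction=(np.sin(tilt), 0.0, np.cos(tilt)),
        chain="A", start_res=401,
    )
    mobile = make_ideal_helix(mobile_len, origin=(5.0, 0.0, 0.0), chain="A", start_res=1)
    ref = _merge(core + [cth, mobile])

    hinge = np.asarray(hinge, dtype=float) if hinge is not None else mobile.atoms[0].position
    R = Rotation.from_rotvec(np.array([0.0, 1.0, 0.0]) * np.radians(rotation_deg)).as_matrix()
    moved = mobile.transformed(rotation=R, translation=hinge - R @ hinge)
    conf = _merge(core + [cth, moved])
    if apply_global_motion:
        rng = np.random.default_rng(seed)
        Rg = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        tg = rng.uniform(-20, 20, 3)
        conf = conf.transformed(rotation=Rg, translation=tg)
    info = {
        "rotation_deg": float(rotation_deg),
        "core_ranges": [("A", 101, 130), ("A", 201, 230), ("A", 301, 330), ("A", 401, 420)],
        "mobile_range": ("A", 1, mobile_len),
        "cth_range": ("A", 401, 420),
        "cth_tilt_from_axis_deg": 70.0,
        "hinge": [float(x) for x in hinge],
    }
    return ref, conf, info


# ---------------------------------------------------------------------------
# Channel assemblies emulating the two conformational states

def make_channel_assembly(kind: str = "cylindrical", n_subunits: int = 10, seed: int = 0) -> dict:
    """A full synthetic channel emulating a cylindrical or conical pore state.

    Geometry (decamer): 90 A total height (z in [-45, 45], +z
    intracellular), a 30 A membrane band (z in [-15, 15]), lumen
    entrances of radius 26 A at both mouths, a 10 A constriction
    plateau just inside the intracellular membrane boundary, an outer
    wall giving a 110 A vdW envelope, and a 30 A-high intracellular
    ring emulating the C-terminal-helix ring.  The undecamer scales the
    lumen (entrance 30 A, constriction 15 A) and the envelope (120 A).
    The conical variant replaces the cylindrical lumen by a funnel
    narrowing toward the intracellular side with no re-widening.

    Returns a dict with the component models ('lumen_wall',
    'outer_wall', 'cth_ring'), the merged 'full' model, the
    construction 'axis' and a 'params' dict of ground-truth values.
    """
    if kind not in ("cylindrical", "conical"):
        raise ValueError(f"unknown channel kind {kind!r}")
    if n_subunits == 10:
        entrance_r, constr_r, outer_d = 26.0, 10.0, 110.0
        mid_r = 21.0
    elif n_subunits == 11:
        entrance_r, constr_r, outer_d = 30.0, 15.0, 120.0
        mid_r = 24.0
    else:
        raise ValueError("assemblies are defined for 10 or 11 subunits")
    if kind == "cylindrical":
        knots = (
            (-45.0, entrance_r), (-38.0, entrance_r), (-26.0, mid_r), (-2.0, mid_r),
            (14.0, constr_r), (18.0, constr_r), (38.0, entrance_r), (45.0, entrance_r),
        )
    else:
        knots = (
            (-45.0, entrance_r), (-15.0, entrance_r),
            (15.0, constr_r - 2.0), (45.0, constr_r - 2.0),
        )
    # mouths sit on plateau segments, so no overhang is needed for
    # profile exactness and the wall spans exactly the nominal height
    lumen = make_ring_channel(ChannelSpec(
        n_subunits=n_subunits, lumen_knots=knots, seed=seed,
        residue_name="LEU", overhang=0.0,
    ))
    vdw = 2.0
    outer_wall = make_ring_channel(ChannelSpec(
        n_subunits=n_subunits,
        lumen_knots=((-45.0, outer_d / 2 - 2 * vdw), (45.0, outer_d / 2 - 2 * vdw)),
        seed=seed + 1, overhang=0.0, ring_spacing=1.5, residue_name="SER",
    ))
    cth_ring = make_ring_channel(ChannelSpec(
        n_subunits=n_subunits,
        lumen_knots=((15.0, 41.0), (45.0, 41.0)),
        seed=seed + 2, overhang=0.0, ring_spacing=1.5, residue_name="GLU",
    ))
    full = _merge([lumen, outer_wall, cth_ring])
    params = {
        "kind": kind,
        "n_subunits": n_subunits,
        "lumen_knots": [list(k) for k in knots],
        "entrance_radius_A": entrance_r,
        "constriction_radius_A": constr_r if kind == "cylindrical" else constr_r - 2.0,
        "constriction_z_A": [14.0, 18.0] if kind == "cylindrical" else [15.0, 45.0],
        "height_A": 90.0,
        "outer_diameter_A": outer_d,
        "cth_ring_height_A": 30.0,
        "membrane_band_A": [-15.0, 15.0],
        "mouth_z_A": [-45.0, 45.0],
        "vdw_A": vdw,
    }
    return {
        "lumen_wall": lumen,
        "outer_wall": outer_wall,
        "cth_ring": cth_ring,
        "full": full,
        "axis": channel_axis_of(),
        "params": params,
    }


# ---------------------------------------------------------------------------
# Canonical fixture suite

def _fixture_frame() -> DensityMap:
    """Common 96^3 lattice at 1.34 A pixel, centered on the construction axis."""
    n = 96
    pixel = 1.34
    origin = np.full(3, -n * pixel / 2)
    return DensityMap(np.zeros((n, n, n), dtype=np.float32),
                      np.full(3, pixel), origin)


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the canonical fixture set and return its manifest.

    Contents: a cylindrical channel with a lumenal bilayer rendered to
    a map (bimodal lumen profile); a conical channel whose lumenal
    density lost the outer-leaflet sheet and whose inner-leaflet sheet
    is shifted intracellularly; conformer pairs at 30 and 60 degrees;
    and ``manifest.json`` with every ground-truth parameter.  Two runs
    with the same seed produce identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # electron-count amplitudes give headgroup pseudo-atoms (P) the
    # density contrast over tails (C) that real headgroups have
    render = mapsim.RenderSpec(resolution=6.0, pixel=1.34, amplitude_mode="electron-count")
    frame = _fixture_frame()
    manifest = {"seed": int(seed),
                "render": {"resolution_A": 6.0, "pixel_A": 1.34,
                           "amplitude_mode": "electron-count"},
                "frame": {"n": 96, "origin_A": list(frame.origin)}}

    # -- cylindrical channel + lumenal bilayer
    cyl = make_channel_assembly("cylindrical", 10, seed=seed)
    sep = 38.0
    bilayer = make_toy_bilayer(BilayerSpec(headgroup_separation=sep, seed=seed + 10))
    write_structure(cyl["full"], out / "cylindrical_channel.pdb")
    cyl_map = mapsim.simulate_density(cyl["full"].atoms + bilayer, spec=render, frame=frame)
    write_density_map(cyl_map, out / "cylindrical_map.mrc")
    manifest["cylindrical"] = {
        "channel": cyl["params"],
        "model_file": "cylindrical_channel.pdb",
        "map_file": "cylindrical_map.mrc",
        "bilayer": {"headgroup_separation_A": sep,
                    "sheet_z_A": [-sep / 2, sep / 2]},
    }

    # -- conical channel + redistributed lumenal density:
    #    outer (extracellular, -z) sheet removed, inner sheet shifted intracellularly
    con = make_channel_assembly("conical", 10, seed=seed + 1)
    shift = 8.0
    inner = [a for a in make_toy_bilayer(BilayerSpec(headgroup_separation=sep, seed=seed + 11))
             if a.position[2] > 0 or a.residue_name == "TAL"]
    inner_shifted = [AtomRecord(
        element=a.element, atom_name=a.atom_name, chain_id=a.chain_id,
        residue_number=a.residue_number, residue_name=a.residue_name,
        position=a.position + np.array([0.0, 0.0, shift]),
        vdw_radius=a.vdw_radius,
    ) for a in inner]
    write_structure(con["full"], out / "conical_channel.pdb")
    con_map = mapsim.simulate_density(con["full"].atoms + inner_shifted, spec=render, frame=frame)
    write_density_map(con_map, out / "conical_map.mrc")
    manifest["conical"] = {
        "channel": con["params"],
        "model_file": "conical_channel.pdb",
        "map_file": "conical_map.mrc",
        "inner_sheet_z_A": sep / 2 + shift,
        "inner_sheet_shift_A": shift,
        "outer_sheet_removed": True,
    }

    # -- conformer pairs
    manifest["conformers"] = []
    for ang in (30.0, 60.0):
        ref, conf, info = make_conformer_pair(ang, seed=seed + int(ang))
        rf = f"conformer_ref_{int(ang)}.pdb"
        cf = f"conformer_rot_{int(ang)}.pdb"
        write_structure(ref, out / rf)
        write_structure(conf, out / cf)
        manifest["conformers"].append({
            "reference_file": rf, "conformer_file": cf, **info,
        })

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
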