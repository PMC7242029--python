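"""Quantitative comparison of channel conformations.

The cylindrical-to-conical transition of large ring channels is driven
by rigid-body-like reorientations of individual helices: after
superposing the conformationally stable core of two subunits, the
angle between the axes of corresponding helices measures the motion
(e.g. the pore-lining first transmembrane helix swinging toward the
pore axis, or the intracellular half of the third helix tilting away
from it).  A helix axis is the dominant principal direction of its
C-alpha positions, oriented N-terminus to C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import ChannelAxis, DegenerateGeometryError, StructureModel

__all__ = [
    "SuperpositionResult",
    "HelixGeometry",
    "MembraneTilt",
    "superpose",
    "helix_axis",
    "interhelix_angle",
    "tilt_to_membrane_plane",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be a proper rotation (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "SuperpositionResult":
        return SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)


@dataclass(frozen=True)
class HelixGeometry:
    """A helix axis: unit direction oriented N->C, plus the C-alpha centroid."""

    chain_id: str
    res_range: tuple
    axis_direction: np.ndarray
    centroid: np.ndarray
    n_calpha: int

    def __post_init__(self):
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        object.__setattr__(self, "axis_direction", d / np.linalg.norm(d))
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float).reshape(3))


def _calpha_coords(model: StructureModel, chain: str, res_range: tuple) -> np.ndarray:
    sel = model.select(chain=chain, res_range=res_range, atom_name="CA")
    # keep residue order as encountered (models are stored in residue order)
    return sel.coords


def superpose(reference: StructureModel, mobile: StructureModel, selection) -> SuperpositionResult:
    """Optimal rigid superposition of paired C-alpha selections (Kabsch).

    *selection* is a sequence of range pairs
    ``((ref_chain, ref_lo, ref_hi), (mob_chain, mob_lo, mob_hi))``;
    each pair must contribute the same number of C-alpha atoms, matched
    in residue order.  Returns the proper rotation and translation
    minimizing the C-alpha RMSD, and the minimized RMSD itself.
    """
    ref_pts, mob_pts = [], []
    for (rc, rlo, rhi), (mc, mlo, mhi) in selection:
        a = _calpha_coords(reference, rc, (rlo, rhi))
        b = _calpha_coords(mobile, mc, (mlo, mhi))
        if len(a) != len(b):
            raise ValueError(
                f"range pairing mismatch: {rc}:{rlo}-{rhi} has {len(a)} CA, "
                f"{mc}:{mlo}-{mhi} has {len(b)}"
            )
        ref_pts.append(a)
        mob_pts.append(b)
    P = np.concatenate(ref_pts)
    Q = np.concatenate(mob_pts)
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 paired C-alpha positions")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("paired positions are collinear")
    rot, rssd = Rotation.align_vectors(P0, Q0)
    R = rot.as_matrix()
    t = Pc - R @ Qc
    rmsd = float(rssd / np.sqrt(len(P)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_matched=len(P))


def helix_axis(model: StructureModel, chain: str, res_range: tuple) -> HelixGeometry:
    """Helix axis as the dominant principal direction of the C-alpha set.

    The sign is fixed so the axis points from the N-terminal toward the
    C-terminal end of the range.
    """
    ca = _calpha_coords(model, chain, res_range)
    if len(ca) < 4:
        raise ValueError(
            f"need >= 4 C-alpha atoms in {chain}:{res_range[0]}-{res_range[1]}, got {len(ca)}"
        )
    centroid = ca.mean(axis=0)
    rel = ca - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return HelixGeometry(
        chain_id=chain, res_range=(int(res_range[0]), int(res_range[1])),
        axis_direction=direction, centroid=centroid, n_calpha=len(ca),
    )


def interhelix_angle(
    a: HelixGeometry,
    b: HelixGeometry,
    frame: SuperpositionResult = None,
    oriented: bool = False,
) -> float:
    """Angle (degrees) between two helix axes, *b* mapped through *frame*.

    Unsigned acute angle in [0, 90] by default; with ``oriented=True``
    the N->C orientation is respected and the angle lies in [0, 180].
    """
    db = b.axis_direction if frame is None else frame.rotation @ b.axis_direction
    c = float(np.dot(a.axis_direction, db))
    if not oriented:
        c = abs(c)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class MembraneTilt:
    """Helix tilt relative to the membrane plane (the plane normal to the channel axis).

    Both complementary readings are carried to avoid 70/20-degree
    ambiguity: ``from_axis_deg`` is the angle between the helix and the
    channel axis (0 = parallel to the axis), ``from_plane_deg`` the
    angle between the helix and the membrane plane (0 = in-plane).
    ``from_axis_deg + from_plane_deg == 90``.
    """

    from_axis_deg: float
    from_plane_deg: float
    convention: str = "tilt measured from the channel axis toward the membrane plane"


def tilt_to_membrane_plane(h: HelixGeometry, axis: ChannelAxis) -> MembraneTilt:
    """Tilt of helix *h* relative to the membrane plane normal to *axis*."""
    c = abs(float(np.dot(h.axis_direction, axis.direction)))
    from_axis = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return MembraneTilt(from_axis_deg=from_axis, from_plane_deg=90.0 - from_axis)
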