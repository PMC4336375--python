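"""Rigid-body water poses and the configuration-space distance metrics.

A water molecule is reduced to a pose: the oxygen position in Å and a
unit quaternion giving the rotation from the laboratory frame to the
molecular body frame.  Distances between poses combine a Euclidean
translational part (Å) with the geodesic distance on the rotation group
(radians); the two are added in quadrature without a unit-weighting
factor, so the bulk number density carries the dimensional bookkeeping
in the entropy formulas that consume these distances.

Body-frame convention: origin at the oxygen, z-axis along the H-O-H
bisector, molecule in the xz-plane with the first hydrogen at positive
x.  Any fixed convention gives identical distances; entropy estimates
are invariant to a global rotation of the laboratory frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaterAtoms",
    "WaterPose",
    "body_frame_quaternion",
    "quaternion_from_matrix",
    "trans_distance",
    "orient_distance",
    "total_distance",
    "pair_distance",
]

_QUAT_NORM_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when O, H1, H2 are collinear and no body frame exists."""


@dataclass(frozen=True)
class WaterAtoms:
    """Raw atomic coordinates of one rigid water, Å."""

    oxygen: np.ndarray
    hydrogen1: np.ndarray
    hydrogen2: np.ndarray

    def __post_init__(self):
        for name in ("oxygen", "hydrogen1", "hydrogen2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)

    def validate(self) -> None:
        """Check O-H bond-length balance and the H-O-H angle.

        The two O-H distances must agree within 20% and the H-O-H angle
        must lie in (60°, 180°); outside that the triplet is not a
        plausible rigid water.
        """
        d1 = np.linalg.norm(self.hydrogen1 - self.oxygen)
        d2 = np.linalg.norm(self.hydrogen2 - self.oxygen)
        if d1 == 0.0 or d2 == 0.0:
            raise DegenerateGeometryError("hydrogen coincides with oxygen")
        if abs(d1 - d2) > 0.2 * max(d1, d2):
            raise ValueError(f"O-H distances differ by >20%: {d1:.3f} vs {d2:.3f} Å")
        cosang = np.dot(self.hydrogen1 - self.oxygen, self.hydrogen2 - self.oxygen) / (d1 * d2)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if not (60.0 < ang < 180.0):
            raise ValueError(f"H-O-H angle {ang:.1f}° outside (60°, 180°)")


@dataclass(frozen=True)
class WaterPose:
    """One water's rigid-body pose in one trajectory frame.

    ``orientation`` is the unit quaternion (w, x, y, z) rotating
    laboratory axes into the body frame, canonicalized to w >= 0.
    """

    position: np.ndarray
    orientation: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if q.shape != (4,):
            raise ValueError("orientation must be a quaternion (w, x, y, z)")
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-9:
            if abs(norm - 1.0) > _QUAT_NORM_TOL:
                raise ValueError(f"quaternion norm {norm} deviates from 1 by more than {_QUAT_NORM_TOL}")
            q = q / norm
        if q[0] < 0:
            q = -q
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", q)


def quaternion_from_matrix(rot: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix.

    Shepperd's method: pick the largest of the four squared components
    from the trace pattern for numerical stability.  The result is
    canonicalized to a nonnegative scalar part.
    """
    m = np.asarray(rot, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array([0.25 * s,
                      (m[2, 1] - m[1, 2]) / s,
                      (m[0, 2] - m[2, 0]) / s,
                      (m[1, 0] - m[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(m[i, i] - m[j, j] - m[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def body_frame_matrix(atoms: WaterAtoms) -> np.ndarray:
    """Rotation matrix whose rows are the body axes in laboratory coordinates."""
    atoms.validate()
    b1 = atoms.hydrogen1 - atoms.oxygen
    b2 = atoms.hydrogen2 - atoms.oxygen
    z = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
    zn = np.linalg.norm(z)
    if zn < 1e-10:
        raise DegenerateGeometryError("H-O-H bisector vanishes (collinear atoms)")
    z /= zn
    x = b1 - np.dot(b1, z) * z  # H1 in-plane component, positive body x
    xn = np.linalg.norm(x)
    if xn < 1e-10:
        raise DegenerateGeometryError("O, H1, H2 are collinear")
    x /= xn
    y = np.cross(z, x)
    return np.array([x, y, z])


def body_frame_quaternion(atoms: WaterAtoms) -> np.ndarray:
    """Unit quaternion rotating the laboratory frame to the water body frame.

    Convention: z along the H-O-H bisector, molecule in the xz-plane,
    H1 at positive x.  Canonical hemisphere (scalar part >= 0).
    """
    return quaternion_from_matrix(body_frame_matrix(atoms))


def pose_from_atoms(atoms: WaterAtoms, frame_index: int = 0) -> WaterPose:
    """Build a :class:`WaterPose` from raw O/H/H coordinates."""
    return WaterPose(position=atoms.oxygen,
                     orientation=body_frame_quaternion(atoms),
                     frame_index=frame_index)


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norm - 1.0) > _QUAT_NORM_TOL):
        raise ValueError("non-unit quaternion")
    return q


def trans_distance(a: WaterPose, b: WaterPose) -> float:
    """Euclidean distance between the two oxygen positions, Å."""
    return float(np.linalg.norm(a.position - b.position))


def orient_distance(qa: np.ndarray, qb: np.ndarray) -> float:
    """Geodesic distance between two orientations: 2·acos(|qa·qb|), radians.

    The absolute value folds the quaternion double cover (q and -q are
    the same rotation); the dot product is clamped to [0, 1] against
    floating-point overshoot.  Molecular C2 symmetry is deliberately not
    folded in: its symmetry number cancels between the sampled and the
    uniform-reference entropies.
    """
    qa = _check_unit(qa)
    qb = _check_unit(qb)
    dot = abs(float(np.dot(qa, qb)))
    # identical rotations stored at float precision give |dot| = 1 ± O(1e-16);
    # snap to 1 inside a 1e-12 band so d(q, -q) is exactly zero (acos is
    # steep near 1, so the band maps only distances below ~3e-6 rad to 0)
    if dot >= 1.0 - 1e-12:
        return 0.0
    return 2.0 * float(np.arccos(dot))


def total_distance(a: WaterPose, b: WaterPose) -> float:
    """Six-dimensional pose distance sqrt(d_trans² + d_orient²).

    Å and radians are combined as raw numbers; the mixed unit is
    absorbed by the bulk density in the entropy expressions.
    """
    dt = trans_distance(a, b)
    do = orient_distance(a.orientation, b.orientation)
    return float(np.sqrt(dt * dt + do * do))


def pair_distance(pairA: tuple, pairB: tuple) -> float:
    """Twelve-dimensional distance between two pose *pairs*.

    Each argument is (pose at site 1, pose at site 2) with a fixed site
    order; the metric combines the per-site total distances in
    quadrature and never swaps sites between frames.
    """
    d1 = total_distance(pairA[0], pairB[0])
    d2 = total_distance(pairA[1], pairB[1])
    return float(np.sqrt(d1 * d1 + d2 * d2))
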