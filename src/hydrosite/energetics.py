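"""Nonbonded interaction energies: solute–water, water–water, ΔE.

Energies are plain Lennard-Jones + Coulomb sums over site pairs,

    U = Σ_ij 4ε_ij[(σ_ij/r)^12 − (σ_ij/r)^6] + 332.0636 q_i q_j / r,

with Lorentz–Berthelot combination rules, optional CHARMM-style
switching of the LJ term between 9.0 and 11.0 Å, and optional
minimum-image wrapping when an orthorhombic box is given.  No Ewald
summation: lattice electrostatics belong to the simulation engine that
produced the trajectory, while the per-site energy decomposition is
defined on direct interaction energies.

The four-site rigid water model is built in: point charges on the two
hydrogens and on a massless M-site displaced from the oxygen along the
H-O-H bisector, LJ on the oxygen only.  The M-site is reconstructed
geometrically from the pose each frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KCAL, E_BULK
from .geometry import WaterPose
from .sites import SiteSeries

__all__ = [
    "NonbondedSite",
    "WaterModel",
    "TIP4P2005",
    "EnergyComponents",
    "pair_energy",
    "water_nonbonded_sites",
    "solute_water_energy",
    "water_water_energy",
    "delta_E_ifst",
]


@dataclass(frozen=True)
class NonbondedSite:
    """One interaction site: position (Å), charge (e), LJ σ (Å) and ε (kcal/mol)."""

    position: np.ndarray
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.lj_epsilon < 0 or self.lj_sigma < 0:
            raise ValueError("LJ parameters must be nonnegative")
        object.__setattr__(self, "position", p)


@dataclass(frozen=True)
class WaterModel:
    """A rigid four-site water parameter set."""

    name: str
    q_hydrogen: float
    q_msite: float
    o_sigma: float
    o_epsilon: float
    r_oh: float
    hoh_angle_deg: float
    r_om: float

    def __post_init__(self):
        net = 2 * self.q_hydrogen + self.q_msite
        if abs(net) > 1e-12:
            raise ValueError(f"water model net charge {net} != 0")


#: TIP4P-2005 rigid water (Abascal & Vega parameterization).
TIP4P2005 = WaterModel(name="TIP4P-2005",
                       q_hydrogen=0.5564, q_msite=-1.1128,
                       o_sigma=3.1589, o_epsilon=0.1852,
                       r_oh=0.9572, hoh_angle_deg=104.52,
                       r_om=0.1546)


@dataclass(frozen=True)
class EnergyComponents:
    """Per-site mean energies, kcal/mol."""

    E_sw: float
    E_ww: float
    dE_ifst: float


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z).

    Inverse of the body-frame quaternion extraction: rows of the result
    are the body axes in laboratory coordinates, so a body-frame vector
    v maps to the laboratory as ``v @ M``.
    """
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def water_nonbonded_sites(pose: WaterPose, model: WaterModel = TIP4P2005) -> list[NonbondedSite]:
    """Rebuild a water's four interaction sites from its rigid-body pose.

    Body frame: z along the H-O-H bisector, hydrogens in the xz-plane
    symmetric about z, M-site on +z between O and the hydrogens.
    """
    half = np.radians(model.hoh_angle_deg / 2.0)
    h1_body = model.r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2_body = model.r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])
    m_body = model.r_om * np.array([0.0, 0.0, 1.0])
    rot = _quat_to_matrix(pose.orientation)  # rows = body axes in lab coords
    o = pose.position
    return [
        NonbondedSite(o, 0.0, model.o_sigma, model.o_epsilon),
        NonbondedSite(o + h1_body @ rot, model.q_hydrogen),
        NonbondedSite(o + h2_body @ rot, model.q_hydrogen),
        NonbondedSite(o + m_body @ rot, model.q_msite),
    ]


def _switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM switching function: 1 below r_on, 0 above r_off, C1 between."""
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    s = ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3
    return np.where(r2 <= on2, 1.0, np.where(r2 >= off2, 0.0, s))


def pair_energy(a: list[NonbondedSite], b: list[NonbondedSite],
                scheme: str = "none",
                box: np.ndarray | None = None,
                r_on: float = 9.0, r_off: float = 11.0) -> float:
    """Interaction energy between two disjoint molecules, kcal/mol.

    ``scheme``: "none" for plain sums, "switched" to switch the LJ term
    smoothly to zero between ``r_on`` and ``r_off`` Å.  ``box`` enables
    minimum-image wrapping (orthorhombic edges, Å).
    """
    if scheme not in ("none", "switched"):
        raise ValueError(f"unknown cutoff scheme {scheme!r}")
    pa = np.array([s.position for s in a])
    pb = np.array([s.position for s in b])
    dv = pa[:, None, :] - pb[None, :, :]
    if box is not None:
        box = np.asarray(box, dtype=float)
        dv -= box * np.round(dv / box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", dv, dv))
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident interaction sites between molecules")
    qa = np.array([s.charge for s in a])
    qb = np.array([s.charge for s in b])
    coul = COULOMB_KCAL * np.outer(qa, qb) / r
    sig = 0.5 * (np.array([s.lj_sigma for s in a])[:, None] +
                 np.array([s.lj_sigma for s in b])[None, :])
    eps = np.sqrt(np.outer([s.lj_epsilon for s in a],
                           [s.lj_epsilon for s in b]))
    with np.errstate(divide="ignore"):
        sr6 = np.where(eps > 0.0, (sig / r) ** 6, 0.0)
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    if scheme == "switched":
        lj = lj * _switch(r, r_on, r_off)
    return float(np.sum(coul) + np.sum(lj))


def solute_water_energy(site: SiteSeries, solute: list[NonbondedSite],
                        model: WaterModel = TIP4P2005,
                        scheme: str = "none",
                        box: np.ndarray | None = None) -> float:
    """Mean solute–water interaction energy E_sw over occupied frames, kcal/mol.

    The solute is fixed across frames (rigid-solute analysis setting).
    """
    if site.n == 0:
        raise ValueError("empty site series")
    total = 0.0
    for pose in site.poses():
        total += pair_energy(water_nonbonded_sites(pose, model), solute,
                             scheme=scheme, box=box)
    return total / site.n


def water_water_energy(site: SiteSeries,
                       other_waters: list[list[WaterPose]],
                       model: WaterModel = TIP4P2005,
                       scheme: str = "none",
                       box: np.ndarray | None = None) -> float:
    """Half the mean interaction energy of the site water with all other waters.

    ``other_waters[f]`` lists the other waters present in the frame with
    index ``site.frame_indices[f]``; the half-share convention matches
    the definition of the bulk reference energy, so summing this
    quantity over all waters recovers the total unique-pair energy.
    Returns 0 for a cavity with no other waters.
    """
    if site.n == 0:
        raise ValueError("empty site series")
    if len(other_waters) != site.n:
        raise ValueError("other_waters must align with the site's occupied frames")
    total = 0.0
    for pose, others in zip(site.poses(), other_waters):
        w = water_nonbonded_sites(pose, model)
        for o in others:
            total += 0.5 * pair_energy(w, water_nonbonded_sites(o, model),
                                       scheme=scheme, box=box)
    return total / site.n


def delta_E_ifst(E_sw: float, E_ww: float, n_waters: int = 1,
                 E_bulk: float = E_BULK) -> float:
    """Hydration energy ΔE = E_sw + E_ww − n·E_bulk, kcal/mol."""
    return E_sw + E_ww - n_waters * E_bulk
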