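"""Hydration sites, per-frame water assignment, and block statistics.

A hydration site is a sphere around a reference position (typically a
crystallographic water oxygen).  Each trajectory frame's waters are
assigned greedily: sites take the closest unassigned water oxygen
within their radius, waters go to at most one site, and ties are broken
by lexicographic site id.  Frames where a site is transiently empty are
simply dropped from that site's series — the entropy estimators count
only occupied frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import WaterPose

__all__ = [
    "HydrationSite",
    "SiteSeries",
    "PairSeries",
    "OccupancyError",
    "assign_waters",
    "build_site_series",
    "build_pair_series",
    "block_partition",
]

#: Pairs of sites farther apart than this (mean centre separation, Å)
#: contribute no water-water correlation term.
DEFAULT_PAIR_GATE = 4.0

#: Default site radius, Å.  Buried waters are confined by the cavity
#: walls, so any radius comfortably above the positional spread works;
#: occupancies below ~0.99 suggest the site definition is too tight.
DEFAULT_SITE_RADIUS = 1.2


class OccupancyError(ValueError):
    """A pair series could not be formed (no co-occupied frames, or a gap)."""


@dataclass(frozen=True)
class HydrationSite:
    """A spherical hydration site centred on a reference water position."""

    site_id: str
    center: np.ndarray
    radius: float = DEFAULT_SITE_RADIUS
    source_label: str = ""

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,):
            raise ValueError("site center must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        object.__setattr__(self, "center", c)


@dataclass
class SiteSeries:
    """The pose time series of the water occupying one hydration site.

    Stored as flat arrays for the estimators: ``positions`` (n, 3),
    ``orientations`` (n, 4) and ``frame_indices`` (n,) cover only the
    occupied frames; ``n_frames_total`` is the trajectory length.
    """

    site: HydrationSite
    positions: np.ndarray
    orientations: np.ndarray
    frame_indices: np.ndarray
    n_frames_total: int

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        n = len(self.positions)
        if self.orientations.shape != (n, 4) or self.frame_indices.shape != (n,):
            raise ValueError("positions, orientations and frame_indices must agree in length")
        if n > self.n_frames_total:
            raise ValueError("more occupied frames than total frames")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def occupancy(self) -> float:
        return self.n / self.n_frames_total if self.n_frames_total else 0.0

    def position_array(self) -> np.ndarray:
        return self.positions

    def orientation_array(self) -> np.ndarray:
        return self.orientations

    def poses(self) -> list[WaterPose]:
        return [WaterPose(p, q, int(f)) for p, q, f in
                zip(self.positions, self.orientations, self.frame_indices)]

    def subset(self, indices: np.ndarray) -> "SiteSeries":
        """A new series restricted to the given occupied-frame indices."""
        indices = np.asarray(indices, dtype=int)
        return SiteSeries(site=self.site,
                          positions=self.positions[indices],
                          orientations=self.orientations[indices],
                          frame_indices=self.frame_indices[indices],
                          n_frames_total=self.n_frames_total)


@dataclass
class PairSeries:
    """Synchronized pose pairs for two co-occupied hydration sites.

    The site order is fixed for the whole series; frame f contributes
    the 12D sample (pose of water 1 in f, pose of water 2 in f).
    """

    site_ids: tuple[str, str]
    positions1: np.ndarray
    orientations1: np.ndarray
    positions2: np.ndarray
    orientations2: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self):
        n = len(self.positions1)
        for a in ("positions1", "positions2"):
            setattr(self, a, np.atleast_2d(np.asarray(getattr(self, a), dtype=float)))
        for a in ("orientations1", "orientations2"):
            setattr(self, a, np.atleast_2d(np.asarray(getattr(self, a), dtype=float)))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        shapes = (self.positions1.shape, self.positions2.shape,
                  self.orientations1.shape, self.orientations2.shape)
        if shapes != ((n, 3), (n, 3), (n, 4), (n, 4)) or self.frame_indices.shape != (n,):
            raise ValueError("pair series arrays must agree in length")

    @property
    def n(self) -> int:
        return len(self.positions1)

    def position_array(self) -> np.ndarray:
        """Stacked (n, 6) translational coordinates of the pair."""
        return np.hstack([self.positions1, self.positions2])

    def orientation_array(self) -> np.ndarray:
        """Stacked (n, 8) quaternion coordinates of the pair."""
        return np.hstack([self.orientations1, self.orientations2])

    def site1(self) -> SiteSeries:
        return SiteSeries(site=HydrationSite(self.site_ids[0], self.positions1.mean(axis=0)),
                          positions=self.positions1, orientations=self.orientations1,
                          frame_indices=self.frame_indices, n_frames_total=self.n)

    def site2(self) -> SiteSeries:
        return SiteSeries(site=HydrationSite(self.site_ids[1], self.positions2.mean(axis=0)),
                          positions=self.positions2, orientations=self.orientations2,
                          frame_indices=self.frame_indices, n_frames_total=self.n)

    def subset(self, indices: np.ndarray) -> "PairSeries":
        indices = np.asarray(indices, dtype=int)
        return PairSeries(site_ids=self.site_ids,
                          positions1=self.positions1[indices],
                          orientations1=self.orientations1[indices],
                          positions2=self.positions2[indices],
                          orientations2=self.orientations2[indices],
                          frame_indices=self.frame_indices[indices])


def assign_waters(frame: list[WaterPose], sites: list[HydrationSite]) -> dict[str, WaterPose]:
    """Greedy nearest assignment of one frame's waters to sites.

    Each site takes the closest unassigned water oxygen within its
    radius; each water joins at most one site.  Site-water candidate
    pairs are processed in order of increasing distance, ties broken by
    lexicographic site id, so the result is independent of input order.
    Unoccupied sites are simply absent from the mapping.
    """
    if not frame or not sites:
        return {}
    centers = np.array([s.center for s in sites])
    waters = np.array([w.position for w in frame])
    dist = np.linalg.norm(centers[:, None, :] - waters[None, :, :], axis=-1)
    cand = [(dist[i, j], sites[i].site_id, i, j)
            for i in range(len(sites)) for j in range(len(frame))
            if dist[i, j] <= sites[i].radius]
    cand.sort(key=lambda t: (t[0], t[1]))
    taken_sites: set[int] = set()
    taken_waters: set[int] = set()
    out: dict[str, WaterPose] = {}
    for _, sid, i, j in cand:
        if i in taken_sites or j in taken_waters:
            continue
        taken_sites.add(i)
        taken_waters.add(j)
        out[sid] = frame[j]
    return out


def build_site_series(frames: list[list[WaterPose]],
                      sites: list[HydrationSite]) -> dict[str, SiteSeries]:
    """Assign every frame and collect one :class:`SiteSeries` per site."""
    acc: dict[str, list[WaterPose]] = {s.site_id: [] for s in sites}
    for f_idx, frame in enumerate(frames):
        assigned = assign_waters(frame, sites)
        for sid, pose in assigned.items():
            acc[sid].append(WaterPose(pose.position, pose.orientation, f_idx))
    out = {}
    for s in sites:
        poses = acc[s.site_id]
        out[s.site_id] = SiteSeries(
            site=s,
            positions=np.array([p.position for p in poses]).reshape(-1, 3),
            orientations=np.array([p.orientation for p in poses]).reshape(-1, 4),
            frame_indices=np.array([p.frame_index for p in poses], dtype=int),
            n_frames_total=len(frames))
    return out


def build_pair_series(a: SiteSeries, b: SiteSeries,
                      max_center_sep: float = DEFAULT_PAIR_GATE) -> PairSeries:
    """Synchronize two site series into a pair series over co-occupied frames.

    The pair is rejected (``OccupancyError``) if the mean centre
    separation exceeds ``max_center_sep`` — distant sites carry no
    water-water correlation term — or if no frame has both sites
    occupied.
    """
    sep = float(np.linalg.norm(a.site.center - b.site.center))
    if sep > max_center_sep:
        raise OccupancyError(
            f"sites {a.site.site_id},{b.site.site_id} are {sep:.2f} Å apart "
            f"(> {max_center_sep} Å pair gate)")
    common, ia, ib = np.intersect1d(a.frame_indices, b.frame_indices,
                                    return_indices=True)
    if len(common) == 0:
        raise OccupancyError(
            f"sites {a.site.site_id},{b.site.site_id} share no co-occupied frames")
    return PairSeries(site_ids=(a.site.site_id, b.site.site_id),
                      positions1=a.positions[ia], orientations1=a.orientations[ia],
                      positions2=b.positions[ib], orientations2=b.orientations[ib],
                      frame_indices=common)


def block_partition(n_frames: int, n_blocks: int, block_size: int,
                    seed: int = 0) -> list[np.ndarray]:
    """Disjoint random blocks of frame indices for block statistics.

    Frames are shuffled reproducibly and cut into ``n_blocks`` blocks of
    ``block_size``; every analysis quantity is recomputed per block to
    yield a between-block mean ± SD.  Disjoint blocks (rather than
    bootstrap resamples) keep the SD a clean independent-replicate
    estimate; a bootstrap variant is available downstream.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    if n_blocks * block_size > n_frames:
        raise ValueError(
            f"{n_blocks} blocks of {block_size} need {n_blocks * block_size} frames; "
            f"only {n_frames} available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_frames)
    return [np.sort(order[i * block_size:(i + 1) * block_size])
            for i in range(n_blocks)]
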