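"""Synthetic pose trajectories with closed-form entropies.

Every generator returns its analytic reference value alongside the
samples, so estimator validation is self-describing:

* ``uniform_box`` — positions uniform in a cubic box of edge L,
  orientations uniform on the rotation group:
  S_sw = R ln(L³ ρ).  The box is treated as periodic (a 3-torus) when
  its samples are evaluated, which leaves the closed form unchanged
  while removing the hard-wall boundary that violates the
  locally-uniform-density assumption of nearest-neighbour estimation.
* ``gaussian_well`` — isotropic Gaussian positions of width σ per axis,
  uniform orientations: S_sw = R[(3/2) ln(2πeσ²) + ln ρ].
* ``harmonic_boltzmann`` — the Boltzmann distribution of a harmonic
  well of force constant k_harm at temperature T, i.e. a Gaussian with
  σ² = RT/k_harm per axis: S_sw = R[(3/2) ln(2πeRT/k_harm) + ln ρ].
* ``correlated_pair`` — two sites whose translational coordinates are
  jointly Gaussian with per-axis correlation r (orientations
  independent uniform): I_ww = −(3/2) R ln(1 − r²).

Orientations are kept uniform (maximum entropy) so they contribute
exactly zero relative entropy and the translational closed forms stay
exact.  All draws are reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_CAL, R_KCAL, RHO_BULK, T_DEFAULT
from .sites import HydrationSite, PairSeries, SiteSeries

__all__ = [
    "SyntheticSpec",
    "SyntheticSite",
    "SyntheticPair",
    "uniform_quaternion",
    "sample_site",
    "sample_correlated_pair",
]

KINDS = ("uniform_box", "gaussian_well", "harmonic_boltzmann", "correlated_pair")

#: Translational spread typical of a buried, hydrogen-bonded cavity
#: water (sub-ångström positional RMSF).
DEFAULT_SIGMA = 0.35

#: Default box edge: the bulk volume per molecule, so S_sw = 0.
DEFAULT_BOX_EDGE = (1.0 / RHO_BULK) ** (1.0 / 3.0)

#: Hydrogen-bonding centre separation for a doubly occupied cavity, Å.
DEFAULT_PAIR_SEPARATION = 2.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic site or pair trajectory."""

    kind: str
    n_frames: int
    seed: int = 0
    box_edge: float = DEFAULT_BOX_EDGE        # uniform_box
    sigma: float = DEFAULT_SIGMA              # gaussian_well / correlated_pair
    k_harm: float = 0.5                       # harmonic_boltzmann, kcal/mol/Å²
    T: float = T_DEFAULT                      # harmonic_boltzmann
    r: float = 0.0                            # correlated_pair, per-axis correlation
    separation: float = DEFAULT_PAIR_SEPARATION
    rho: float = RHO_BULK
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; choose from {KINDS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (-1.0 < self.r < 1.0):
            raise ValueError("correlation r must lie strictly inside (-1, 1)")
        if self.kind == "uniform_box" and self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.kind in ("gaussian_well", "correlated_pair") and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "harmonic_boltzmann" and (self.k_harm <= 0 or self.T <= 0):
            raise ValueError("k_harm and T must be positive")


@dataclass(frozen=True)
class SyntheticSite:
    """A generated site series plus its analytic reference entropy."""

    series: SiteSeries
    analytic_S_sw: float       # cal/mol/K
    spec: SyntheticSpec
    periodic_box: np.ndarray | None = None


@dataclass(frozen=True)
class SyntheticPair:
    """A generated pair series plus its analytic mutual information."""

    pairs: PairSeries
    analytic_I_ww: float       # cal/mol/K
    spec: SyntheticSpec


def uniform_quaternion(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Unit quaternions uniform on the rotation group (Haar measure).

    Normalized 4D Gaussians are uniform on the 3-sphere; folding to the
    w >= 0 hemisphere picks the canonical representative of each
    rotation without disturbing uniformity.
    """
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1.0
    return q


def _gaussian_s_sw(sigma: float, rho: float) -> float:
    return R_CAL * (1.5 * np.log(2.0 * np.pi * np.e * sigma * sigma) + np.log(rho))


def sample_site(spec: SyntheticSpec) -> SyntheticSite:
    """Draw a single-site pose trajectory from the spec's distribution."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    center = np.asarray(spec.center, dtype=float)
    box = None
    if spec.kind == "uniform_box":
        pos = rng.uniform(0.0, spec.box_edge, (n, 3))
        analytic = R_CAL * np.log(spec.box_edge ** 3 * spec.rho)
        box = np.full(3, spec.box_edge)
    elif spec.kind == "gaussian_well":
        pos = center + rng.normal(0.0, spec.sigma, (n, 3))
        analytic = _gaussian_s_sw(spec.sigma, spec.rho)
    elif spec.kind == "harmonic_boltzmann":
        sigma = np.sqrt(R_KCAL * spec.T / spec.k_harm)
        pos = center + rng.normal(0.0, sigma, (n, 3))
        analytic = _gaussian_s_sw(sigma, spec.rho)
    else:
        raise ValueError("use sample_correlated_pair for kind='correlated_pair'")
    series = SiteSeries(site=HydrationSite(f"synthetic-{spec.kind}", center,
                                           radius=max(3.0 * spec.sigma, spec.box_edge)),
                        positions=pos,
                        orientations=uniform_quaternion(rng, n),
                        frame_indices=np.arange(n),
                        n_frames_total=n)
    return SyntheticSite(series=series, analytic_S_sw=float(analytic),
                         spec=spec, periodic_box=box)


def sample_correlated_pair(spec: SyntheticSpec) -> SyntheticPair:
    """Draw a doubly occupied cavity with correlated translations.

    Site-2 positions follow z2 = r·z1 + √(1−r²)·ε so each axis pair is
    bivariate Gaussian with correlation r; orientations are independent
    uniform.  The analytic mutual information is −(3/2) R ln(1 − r²).
    """
    if spec.kind != "correlated_pair":
        raise ValueError("spec.kind must be 'correlated_pair'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    center1 = np.asarray(spec.center, dtype=float)
    center2 = center1 + np.array([spec.separation, 0.0, 0.0])
    z1 = rng.standard_normal((n, 3))
    z2 = spec.r * z1 + np.sqrt(1.0 - spec.r ** 2) * rng.standard_normal((n, 3))
    pairs = PairSeries(site_ids=("synthetic-1", "synthetic-2"),
                       positions1=center1 + spec.sigma * z1,
                       orientations1=uniform_quaternion(rng, n),
                       positions2=center2 + spec.sigma * z2,
                       orientations2=uniform_quaternion(rng, n),
                       frame_indices=np.arange(n))
    analytic = -1.5 * R_CAL * np.log(1.0 - spec.r ** 2)
    return SyntheticPair(pairs=pairs, analytic_I_ww=float(analytic), spec=spec)
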