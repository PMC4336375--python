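# Methods

## Model

A buried water molecule is treated as a rigid body: its configuration is
the oxygen position **r** (Å) and the orientation quaternion **q** (the
lab→body rotation; body frame: z along the H–O–H bisector, molecule in
the xz-plane, first hydrogen at +x). Any fixed body-frame convention
gives identical inter-pose distances, so estimates are invariant to a
global rigid motion of the laboratory frame (asserted by test).

Distances combine translation and rotation in quadrature,

    d_trans = |r₁ − r₂|            (Å)
    d_orient = 2·acos(|q₁·q₂|)     (radians; geodesic on the rotation group)
    d_total² = d_trans² + d_orient²
    d_pair²  = d_total² + d_total′²   (synchronized site pairs, 12D)

Å and radians are added as raw numbers; the bulk number density ρ carries
the dimensional bookkeeping in the entropy expressions. The absolute
value in d_orient folds the quaternion double cover only. Water's C2
molecular symmetry is deliberately *not* folded in: its symmetry number
appears identically in the sampled and uniform-reference entropies and
cancels.

## Entropy estimators

Absolute entropy from kth-nearest-neighbour distances (k = 1 in
production; any k is supported and validated for k ∈ {1, 2, 4}):

    H_abs = (1/n) Σᵢ ln[ n·d_{i,k}^p·π^{p/2} / Γ(p/2+1) ] − L_{k−1} + γ

Relative (thermodynamic) entropies subtract the uniform reference —
positions at bulk density ρ, orientations uniform over the rotation
group, whose volume under this metric is 8π² — giving the 6D single-site
form with constant 48 = 6·8 and the 12D pair form with constant
46080 = 720·64. The reference is ln(8π²/ρ) per water: the per-molecule
reference volume is 1/ρ.

Nearest neighbours are exact. Poses are embedded as (x, y, z, 2q) with
both quaternion signs; a KD-tree supplies candidates under the Euclidean
embedding metric, which bounds the true mixed metric from below within a
factor π/(2√2); candidates are verified against the true metric and the
candidate set expands until the bound certifies the neighbour.
Approximate search is never used — the estimator is distance-sensitive.
Duplicate samples (zero distance) raise by default; an opt-in jitter of
~1e-10 Å breaks exact ties explicitly rather than silently.

An optional periodic box applies minimum-image translational distances.
This matters for validation: a *hard-walled* uniform box violates the
estimator's locally-uniform-density assumption at the boundary (measured
bias ≈ +0.7 cal/mol/K at n = 16000 for a 1 Å box), whereas the same
uniform distribution on a 3-torus has the same closed-form entropy,
S_sw = R ln(L³ρ), and no boundary. The uniform-box generator therefore
declares a periodic box for evaluation.

## Mutual information by permuted fill modes

For a doubly occupied cavity, the excess correlation not captured by the
two single-site terms is estimated by comparing the true synchronized
series against one whose site-2 poses are randomly permuted across
frames (marginals exactly preserved, joint structure destroyed):

    I_ww = (R/n) Σᵢ ln[ d_perm,i¹² / d_pair,i¹² ]  ≥ 0 in expectation

The additive bias terms of the two 12D entropy estimates cancel, which
is the reason this route is preferred over the three-entropy
decomposition I_ww = S*_sw + S*_sw′ − S_sww′ (kept as a diagnostic):
combining nearest-neighbour entropies of different dimensionality leaves
a residual finite-sample offset that does not cancel. Estimates are
averaged over 8 fill permutations by default (seed-controlled; the
count is exposed because averaging only reduces permutation noise).
The cavity term is S_ww = −Σ_pairs (I_ww + S_vol) over pairs whose mean
site-centre separation is within 4.0 Å; S_vol defaults to zero for
cavity pairs (pair-correlated subvolumes are tiny); the bulk value
−0.99 cal/mol/K ships as a named constant for sensitivity analyses.
In per-site ledgers each member of a pair receives half of
−(I_ww + S_vol), so a cavity's summed ledger counts the pair term once.

## Energies

Plain Lennard-Jones + Coulomb site sums with Lorentz–Berthelot
combination, Coulomb constant 332.0636 kcal·Å/mol/e². TIP4P-2005 is
built in (charges on H and the M-site, LJ on oxygen; the massless M-site
is rebuilt geometrically from the pose each frame, 0.1546 Å along the
bisector). Optional CHARMM-style switching of the LJ term between 9.0
and 11.0 Å (C1-continuous, verified numerically) and optional
minimum-image wrapping for orthorhombic boxes. No Ewald summation:
lattice electrostatics belong to the engine that generated the
trajectory; the per-site decomposition is defined on direct interaction
energies. E_ww and E_bulk follow the half-share convention (half the
interaction of one water with all others), so per-water sums conserve
the total pair energy.

## Bulk reference constants

ρ = 0.03324 Å⁻³, E_bulk = −11.5748 kcal/mol, T = 300 K, and the bulk
insertion free energy −6.95 kcal/mol are configuration constants of the
TIP4P-2005 model, not computed here (they require bulk simulations).
Two bulk entropies ship: the conventionally quoted S_bulk =
−15.5097 cal/mol/K, and the value implied by the cycle identity
T·S_bulk = E_bulk − ΔG_insertion, −15.4160 cal/mol/K. They differ by
0.094 cal/mol/K; per-site free-energy ledgers close exactly only with
the cycle-consistent value (T·S_bulk = −4.62 kcal/mol), so
`BulkReference` defaults to it and the quoted constant remains
selectable. This choice is what reproduces the bundled benchmark
ledgers (e.g. −T·S_sw = +7.29 → −T·ΔS = +2.67 → ΔG = −16.03 kcal/mol
for the most strongly bound site).

## Sites, assignment, blocks

Hydration sites are spheres (default radius 1.2 Å) around reference
positions, typically crystallographic water oxygens. Assignment is
globally distance-ordered greedy — candidate (site, water) pairs sorted
by distance, ties by site id — which is stable under input reordering
and equals optimal matching when waters are well separated (tested
against exhaustive matching). Frames where a site is empty are dropped
from that site's series; occupancies below ~0.99 suggest a mis-sized
site for buried waters. Error bars come from disjoint random frame
blocks (e.g. 10 × 2000 from 20000 snapshots), reported as between-block
mean ± SD; disjointness keeps the SD a clean replicate estimate.

## Synthetic generators

The generators emulate localized cavity waters with exactly known
statistics: uniform box (periodic; S_sw = R ln L³ρ), Gaussian well of
width σ (default 0.35 Å, a typical buried-water positional RMSF;
S_sw = R[(3/2)ln(2πeσ²) + ln ρ]), harmonic Boltzmann well
(σ² = RT/k_harm), and correlated pairs (per-axis translational
correlation r at 2.8 Å separation; I_ww = −(3/2)R ln(1−r²)).
Orientations are uniform (Haar; normalized 4D Gaussians), contributing
exactly zero relative entropy so the translational closed forms stay
exact. What the generators do *not* emulate: cavity-wall anisotropy,
orientational ordering by hydrogen bonding, force-field realism, and
temporal autocorrelation — so passing closed-form tests validates the
estimators, not the physics of any particular cavity.

## Numerical behaviour and known limitations

Measured on the bundled generators (20 seeds, errors in cal/mol/K):

* The k = 1 estimator's S_sw error decreases with n for all kinds at
  small-to-moderate n; for the periodic uniform box it reaches
  +0.010 ± 0.006 (SE) at n = 16000, statistically indistinguishable
  from zero.
* For Gaussian-type positions with fully uniform orientations the
  estimator retains an intrinsic finite-sample offset at n = 16000
  (gaussian well σ = 0.35 Å: −0.074; harmonic well σ = 1.09 Å: −0.031),
  decaying only slowly (~n^(−1/3)); at σ = 0.35 Å the |error| median is
  no longer monotone between n = 4000 and 16000 because a decaying
  positive curvature term crosses a slowly decaying negative intrinsic
  term. Practical block sizes (n ≈ 2000) sit where the two nearly
  cancel.
* The permuted-fill I_ww is clean for independent pairs (centred on
  zero within error) and monotone in |r|, but when the translational
  spread is far below the orientational scale (σ ≈ 0.35 Å against a
  fully uniform orientation distribution) the 12D neighbour distances
  are dominated by the orientational coordinates and the translational
  correlation is underestimated (r = 0.8: ≈ −1.8 at n = 4000,
  converging only as ~n^(−1/6)). With commensurate scales (σ ≈ 2 Å)
  the Gaussian closed form is recovered within error — and in real
  cavities both coordinates are concentrated, which is the balanced
  regime.
* The three-entropy decomposition disagrees with the permuted-fill
  route by far more than the combined statistical error
  (≈ 0.8 cal/mol/K at n = 16000, r = 0.5) — the dimensionality-mismatch
  bias it is documented to suffer, and the reason it is a diagnostic
  only.

Problem sizes used in the validation suite: single-site estimators at
n ∈ {250, 1000, 4000, 16000} × 20 seeds; pair mutual information at
n = 4000 × 20 seeds with 2 fill permutations; the decomposition
diagnostic at n = 16000 × 3 seeds.

## Scope

The package analyzes snapshots; it does not run dynamics, sample
alchemical legs (exnihilation values are user inputs), evaluate S_vol
from correlation functions, or discover sites by density clustering.
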