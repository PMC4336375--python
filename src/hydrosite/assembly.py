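"""Assembling per-site thermodynamics and comparison statistics.

The per-water ledger combines the energy and entropy pieces,

    ΔE_IFST = E_sw + E_ww − n·E_bulk,
    ΔS_IFST = S_sw + S_ww − n·S_bulk,
    ΔG_IFST = ΔE_IFST − T·ΔS_IFST,

each recomputed per frame block to give a between-block mean ± SD.
A nonlocal correction R(αT − 1) (≈ −R without a thermal-expansion
coefficient) converts ΔS_IFST into a hydration entropy; it is reported
separately and never folded into the per-site ledger.

Two bulk-entropy constants ship: the quoted model value S_BULK and the
value implied by the bulk energy and the insertion free energy,
S_BULK_CYCLE = (E_bulk − ΔG_insertion)/T.  Published per-site ledgers
are internally consistent only with the latter, so table arithmetic
defaults to it while the quoted constant remains selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (E_BULK, R_CAL, RHO_BULK, S_BULK, S_BULK_CYCLE,
                        T_DEFAULT)

__all__ = [
    "BulkReference",
    "ThermoComponents",
    "delta_S_ifst",
    "delta_G_ifst",
    "nonlocal_correction",
    "comparison_stats",
    "summarize_sites",
]


@dataclass(frozen=True)
class BulkReference:
    """Bulk-solvent constants anchoring the per-site decomposition.

    ``s_bulk`` defaults to the cycle-consistent value; pass
    ``S_BULK`` for the quoted model constant.  ``alpha`` (thermal
    expansion, 1/K) and ``kappa`` (isothermal compressibility) are
    optional bookkeeping for the nonlocal correction.
    """

    rho: float = RHO_BULK
    E_bulk: float = E_BULK
    s_bulk: float = S_BULK_CYCLE
    T: float = T_DEFAULT
    alpha: float | None = None
    kappa: float | None = None

    def __post_init__(self):
        if self.rho <= 0 or self.T <= 0:
            raise ValueError("rho and T must be positive")


@dataclass(frozen=True)
class ThermoComponents:
    """One hydration site's thermodynamic ledger, kcal/mol.

    Entropic fields are stored as −T·S contributions so every column is
    directly a free-energy contribution.  ``*_sd`` fields hold
    between-block standard deviations when block statistics were run.
    """

    site_id: str
    E_sw: float
    E_ww: float
    dE_ifst: float
    minus_T_S_sw: float
    minus_T_S_ww: float
    minus_T_dS_ifst: float
    dG_ifst: float
    n_waters: int = 1
    sd: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-9) -> None:
        """Check the internal ledger identities."""
        if abs(self.dG_ifst - (self.dE_ifst + self.minus_T_dS_ifst)) > atol:
            raise ValueError("dG != dE - T dS in the ledger")


def delta_S_ifst(S_sw: float, S_ww: float, n_waters: int,
                 bulk: BulkReference) -> float:
    """ΔS_IFST = S_sw + S_ww − n·S_bulk, cal/mol/K."""
    return S_sw + S_ww - n_waters * bulk.s_bulk


def delta_G_ifst(dE: float, minus_T_dS: float) -> float:
    """ΔG_IFST = ΔE_IFST + (−T·ΔS_IFST), kcal/mol."""
    return dE + minus_T_dS


def nonlocal_correction(dS_ifst: float, bulk: BulkReference) -> float:
    """Hydration entropy including the nonlocal term, cal/mol/K.

    Returns ΔS_IFST + R(αT − 1) when the bulk reference carries a
    thermal-expansion coefficient, else the ΔS_IFST − R approximation.
    """
    if bulk.alpha is not None:
        return dS_ifst + R_CAL * (bulk.alpha * bulk.T - 1.0)
    return dS_ifst - R_CAL


def assemble_site(site_id: str, E_sw: float, E_ww: float,
                  S_sw: float, S_ww: float,
                  bulk: BulkReference, n_waters: int = 1,
                  sd: dict | None = None) -> ThermoComponents:
    """Build a consistent :class:`ThermoComponents` from raw components."""
    dE = E_sw + E_ww - n_waters * bulk.E_bulk
    dS = delta_S_ifst(S_sw, S_ww, n_waters, bulk)
    mtds = -bulk.T * dS / 1000.0
    return ThermoComponents(site_id=site_id, E_sw=E_sw, E_ww=E_ww, dE_ifst=dE,
                            minus_T_S_sw=-bulk.T * S_sw / 1000.0,
                            minus_T_S_ww=-bulk.T * S_ww / 1000.0,
                            minus_T_dS_ifst=mtds,
                            dG_ifst=delta_G_ifst(dE, mtds),
                            n_waters=n_waters, sd=dict(sd or {}))


def analyze_frames(frames, sites, solute=None,
                   bulk: BulkReference | None = None,
                   n_blocks: int = 0, block_size: int = 0, seed: int = 0,
                   pair_gate: float = 4.0,
                   n_permutations: int = 8,
                   scheme: str = "none",
                   box=None,
                   s_vol: float = 0.0,
                   knn_k: int = 1) -> dict:
    """Full per-site thermodynamic analysis of a pose trajectory.

    ``frames`` is a list of per-frame :class:`~hydrosite.geometry.WaterPose`
    lists; ``sites`` the hydration-site definitions; ``solute`` an
    optional list of fixed nonbonded solute sites (omitting it skips the
    energy terms).  Waters are assigned per frame, site pairs within
    ``pair_gate`` Å (mean centre separation) get a permuted-fill mutual
    information, and each pair's −(I_ww + S_vol) is split half/half
    between its two member sites so a cavity's summed ledger counts the
    pair correlation exactly once.  With ``n_blocks`` > 0 every quantity
    is recomputed on disjoint random frame blocks and reported as the
    between-block mean, with SDs in each component's ``sd`` dict.

    Returns ``{"sites": [ThermoComponents...], "pairs": [...]}``.
    """
    from itertools import combinations

    from .energetics import solute_water_energy, water_water_energy
    from .entropy import solute_water_entropy
    from .mutualinfo import pair_mutual_information
    from .sites import (OccupancyError, build_pair_series, build_site_series,
                        block_partition)

    bulk = bulk or BulkReference()
    series = build_site_series(frames, sites)
    site_ids = [s.site_id for s in sites]

    pair_list = []
    for a, b in combinations(site_ids, 2):
        try:
            ps = build_pair_series(series[a], series[b], max_center_sep=pair_gate)
        except OccupancyError:
            continue
        pair_list.append((a, b, ps))

    def one_pass(sel=None, pass_seed=0):
        """Per-site components for one frame selection (None = all frames)."""
        out = {}
        frame_ok = None if sel is None else set(sel)
        for sid in site_ids:
            ss = series[sid]
            if sel is not None:
                keep = np.flatnonzero(np.isin(ss.frame_indices, sel))
                ss = ss.subset(keep)
            if ss.n < knn_k + 1:
                continue
            S_sw = solute_water_entropy(ss, bulk.rho, k=knn_k).value
            E_sw = 0.0
            if solute:
                E_sw = solute_water_energy(ss, solute, scheme=scheme, box=box)
            out[sid] = {"S_sw": S_sw, "E_sw": E_sw, "S_ww": 0.0, "E_ww": 0.0,
                        "occupancy": ss.occupancy, "n": ss.n, "_series": ss}
        for a, b, ps in pair_list:
            if sel is not None:
                keep = np.flatnonzero(np.isin(ps.frame_indices, sel))
                ps = ps.subset(keep)
            if ps.n < knn_k + 1 or a not in out or b not in out:
                continue
            mi = pair_mutual_information(ps, n_permutations=n_permutations,
                                         seed=pass_seed, k=knn_k)
            half = -(mi.value + s_vol) / 2.0
            out[a]["S_ww"] += half
            out[b]["S_ww"] += half
            out[a]["I_ww"] = out[b]["I_ww"] = mi.value
            if solute is not None:
                e_ab = _mean_pair_water_energy(ps, scheme, box)
                out[a]["E_ww"] += 0.5 * e_ab
                out[b]["E_ww"] += 0.5 * e_ab
        return out

    full = one_pass(None, seed)
    blocks = []
    if n_blocks > 0:
        idx_blocks = block_partition(len(frames), n_blocks, block_size, seed)
        blocks = [one_pass(blk, seed + 1 + i) for i, blk in enumerate(idx_blocks)]

    results = []
    for sid in site_ids:
        if sid not in full:
            continue
        central = full[sid]
        if blocks:
            per_block = [b[sid] for b in blocks if sid in b]
            comp_blocks = [assemble_site(sid, p["E_sw"], p["E_ww"], p["S_sw"],
                                         p["S_ww"], bulk) for p in per_block]
            cols = ["E_sw", "E_ww", "dE_ifst", "minus_T_S_sw", "minus_T_S_ww",
                    "minus_T_dS_ifst", "dG_ifst"]
            mean = {c: float(np.mean([getattr(t, c) for t in comp_blocks])) for c in cols}
            sd = {c: float(np.std([getattr(t, c) for t in comp_blocks], ddof=1))
                  for c in cols}
            comp = ThermoComponents(site_id=sid, n_waters=1, sd=sd, **mean)
        else:
            comp = assemble_site(sid, central["E_sw"], central["E_ww"],
                                 central["S_sw"], central["S_ww"], bulk)
        results.append(comp)
    pair_rows = [{"site_1": a, "site_2": b, "n_frames": ps.n,
                  "I_ww": full.get(a, {}).get("I_ww")}
                 for a, b, ps in pair_list]
    return {"sites": results, "pairs": pair_rows}


def _mean_pair_water_energy(ps, scheme, box) -> float:
    """Mean water-water interaction energy of a synchronized pair, kcal/mol."""
    from .energetics import pair_energy, water_nonbonded_sites
    from .geometry import WaterPose
    total = 0.0
    for i in range(ps.n):
        w1 = water_nonbonded_sites(WaterPose(ps.positions1[i], ps.orientations1[i]))
        w2 = water_nonbonded_sites(WaterPose(ps.positions2[i], ps.orientations2[i]))
        total += pair_energy(w1, w2, scheme=scheme, box=box)
    return total / ps.n


def comparison_stats(reference, predicted) -> dict:
    """Agreement statistics between two per-site ΔG lists, kcal/mol.

    Returns the coefficient of determination of the least-squares
    linear fit (the squared Pearson correlation), the mean unsigned
    difference, and the mean signed difference with the convention
    ``reference − predicted`` per site, so a negative mean says the
    reference values sit below the predictions on average.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be equal-length 1D lists")
    if len(ref) < 2:
        raise ValueError("need at least two sites to compare")
    r = np.corrcoef(ref, pred)[0, 1]
    diff = ref - pred
    return {
        "r_squared": float(r * r),
        "mud": float(np.mean(np.abs(diff))),
        "mean_signed": float(np.mean(diff)),
        "n": int(len(ref)),
    }


def summarize_sites(table: list[ThermoComponents], decimals: int = 2) -> dict:
    """Column-wise minimum, maximum and mean over a per-site table.

    Values are rounded to the reporting precision (two decimals in
    kcal/mol by default).
    """
    if not table:
        raise ValueError("empty site table")
    cols = ["E_sw", "E_ww", "dE_ifst", "minus_T_S_sw", "minus_T_S_ww",
            "minus_T_dS_ifst", "dG_ifst"]
    out = {}
    for c in cols:
        v = np.array([getattr(t, c) for t in table], dtype=float)
        out[c] = {"min": round(float(v.min()), decimals),
                  "max": round(float(v.max()), decimals),
                  "mean": round(float(v.mean()), decimals)}
    return out
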