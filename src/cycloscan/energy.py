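"""Scoring model: Lennard-Jones, screened Coulomb, hydrogen bonds, strain.

The published screen used a proprietary scoring function; values produced
here are on this model's own internal scale (kcal/mol-like) and only
orderings and class contrasts are meaningful. The functional forms:

* LJ 6-12 per element pair: ``eps_ij * ((rm/r)^12 - 2 (rm/r)^6)`` with
  ``rm = rm_i + rm_j``, ``eps_ij = sqrt(eps_i eps_j)``.
* Coulomb with distance-dependent dielectric ``eps(r) = 4 r``:
  ``332.0637 * q_i q_j / (4 r^2)``.
* Hydrogen bond 10-12 well between donor/acceptor heavy atoms,
  ``eps_hb * (5 (r0/r)^12 - 6 (r0/r)^10)`` weighted by ``cos^2`` of the
  antecedent-donor-acceptor angle (zero below 90 deg).
* Torsion strain: 3-fold barrier on peptide sidechain chi angles plus a
  cosine rotamer-deviation penalty for moved gatekeeper sidechains.

All pair terms are truncated at the nonbonded cutoff, so a fully separated
pose scores exactly zero. Pairs closer than the clash distance contribute a
large finite repulsion and set the clash flag (never infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa import (
    BACKBONE_PARTIAL_CHARGE,
    LJ_EPS,
    LJ_RMIN_HALF,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    SIDECHAIN_PARTIAL_CHARGE,
)
from .core import Structure

COULOMB_CONST = 332.0637  # kcal mol^-1 Å e^-2


@dataclass
class EnergyModel:
    """Force-field parameters; defaults are the documented internal scale."""

    lj_eps: dict = field(default_factory=lambda: dict(LJ_EPS))
    lj_rmin_half: dict = field(default_factory=lambda: dict(LJ_RMIN_HALF))
    dielectric_slope: float = 4.0        # eps(r) = slope * r
    hb_eps: float = 2.0                  # kcal/mol well depth
    hb_r0: float = 2.9                   # Å optimal donor-acceptor distance
    hb_dist_min: float = 2.5             # Å counting window
    hb_dist_max: float = 3.5
    hb_angle_min: float = 100.0          # deg, antecedent-donor-acceptor
    cutoff: float = 8.0                  # Å nonbonded truncation
    clash_dist: float = 0.5              # Å; closer pairs -> finite clash energy
    clash_energy: float = 1000.0
    tether_k: float = 10.0               # kcal mol^-1 Å^-2
    chi_barrier: float = 0.3             # peptide sidechain 3-fold barrier height
    rotamer_k: float = 1.0               # gatekeeper deviation penalty scale

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.lj_eps.values()) or self.hb_eps < 0:
            raise ValueError("well depths must be non-negative")
        max_rmin = 2 * max(self.lj_rmin_half.values())
        if self.cutoff <= max_rmin:
            raise ValueError("cutoff must exceed the largest LJ radius sum")


@dataclass
class AtomParams:
    """Per-atom force-field arrays for one structure."""

    eps: np.ndarray
    rmin_half: np.ndarray
    charge: np.ndarray
    donor: np.ndarray        # bool
    acceptor: np.ndarray     # bool
    antecedent: np.ndarray   # int index of a bonded heavy atom, for HB angles


def _antecedent_name(res_name: str, atom_name: str) -> tuple[str, ...]:
    """Plausible bonded heavy-atom names for donor/acceptor geometry."""
    table = {
        "N": ("CA",), "O": ("C",),
        "NE": ("CD",), "NH1": ("CZ",), "NH2": ("CZ",),
        "ND2": ("CG",), "OD1": ("CG",), "OD2": ("CG",),
        "NE2": ("CD", "CD2"), "OE1": ("CD",), "OE2": ("CD",),
        "ND1": ("CG",), "NZ": ("CE",), "OG": ("CB",), "OG1": ("CB",),
        "NE1": ("CD1",), "OH": ("CZ",), "SG": ("CB",),
    }
    return table.get(atom_name, ("CA",))


def atom_params(structure: Structure, model: EnergyModel) -> AtomParams:
    """Assign LJ/charge/H-bond typing to every atom of a structure."""
    n = structure.n_atoms
    eps = np.zeros(n)
    rmin_half = np.zeros(n)
    charge = np.zeros(n)
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    antecedent = np.full(n, -1, dtype=np.int64)

    for ri in range(structure.n_residues):
        sl = structure.residue_slice(ri)
        res_name = str(structure.res_name[sl.start])
        names = structure.atom_name[sl]
        local = {str(nm): sl.start + j for j, nm in enumerate(names)}
        for j in range(sl.start, sl.stop):
            el = str(structure.element[j])
            name = str(structure.atom_name[j])
            eps[j] = model.lj_eps.get(el, 0.1)
            rmin_half[j] = model.lj_rmin_half.get(el, 1.9)
            if name in BACKBONE_PARTIAL_CHARGE:
                charge[j] = BACKBONE_PARTIAL_CHARGE[name]
            charge[j] += SIDECHAIN_PARTIAL_CHARGE.get((res_name, name), 0.0)
            is_donor = (name == "N" and res_name != "PRO") or (
                name in SIDECHAIN_DONORS.get(res_name, ())
            )
            is_acceptor = (name == "O") or (
                name in SIDECHAIN_ACCEPTORS.get(res_name, ())
            )
            if is_donor or is_acceptor:
                for cand in _antecedent_name(res_name, name):
                    if cand in local:
                        antecedent[j] = local[cand]
                        break
                if antecedent[j] < 0:
                    is_donor = is_acceptor = False  # no geometry available
            donor[j] = is_donor
            acceptor[j] = is_acceptor
    return AtomParams(eps, rmin_half, charge, donor, acceptor, antecedent)


def pair_energies(
    coords_a: np.ndarray,
    params_a: AtomParams,
    idx_a: np.ndarray,
    coords_b: np.ndarray,
    params_b: AtomParams,
    idx_b: np.ndarray,
    model: EnergyModel,
) -> tuple[float, float, float, bool]:
    """(LJ, Coulomb, H-bond) energy between two atom selections.

    Selections must belong to different molecules (no exclusions applied).
    Returns ``(e_lj, e_coul, e_hb, clash)``.
    """
    xa = coords_a[idx_a]
    xb = coords_b[idx_b]
    diff = xa[:, None, :] - xb[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    within = r < model.cutoff
    clash = bool(np.any(r < model.clash_dist))

    e_lj = 0.0
    e_coul = 0.0
    e_hb = 0.0
    eps_ij = np.sqrt(np.outer(params_a.eps[idx_a], params_b.eps[idx_b]))
    rm_ij = params_a.rmin_half[idx_a][:, None] + params_b.rmin_half[idx_b][None, :]
    q_ij = np.outer(params_a.charge[idx_a], params_b.charge[idx_b])

    r_safe = np.maximum(r, model.clash_dist)
    ratio = rm_ij / r_safe
    lj = eps_ij * (ratio**12 - 2.0 * ratio**6)
    lj = lj + np.where(r < model.clash_dist, model.clash_energy, 0.0)
    e_lj = float(np.sum(lj[within]))

    coul = COULOMB_CONST * q_ij / (model.dielectric_slope * r_safe**2)
    e_coul = float(np.sum(coul[within]))

    # hydrogen bonds: donor in one selection, acceptor in the other
    for (da, db, ca_, cb_, pa, pb, ia, ib, rmat, sgn) in (
        (params_a.donor[idx_a], params_b.acceptor[idx_b], coords_a, coords_b,
         params_a, params_b, idx_a, idx_b, r, +1),
        (params_b.donor[idx_b], params_a.acceptor[idx_a], coords_b, coords_a,
         params_b, params_a, idx_b, idx_a, r.T, +1),
    ):
        dmask = np.flatnonzero(da)
        amask = np.flatnonzero(db)
        for di in dmask:
            d_glob = ia[di]
            ant = pa.antecedent[d_glob]
            for aj in amask:
                dist = rmat[di, aj]
                if dist < model.hb_dist_min or dist > model.hb_dist_max:
                    continue
                v1 = ca_[ant] - ca_[d_glob]
                v2 = cb_[ib[aj]] - ca_[d_glob]
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle < model.hb_angle_min:
                    continue
                w = cosang**2  # cos^2 of the angle, grows toward linearity
                ratio0 = model.hb_r0 / dist
                e_hb += model.hb_eps * (5 * ratio0**12 - 6 * ratio0**10) * w
    return e_lj, e_coul, e_hb, clash


def hbond_pairs(
    coords_a: np.ndarray,
    params_a: AtomParams,
    coords_b: np.ndarray,
    params_b: AtomParams,
    model: EnergyModel,
) -> list[tuple[int, int]]:
    """Donor-acceptor pairs (a_index, b_index) inside the H-bond window."""
    out = []
    for donor_side, params_d, coords_d, params_acc, coords_acc, flip in (
        ("a", params_a, coords_a, params_b, coords_b, False),
        ("b", params_b, coords_b, params_a, coords_a, True),
    ):
        d_idx = np.flatnonzero(params_d.donor)
        a_idx = np.flatnonzero(params_acc.acceptor)
        if len(d_idx) == 0 or len(a_idx) == 0:
            continue
        diff = coords_d[d_idx][:, None, :] - coords_acc[a_idx][None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        for i, di in enumerate(d_idx):
            ant = params_d.antecedent[di]
            for j, aj in enumerate(a_idx):
                if not (model.hb_dist_min <= r[i, j] <= model.hb_dist_max):
                    continue
                v1 = coords_d[ant] - coords_d[di]
                v2 = coords_acc[aj] - coords_d[di]
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle < model.hb_angle_min:
                    continue
                out.append((int(aj), int(di)) if flip else (int(di), int(aj)))
    return sorted(set(out))
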