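"""Tethered Monte-Carlo tetrapeptide screen.

The screen enumerates X-Z-Gly-Pro tetrapeptides, anchors each one's
Gly-Pro onto a template-derived pose, and samples P2/P3 torsions together
with the gatekeeper sidechains by Metropolis Monte Carlo. Two readouts are
kept per peptide: a binding-energy estimate (internal scale) and the
closest approach to the gatekeeper-2 Calpha, which reports on S2-pocket
penetration.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from ._aa import STANDARD_AA1
from . import _kernel
from .core import Structure
from .energy import AtomParams, EnergyModel, atom_params, hbond_pairs, pair_energies
from .peptide import (
    BuiltPeptide,
    TorsionDef,
    _component,
    build_adjacency,
    build_peptide,
    dihedral,
    ideal_residue,
)
from .structures import (
    ActiveSiteMap,
    Superposition,
    kabsch_superpose,
)

KB = 0.0019872  # kcal mol^-1 K^-1

GATEKEEPER_FLEX_POSITIONS = (73, 82, 103)


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class Peptide:
    """An X-Z-Gly-Pro test peptide; P1=Gly and P1'=Pro are fixed."""

    p3: str
    p2: str

    def __post_init__(self):
        for c in (self.p3, self.p2):
            if c not in STANDARD_AA1:
                raise ValueError(f"not a standard amino acid: {c!r}")

    @property
    def sequence(self) -> str:
        return f"{self.p3}{self.p2}GP"


def generate_library(alphabet: str = STANDARD_AA1) -> list[Peptide]:
    """Every (P3, P2) combination over the alphabet, lexicographic order."""
    if len(alphabet) == 0:
        raise ValueError("alphabet must be non-empty")
    letters = sorted(set(alphabet))
    return [Peptide(p3=x, p2=z) for x in letters for z in letters]


@dataclass
class PeptidePose:
    """A placed tetrapeptide with its tether anchor bookkeeping."""

    built: BuiltPeptide
    anchor_atom_indices: np.ndarray   # indices into the peptide's atoms
    anchor_reference: np.ndarray      # (k, 3) template coordinates in Å

    @property
    def structure(self) -> Structure:
        return self.built.structure

    def copy_with_coords(self, coords: np.ndarray) -> "PeptidePose":
        built = BuiltPeptide(
            structure=Structure(
                id=self.structure.id, chain=self.structure.chain,
                atom_name=self.structure.atom_name.copy(),
                element=self.structure.element.copy(),
                res_id=self.structure.res_id.copy(),
                res_name=self.structure.res_name.copy(),
                coord=np.array(coords, dtype=np.float64),
            ),
            bonds=list(self.built.bonds),
            residue_atom_offsets=list(self.built.residue_atom_offsets),
        )
        return PeptidePose(
            built=built,
            anchor_atom_indices=self.anchor_atom_indices.copy(),
            anchor_reference=self.anchor_reference.copy(),
        )


@dataclass
class MCParams:
    iterations: int = 200_000
    temperature: float = 300.0          # Kelvin-equivalent
    anneal: float = 1.0                 # per-iteration geometric kT factor
    move_weights: dict = field(
        default_factory=lambda: {
            "peptide_chi": 1.0, "peptide_backbone": 1.0, "gatekeeper_chi": 1.0
        }
    )
    max_step_deg: float = 30.0
    seed: int = 0
    discrete_angles: tuple[float, ...] | None = None
    log_interval: int = 1000

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        w = list(self.move_weights.values())
        if any(x < 0 for x in w) or not any(x > 0 for x in w):
            raise ValueError("move weights must be non-negative and not all zero")


@dataclass
class ScreenRecord:
    peptide: Peptide
    e_bind: float
    d_s2: float
    n_hb: int
    accepted_moves: int
    pose: PeptidePose | None
    components: dict = field(default_factory=dict)
    status: str = "ok"


# ---------------------------------------------------------------------------
# placement


def find_glypro_ligand(template: Structure) -> tuple[int, int]:
    """Residue indices of the bound Gly-Pro ligand in a template complex.

    The ligand is the last consecutive (GLY, PRO) residue pair that is not
    followed by a covalently continuing chain residue.
    """
    names = template.residue_names()
    ids = template.residue_ids()
    n = template.n_residues
    candidates = []
    for i in range(n - 1):
        if names[i] == "GLY" and names[i + 1] == "PRO" and ids[i + 1] == ids[i] + 1:
            terminal = (i + 2 >= n) or (ids[i + 2] != ids[i + 1] + 1)
            if terminal:
                candidates.append(i)
    if not candidates:
        raise PlacementError("template lacks Gly-Pro ligand")
    return candidates[-1], candidates[-1] + 1


def superpose_template(
    receptor: Structure,
    receptor_map: ActiveSiteMap,
    template: Structure,
    template_map: ActiveSiteMap,
) -> Superposition:
    """Superpose template onto receptor over mapped active-site backbones."""
    xa, xb = [], []
    for pos in receptor_map.entries:
        if not (receptor_map.is_mapped(pos) and template_map.is_mapped(pos)):
            continue
        ri = receptor.residue_index(receptor_map.residue_number(pos))
        ti = template.residue_index(template_map.residue_number(pos))
        for name in ("N", "CA", "C", "O"):
            try:
                xa.append(receptor.coord[receptor.atom_index(ri, name)])
                xb.append(template.coord[template.atom_index(ti, name)])
            except KeyError:
                continue
    if len(xa) < 3:
        raise PlacementError("too few shared active-site atoms for superposition")
    return kabsch_superpose(np.array(xa), np.array(xb))


def _receptor_chi_torsions(receptor: Structure, res_index: int) -> list[TorsionDef]:
    """Chi torsions for one receptor residue, from its ideal-template graph."""
    from ._aa import CHI_ATOMS

    res_name = str(receptor.residue_names()[res_index])
    quads = CHI_ATOMS.get(res_name, [])
    if not quads:
        return []
    try:
        _, _, _, tbonds = ideal_residue(res_name)
        tnames = ideal_residue(res_name)[0]
    except ValueError:
        return []
    sl = receptor.residue_slice(res_index)
    names_here = {str(nm): sl.start + j for j, nm in enumerate(receptor.atom_name[sl])}
    # adjacency over atom names from the template bond graph
    name_adj: dict[str, set[str]] = {}
    for i, j in tbonds:
        a, b = str(tnames[i]), str(tnames[j])
        name_adj.setdefault(a, set()).add(b)
        name_adj.setdefault(b, set()).add(a)
    out = []
    for ci, quad in enumerate(quads):
        if any(nm not in names_here for nm in quad):
            continue
        # atoms distal to the rotated bond, by name-level BFS
        seen = {quad[3]}
        stack = [quad[3]]
        while stack:
            u = stack.pop()
            for v in name_adj.get(u, ()):
                if {u, v} == {quad[1], quad[2]}:
                    continue
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        moving = [names_here[nm] for nm in seen if nm in names_here and nm != quad[2]]
        if not moving:
            continue
        out.append(
            TorsionDef(
                name=f"gk-chi{ci + 1}:{res_name}{res_index}",
                atoms=tuple(names_here[nm] for nm in quad),
                moving=np.array(sorted(moving), dtype=int),
                sign=+1.0,
            )
        )
    return out


def place_peptide(
    peptide: Peptide,
    receptor: Structure,
    template: Structure,
    site_map: ActiveSiteMap,
    template_map: ActiveSiteMap | None = None,
    clash_tolerance: float = 1.5,
) -> PeptidePose:
    """Build the tetrapeptide and anchor its Gly-Pro on the template pose.

    The template's bound Gly-Pro defines the anchor. If ``template_map`` is
    given the template complex is first superposed onto the receptor over
    mapped active-site backbone atoms and, when both structures carry an
    arginine at reference position 55, the receptor's catalytic arginine
    sidechain is set to the template-aligned rotamer (in place).
    """
    gi, pi = find_glypro_ligand(template)

    ligand_coords = {}
    for res_index, res_tag in ((gi, "GLY"), (pi, "PRO")):
        sl = template.residue_slice(res_index)
        for j in range(sl.start, sl.stop):
            ligand_coords[(res_tag, str(template.atom_name[j]))] = template.coord[j]

    if template_map is not None:
        sup = superpose_template(receptor, site_map, template, template_map)
        ligand_coords = {k: sup.apply(v) for k, v in ligand_coords.items()}
        _reposition_catalytic_arginine(receptor, site_map, template, template_map, sup)

    built = build_peptide(peptide.sequence, label=peptide.sequence)
    s = built.structure

    pep_idx, ref_xyz = [], []
    for res_index, res_tag in ((2, "GLY"), (3, "PRO")):
        sl = s.residue_slice(res_index)
        for j in range(sl.start, sl.stop):
            key = (res_tag, str(s.atom_name[j]))
            if key in ligand_coords:
                pep_idx.append(j)
                ref_xyz.append(ligand_coords[key])
    if len(pep_idx) < 3:
        raise PlacementError("fewer than 3 anchor atoms shared with template ligand")
    ref_xyz = np.array(ref_xyz)

    sup = kabsch_superpose(ref_xyz, s.coord[pep_idx])
    s.coord = sup.apply(s.coord)

    pose = PeptidePose(
        built=built,
        anchor_atom_indices=np.array(pep_idx, dtype=int),
        anchor_reference=ref_xyz,
    )

    flex_atoms = np.concatenate(
        [np.arange(s.residue_slice(0).start, s.residue_slice(0).stop),
         np.arange(s.residue_slice(1).start, s.residue_slice(1).stop)]
    )
    dmin = cdist(s.coord[flex_atoms], receptor.coord).min()
    if dmin < clash_tolerance:
        warnings.warn(
            f"initial P2/P3 placement clashes with receptor "
            f"(min distance {dmin:.2f} Å); MC will resolve",
            stacklevel=2,
        )
    return pose


def _reposition_catalytic_arginine(
    receptor: Structure,
    site_map: ActiveSiteMap,
    template: Structure,
    template_map: ActiveSiteMap,
    sup: Superposition,
) -> None:
    """Copy the template catalytic-arginine chi angles onto the receptor."""
    try:
        if site_map.residue_name(55) != "ARG" or template_map.residue_name(55) != "ARG":
            return
        r_index = receptor.residue_index(site_map.residue_number(55))
        t_index = template.residue_index(template_map.residue_number(55))
    except KeyError:
        return
    r_tors = _receptor_chi_torsions(receptor, r_index)
    t_tors = _receptor_chi_torsions(template, t_index)
    for rt, tt in zip(r_tors, t_tors):
        try:
            rt.set_value(receptor.coord, tt.value(template.coord))
        except Exception:
            return


# ---------------------------------------------------------------------------
# scoring


def tether_penalty(pose: PeptidePose, k: float) -> float:
    """Harmonic anchor restraint: ``k * sum(d_i^2)`` over Gly-Pro atoms."""
    d = pose.structure.coord[pose.anchor_atom_indices] - pose.anchor_reference
    return float(k * np.sum(d * d))


def _peptide_chi_torsions(pose: PeptidePose) -> list[TorsionDef]:
    return pose.built.chi_torsions(0) + pose.built.chi_torsions(1)


def score_energy(
    pose: PeptidePose,
    receptor: Structure,
    model: EnergyModel,
    receptor_params: AtomParams | None = None,
    gatekeeper_state: list[tuple[TorsionDef, float]] | None = None,
) -> tuple[float, dict]:
    """Binding-energy estimate of a pose against the (possibly moved) receptor.

    ``E_bind = E_lj + E_coulomb + E_hbond + E_strain`` where the interaction
    terms run over peptide-receptor pairs within the cutoff and the strain
    covers peptide sidechain torsions plus gatekeeper rotamer deviations
    (``gatekeeper_state`` pairs each moved torsion with its initial angle).
    The separated reference is exactly zero. Intra-peptide nonbonded energy
    and the tether are reported in the components but excluded from E_bind.
    """
    s = pose.structure
    pp = atom_params(s, model)
    rp = receptor_params if receptor_params is not None else atom_params(receptor, model)
    all_p = np.arange(s.n_atoms)
    all_r = np.arange(receptor.n_atoms)
    e_lj, e_coul, e_hb, clash = pair_energies(
        s.coord, pp, all_p, receptor.coord, rp, all_r, model
    )

    strain = 0.0
    for tor in _peptide_chi_torsions(pose):
        chi = tor.value(s.coord)
        strain += model.chi_barrier * (1.0 + np.cos(np.deg2rad(3.0 * chi)))
    for tor, theta0 in gatekeeper_state or []:
        chi = tor.value(receptor.coord)
        strain += model.rotamer_k * (1.0 - np.cos(np.deg2rad(chi - theta0)))

    e_intra = _intra_peptide_energy(pose, pp, model)
    e_bind = e_lj + e_coul + e_hb + strain
    components = {
        "lj": e_lj, "coulomb": e_coul, "hbond": e_hb, "strain": strain,
        "intra": e_intra, "tether": tether_penalty(pose, model.tether_k),
        "clash": clash,
    }
    return float(e_bind), components


def _intra_peptide_energy(pose: PeptidePose, pp: AtomParams, model: EnergyModel) -> float:
    """Nonbonded energy between peptide atoms separated by > 3 bonds.

    Term-for-term identical to the MC kernel's treatment of intra-peptide
    pairs (LJ + Coulomb + angular-weighted H-bond), so kernel energy
    deltas are exact deltas of the reference objective.
    """
    from .peptide import bond_distance_matrix

    s = pose.structure
    n = s.n_atoms
    sep = bond_distance_matrix(n, pose.built.bonds, max_depth=3)
    coords = s.coord
    cos_max = float(np.cos(np.deg2rad(model.hb_angle_min)))
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if sep[i, j] <= 3:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r >= model.cutoff:
                continue
            if r < model.clash_dist:
                e += model.clash_energy
                r = model.clash_dist
            rm = pp.rmin_half[i] + pp.rmin_half[j]
            ratio6 = (rm / r) ** 6
            e += np.sqrt(pp.eps[i] * pp.eps[j]) * (ratio6 * ratio6 - 2 * ratio6)
            qq = pp.charge[i] * pp.charge[j]
            if qq:
                e += 332.0637 * qq / (model.dielectric_slope * r * r)
            if model.hb_dist_min <= r <= model.hb_dist_max:
                for d_at, a_at in ((i, j), (j, i)):
                    if not (pp.donor[d_at] and pp.acceptor[a_at]):
                        continue
                    ant = pp.antecedent[d_at]
                    v1 = coords[ant] - coords[d_at]
                    v2 = coords[a_at] - coords[d_at]
                    cosang = float(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    if cosang <= cos_max:
                        ratio0 = model.hb_r0 / r
                        e += (
                            model.hb_eps
                            * (5 * ratio0**12 - 6 * ratio0**10)
                            * cosang**2
                        )
    return float(e)


def sampling_energy(
    pose: PeptidePose,
    receptor: Structure,
    model: EnergyModel,
    gatekeeper_state: list[tuple[TorsionDef, float]] | None = None,
) -> float:
    """The Metropolis objective: E_bind + intra-peptide + tether.

    (Receptor-internal energy of moved gatekeepers is additionally part of
    the kernel's objective but is constant when gatekeepers do not move.)
    """
    e_bind, comp = score_energy(
        pose, receptor, model, gatekeeper_state=gatekeeper_state
    )
    return e_bind + comp["intra"] + comp["tether"]


def count_hbonds(
    pose: PeptidePose,
    receptor: Structure,
    model: EnergyModel,
    receptor_params: AtomParams | None = None,
) -> int:
    """Peptide-receptor donor-acceptor pairs inside the distance/angle window."""
    s = pose.structure
    pp = atom_params(s, model)
    rp = receptor_params if receptor_params is not None else atom_params(receptor, model)
    return len(hbond_pairs(s.coord, pp, receptor.coord, rp, model))


def s2_distance(pose: PeptidePose, receptor: Structure, site_map: ActiveSiteMap) -> float:
    """Minimum peptide-heavy-atom distance (Å) to the gatekeeper-2 Calpha."""
    if not site_map.is_mapped(82):
        raise KeyError("gatekeeper-2 (reference position 82) is unmapped")
    res_index = receptor.residue_index(site_map.residue_number(82))
    ca = receptor.coord[receptor.atom_index(res_index, "CA")]
    d = np.linalg.norm(pose.structure.coord - ca, axis=1)
    return float(d.min())


# ---------------------------------------------------------------------------
# sampling


def _receptor_bonds(receptor: Structure) -> list[tuple[int, int]]:
    """Intra-residue bonds from ideal templates plus backbone C-N links."""
    bonds: list[tuple[int, int]] = []
    prev_c = None
    prev_rid = None
    for ri in range(receptor.n_residues):
        sl = receptor.residue_slice(ri)
        res_name = str(receptor.res_name[sl.start])
        local = {str(nm): sl.start + j for j, nm in enumerate(receptor.atom_name[sl])}
        try:
            tnames, _, _, tbonds = ideal_residue(res_name)
        except ValueError:
            tnames, tbonds = np.array([]), []
        for i, j in tbonds:
            a, b = str(tnames[i]), str(tnames[j])
            if a in local and b in local:
                bonds.append((local[a], local[b]))
        rid = int(receptor.res_id[sl.start])
        if prev_c is not None and rid == prev_rid + 1 and "N" in local:
            bonds.append((prev_c, local["N"]))
        prev_c = local.get("C")
        prev_rid = rid
    return bonds


def _exclusion_matrix(n_atoms: int, bonds, max_sep: int = 3) -> np.ndarray:
    from .peptide import bond_distance_matrix

    sep = bond_distance_matrix(n_atoms, bonds, max_depth=max_sep)
    return (sep <= max_sep).astype(np.uint8).ravel()


def _gatekeeper_torsions(
    receptor: Structure,
    site_map: ActiveSiteMap,
    extra_flexible: tuple[int, ...] = (),
) -> list[TorsionDef]:
    res_indices = []
    for pos in GATEKEEPER_FLEX_POSITIONS:
        if site_map.is_mapped(pos):
            res_indices.append(receptor.residue_index(site_map.residue_number(pos)))
    for rid in extra_flexible:
        res_indices.append(receptor.residue_index(rid))
    torsions = []
    for ri in res_indices:
        torsions.extend(_receptor_chi_torsions(receptor, ri))
    return torsions


def mc_sample(
    pose: PeptidePose,
    receptor: Structure,
    site_map: ActiveSiteMap,
    model: EnergyModel,
    params: MCParams,
    extra_flexible: tuple[int, ...] = (),
) -> tuple[ScreenRecord, np.ndarray]:
    """Metropolis sampling of the flexible torsions; returns the best pose.

    Acceptance runs on the total sampling energy (interaction + strain +
    intra-peptide + tether); the reported ``e_bind`` of the best pose is
    recomputed with :func:`score_energy` and excludes the tether and
    intra-peptide terms. Fully reproducible from ``params.seed``.
    """
    s = pose.structure
    nr = receptor.n_atoms
    coords = np.vstack([receptor.coord, s.coord])

    rp = atom_params(receptor, model)
    pp = atom_params(s, model)
    merged = AtomParams(
        eps=np.concatenate([rp.eps, pp.eps]),
        rmin_half=np.concatenate([rp.rmin_half, pp.rmin_half]),
        charge=np.concatenate([rp.charge, pp.charge]),
        donor=np.concatenate([rp.donor, pp.donor]),
        acceptor=np.concatenate([rp.acceptor, pp.acceptor]),
        antecedent=np.concatenate(
            [rp.antecedent, np.where(pp.antecedent >= 0, pp.antecedent + nr, -1)]
        ),
    )

    gk_torsions = _gatekeeper_torsions(receptor, site_map, extra_flexible)
    gk_theta0 = [t.value(receptor.coord) for t in gk_torsions]

    pep_chi = _peptide_chi_torsions(pose)
    pep_bb = pose.built.backbone_torsions(0) + pose.built.backbone_torsions(1)

    def _shift(t: TorsionDef, off: int) -> TorsionDef:
        return TorsionDef(
            name=t.name,
            atoms=tuple(a + off for a in t.atoms),
            moving=t.moving + off,
            sign=t.sign,
        )

    torsions: list[tuple[TorsionDef, int, float]] = []  # (def, type, theta0)
    for t in pep_chi:
        torsions.append((_shift(t, nr), 0, 0.0))
    for t in pep_bb:
        torsions.append((_shift(t, nr), 1, 0.0))
    for t, th0 in zip(gk_torsions, gk_theta0):
        torsions.append((t, 2, th0))

    type_names = {0: "peptide_chi", 1: "peptide_backbone", 2: "gatekeeper_chi"}
    weights = params.move_weights
    counts = {tt: sum(1 for _, t2, _ in torsions if t2 == tt) for tt in (0, 1, 2)}
    probs = []
    for tdef, tt, th0 in torsions:
        w = weights.get(type_names[tt], 0.0)
        probs.append(w / counts[tt] if counts[tt] else 0.0)
    probs = np.array(probs, dtype=float)
    if probs.sum() <= 0 or len(torsions) == 0:
        raise ValueError("move set has zero total weight")
    cumprob = np.cumsum(probs / probs.sum())

    bonds = _receptor_bonds(receptor) + [
        (i + nr, j + nr) for i, j in pose.built.bonds
    ]
    excl = _exclusion_matrix(nr + s.n_atoms, bonds)

    n_t = len(torsions)
    t_atoms = np.array([t.atoms for t, _, _ in torsions], dtype=np.int64).reshape(n_t, 4)
    t_sign = np.array([t.sign for t, _, _ in torsions], dtype=np.float64)
    t_type = np.array([tt for _, tt, _ in torsions], dtype=np.int64)
    t_theta0 = np.array([th for _, _, th in torsions], dtype=np.float64)
    moving_start = np.zeros(n_t + 1, dtype=np.int64)
    flat = []
    for i, (t, _, _) in enumerate(torsions):
        flat.extend(t.moving.tolist())
        moving_start[i + 1] = len(flat)
    moving_flat = np.array(flat, dtype=np.int64)

    disc = np.array(params.discrete_angles or [0.0], dtype=np.float64)
    use_disc = 1 if params.discrete_angles else 0

    best_rel, best_coords, accepted, trace = _kernel.run_mc(
        coords.copy(), excl,
        merged.eps, merged.rmin_half, merged.charge,
        merged.donor.astype(np.uint8), merged.acceptor.astype(np.uint8),
        merged.antecedent.astype(np.int64),
        t_atoms, t_sign, t_type, t_theta0, cumprob,
        moving_flat, moving_start,
        params.iterations, KB * params.temperature, params.anneal,
        params.max_step_deg, params.seed,
        disc, use_disc, params.log_interval,
        model.cutoff, model.clash_dist, model.clash_energy, model.dielectric_slope,
        model.hb_eps, model.hb_r0, model.hb_dist_min, model.hb_dist_max,
        float(np.cos(np.deg2rad(model.hb_angle_min))),
        model.chi_barrier, model.rotamer_k,
    ) if params.iterations > 0 else (0.0, coords.copy(), 0, np.zeros(1))

    best_receptor = receptor.copy()
    best_receptor.coord = best_coords[:nr]
    best_pose = pose.copy_with_coords(best_coords[nr:])

    e_bind, components = score_energy(
        best_pose, best_receptor, model,
        gatekeeper_state=list(zip(gk_torsions, gk_theta0)),
    )
    record = ScreenRecord(
        peptide=Peptide(p3=s.sequence()[0], p2=s.sequence()[1]),
        e_bind=e_bind,
        d_s2=s2_distance(best_pose, best_receptor, site_map),
        n_hb=count_hbonds(best_pose, best_receptor, model),
        accepted_moves=int(accepted),
        pose=best_pose,
        components=components,
    )
    return record, np.asarray(trace)


def peptide_seed(master_seed: int, sequence: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{sequence}".encode()).digest()
    return int.from_bytes(digest[:8], "little") & 0x7FFFFFFFFFFFFFFF


def run_screen(
    receptor: Structure,
    site_map: ActiveSiteMap,
    library: list[Peptide],
    model: EnergyModel,
    params: MCParams,
    template: Structure,
    template_map: ActiveSiteMap | None = None,
    extra_flexible: tuple[int, ...] = (),
    out_path=None,
    progress: bool = False,
) -> list[ScreenRecord]:
    """Run the full peptide library against one receptor.

    Each peptide gets its own deterministic seed derived from the master
    seed and its sequence, so individual runs are reproducible in
    isolation. Failures are recorded (status "failed") without aborting
    the screen; partial results are flushed to ``out_path`` as TSV.
    """
    if not library:
        raise ValueError("peptide library is empty")
    records: list[ScreenRecord] = []
    fh = open(out_path, "w") if out_path else None
    if fh:
        fh.write("peptide\te_bind\td_s2\tn_hb\taccepted_moves\tstatus\n")
    try:
        for k, pep in enumerate(library):
            run_params = replace(params, seed=peptide_seed(params.seed, pep.sequence))
            try:
                pose = place_peptide(
                    pep, receptor, template, site_map, template_map=template_map
                )
                rec, _ = mc_sample(
                    pose, receptor, site_map, model, run_params,
                    extra_flexible=extra_flexible,
                )
            except (PlacementError, KeyError, ValueError) as exc:
                rec = ScreenRecord(
                    peptide=pep, e_bind=float("nan"), d_s2=float("nan"),
                    n_hb=0, accepted_moves=0, pose=None,
                    status=f"failed: {exc}",
                )
            records.append(rec)
            if fh:
                fh.write(
                    f"{rec.peptide.sequence}\t{rec.e_bind:.6f}\t{rec.d_s2:.6f}\t"
                    f"{rec.n_hb}\t{rec.accepted_moves}\t{rec.status}\n"
                )
                fh.flush()
            if progress and (k + 1) % 20 == 0:
                print(f"  screened {k + 1}/{len(library)} peptides")
    finally:
        if fh:
            fh.close()
    return records


def records_to_table(records: list[ScreenRecord]):
    """Screen records as a pandas DataFrame (one row per peptide)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "peptide": [r.peptide.sequence for r in records],
            "p3": [r.peptide.p3 for r in records],
            "p2": [r.peptide.p2 for r in records],
            "e_bind": [r.e_bind for r in records],
            "d_s2": [r.d_s2 for r in records],
            "n_hb": [r.n_hb for r in records],
            "accepted_moves": [r.accepted_moves for r in records],
            "status": [r.status for r in records],
        }
    )
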