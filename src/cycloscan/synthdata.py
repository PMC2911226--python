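"""Synthetic receptors, templates, and perturbations with known ground truth.

The toy receptor is a non-physical scaffold of idealized residues arranged
around a bound Gly-Pro frame: a proline cavity (S1'-like) with a catalytic
arginine stand-in, and an adjacent S2-like channel of configurable depth
whose rim carries the seven gatekeeper-position residues. Residue numbers
reuse the reference (PPIA) positions so the active-site map is the
identity, which keeps every downstream operation exercisable without any
deposited structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import Structure
from .peptide import build_peptide, ideal_residue
from .structures import ActiveSiteMap, REFERENCE_POSITIONS
from .pockets import SurfaceThresholds

#: PPIA-like rim identities by reference position
PPIA_RIM = {
    73: "THR", 81: "GLU", 82: "LYS", 103: "ALA", 107: "THR", 110: "SER", 111: "GLN"
}

_SCAFFOLD_LIMIT = 12.0  # Å, maximum supportable pocket depth


@dataclass
class ScenarioConfig:
    pocket_depth: float = 8.0
    gap_width: float = 10.0
    rim_residues: dict = field(default_factory=lambda: dict(PPIA_RIM))
    favored_p2_class: str = "aromatic"
    seed: int = 0

    def __post_init__(self):
        if self.gap_width <= 0:
            raise ValueError("gap_width must be positive")
        if set(self.rim_residues) != set(PPIA_RIM):
            raise ValueError("rim_residues must cover the 7 rim positions")


@dataclass
class GroundTruth:
    surface_class: str
    favored_p2_class: str
    gap_width: float
    net_charge: int


#: non-ionizable rim for the aromatic-favoring scenario: removes the
#: electrostatic route so pocket burial (sterics) drives the preference
NEUTRAL_RIM = {
    73: "THR", 81: "ALA", 82: "ALA", 103: "ALA", 107: "THR", 110: "SER", 111: "ALA"
}

SCENARIOS = {
    "aromatic-S2": ScenarioConfig(rim_residues=dict(NEUTRAL_RIM)),
    "acidic": ScenarioConfig(
        rim_residues={**PPIA_RIM, 81: "GLU", 82: "ASP", 110: "ASP"},
    ),
    "occluded": ScenarioConfig(
        pocket_depth=8.0, gap_width=3.0,
        rim_residues={**PPIA_RIM, 73: "TYR", 103: "ARG"},
        favored_p2_class="none",
    ),
}


def _oriented_residue(res_name: str, ca_pos, direction):
    """Ideal residue with its CA at ``ca_pos`` and CA->CB along ``direction``."""
    names, elems, coords, _ = ideal_residue(res_name)
    local = {str(n): i for i, n in enumerate(names)}
    ca = coords[local["CA"]]
    ref_atom = local.get("CB", local.get("N"))
    u = coords[ref_atom] - ca
    u = u / np.linalg.norm(u)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    axis = np.cross(u, d)
    s = np.linalg.norm(axis)
    if s < 1e-9:
        rot = np.eye(3) if np.dot(u, d) > 0 else -np.eye(3) + 2 * np.outer(d, d)
    else:
        angle = np.arctan2(s, np.dot(u, d))
        rot = Rotation.from_rotvec(axis / s * angle).as_matrix()
    placed = (coords - ca) @ rot.T + np.asarray(ca_pos, dtype=float)
    return names, elems, placed


def _anchor_glypro():
    """Gly-Pro dipeptide posed in the construction frame.

    Pro CA at the origin, chain running along +x so that P2/P3 of a longer
    peptide extend toward the S2 channel at x ~ 7.6.
    """
    built = build_peptide("GP", res_ids=[9001, 9002])
    s = built.structure
    ca_g = s.coord[s.atom_index(0, "CA")]
    ca_p = s.coord[s.atom_index(1, "CA")]
    x_dir = ca_g - ca_p
    x_dir /= np.linalg.norm(x_dir)
    # orthonormal frame: x along Pro->Gly, z from the Pro sidechain plane
    cb = s.coord[s.atom_index(1, "CB")]
    v = cb - ca_p
    z_dir = v - np.dot(v, x_dir) * x_dir
    z_dir /= np.linalg.norm(z_dir)
    y_dir = np.cross(z_dir, x_dir)
    rot = np.stack([x_dir, y_dir, z_dir])  # rows: new basis
    s.coord = (s.coord - ca_p) @ rot.T
    return built


def make_toy_receptor(config: ScenarioConfig) -> tuple[Structure, GroundTruth]:
    """Deterministic toy receptor with configured rim, gap, and depth."""
    if config.pocket_depth > _SCAFFOLD_LIMIT:
        raise ValueError(
            f"pocket depth {config.pocket_depth} exceeds scaffold limit "
            f"{_SCAFFOLD_LIMIT}"
        )
    rng = np.random.default_rng(config.seed)
    depth = config.pocket_depth
    s2_center = np.array([7.6, 0.0, 0.0])   # x of the P2 position
    residues: list[tuple[int, str, np.ndarray, np.ndarray]] = []

    def add(res_id, res_name, ca_pos, direction):
        residues.append((res_id, res_name, np.asarray(ca_pos, float),
                         np.asarray(direction, float)))

    # S1' pocket ring around the anchored proline (origin), below and aside
    s1_positions = {60: "PHE", 61: "MET", 113: "PHE", 122: "LEU", 126: "HIS"}
    angles = np.linspace(0, 2 * np.pi, len(s1_positions), endpoint=False)
    for (pos, rn), th in zip(sorted(s1_positions.items()), angles):
        ca = np.array([-1.5 + 2.0 * np.cos(th), 7.5 * np.sin(th), -6.0])
        add(pos, rn, ca, np.array([0.0, 0.0, 0.0]) - ca)
    # catalytic arginine stand-in and remaining reference positions,
    # all kept clear of the peptide corridor (x 0..13, |y| < 3, z > -2)
    add(55, "ARG", [-2.5, 10.5, -0.5], [0.2, -1.0, -0.2])
    add(63, "GLN", [-7.0, 6.0, -3.0], [1.0, -0.5, 0.0])
    add(101, "ALA", [-7.0, -6.0, -3.0], [1.0, 0.5, 0.0])
    add(121, "TRP", [-7.0, 0.0, -7.0], [1.0, 0.0, 0.5])

    # S2 rim, one step below the substrate backbone plane: gatekeepers 1/3
    # face each other across the channel mouth (y axis), gatekeeper 2 sits
    # at the far end of the channel (-z)
    rim = config.rim_residues
    mouth_z = -3.0
    add(82, rim[82], s2_center + [0.5, 0.0, -(depth + 3.0)], [0.0, 0.3, 1.0])
    add(73, rim[73], s2_center + [0.0, +8.0, mouth_z], [0.0, -1.0, 0.0])
    add(103, rim[103], s2_center + [0.0, -8.0, mouth_z], [0.0, +1.0, 0.0])
    add(81, rim[81], s2_center + [-2.5, +7.0, -3.5], [0.4, -1.0, -0.3])
    add(107, rim[107], s2_center + [+2.5, +7.0, -3.5], [-0.4, -1.0, -0.3])
    add(110, rim[110], s2_center + [-2.5, -7.0, -3.5], [0.4, +1.0, -0.3])
    add(111, rim[111], s2_center + [+2.5, -7.0, -3.5], [-0.4, +1.0, -0.3])

    # channel walls: alanine rings pointing outward, leaving the bore open
    next_id = 200
    n_rings = max(1, int(round(depth / 2.5)))
    for k in range(n_rings):
        z = -4.5 - (k + 1) * max(depth - 2.5, 1.0) / (n_rings + 1)
        for th in np.linspace(0, 2 * np.pi, 6, endpoint=False) + 0.3 * k:
            ca = s2_center + np.array([5.5 * np.cos(th), 5.5 * np.sin(th), z])
            out_dir = np.array([np.cos(th), np.sin(th), 0.0])
            add(next_id, "ALA", ca + 0.05 * rng.standard_normal(3), out_dir)
            next_id += 1

    # base slab under both pockets (filler to ~60 residues)
    for gx in np.linspace(-8, 12, 6):
        for gy in np.linspace(-9, 9, 5):
            ca = np.array([gx, gy, -depth - 7.5])
            add(next_id, "GLY", ca + 0.05 * rng.standard_normal(3), [0, 0, 1.0])
            next_id += 1

    # assemble, tuning the gatekeeper-1/3 gap to the configured width
    placements = {rid: (rn, ca, dr) for rid, rn, ca, dr in residues}
    gk_sidechains = {}
    for attempt in range(12):
        coords_by_id = {}
        for rid, (rn, ca, dr) in placements.items():
            names, elems, placed = _oriented_residue(rn, ca, dr)
            coords_by_id[rid] = (names, elems, placed)
        sc = {}
        for rid in (73, 103):
            names, _, placed = coords_by_id[rid]
            mask = ~np.isin(names, ("N", "CA", "C", "O"))
            pts = placed[mask] if mask.any() else placed[names == "CA"]
            sc[rid] = pts
        gap = float(cdist(sc[73], sc[103]).min())
        err = gap - config.gap_width
        if abs(err) < 0.05:
            break
        for rid, sgn in ((73, -1.0), (103, +1.0)):
            rn, ca, dr = placements[rid]
            placements[rid] = (rn, ca + np.array([0.0, sgn * err / 2.0, 0.0]), dr)

    atom_name, element, res_id_arr, res_name_arr, coord = [], [], [], [], []
    for rid in sorted(placements):
        names, elems, placed = coords_by_id[rid]
        for j in range(len(names)):
            atom_name.append(str(names[j]))
            element.append(str(elems[j]))
            res_id_arr.append(rid)
            res_name_arr.append(placements[rid][0])
            coord.append(placed[j])

    receptor = Structure(
        id=f"toy-{config.favored_p2_class}",
        chain="A",
        atom_name=np.array(atom_name, dtype="U6"),
        element=np.array(element, dtype="U2"),
        res_id=np.array(res_id_arr, dtype=int),
        res_name=np.array(res_name_arr, dtype="U3"),
        coord=np.array(coord, dtype=np.float64),
    )

    th = SurfaceThresholds()
    from ._aa import FORMAL_CHARGE

    net = sum(FORMAL_CHARGE.get(rn, 0) for rn in config.rim_residues.values())
    if config.gap_width < th.occlusion_gap:
        cls = "occluded"
    elif net <= th.acidic_charge:
        cls = "acidic"
    else:
        cls = "mixed-neutral"
    truth = GroundTruth(
        surface_class=cls,
        favored_p2_class=config.favored_p2_class,
        gap_width=config.gap_width,
        net_charge=net,
    )
    return receptor, truth


def toy_active_site_map(receptor: Structure) -> ActiveSiteMap:
    """Identity active-site map for toy receptors (reference numbering)."""
    entries = {}
    ids = receptor.residue_ids()
    names = receptor.residue_names()
    lookup = {int(i): str(n) for i, n in zip(ids, names)}
    for pos in REFERENCE_POSITIONS:
        if pos in lookup:
            entries[pos] = (lookup[pos], pos)
        else:
            entries[pos] = "unmapped"
    return ActiveSiteMap(entries)


def make_template_complex(config: ScenarioConfig) -> Structure:
    """Toy receptor plus a Gly-Pro dipeptide posed in the S1' cavity."""
    receptor, _ = make_toy_receptor(config)
    anchor = _anchor_glypro().structure
    return Structure(
        id=receptor.id + "-template",
        chain="A",
        atom_name=np.concatenate([receptor.atom_name, anchor.atom_name]),
        element=np.concatenate([receptor.element, anchor.element]),
        res_id=np.concatenate([receptor.res_id, anchor.res_id]),
        res_name=np.concatenate([receptor.res_name, anchor.res_name]),
        coord=np.vstack([receptor.coord, anchor.coord]),
    )


def perturb_structure(
    s: Structure, mode: str = "rigid", sigma: float = 0.5, seed: int = 0
) -> Structure:
    """Rigid random motion, or i.i.d. Gaussian coordinate noise."""
    rng = np.random.default_rng(seed)
    out = s.copy()
    if mode == "rigid":
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-10, 10, size=3)
        out.coord = s.coord @ rot.T + trans
    elif mode == "noise":
        out.coord = s.coord + sigma * rng.standard_normal(s.coord.shape)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return out
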