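"""Tetrapeptide construction with ideal internal geometry.

Residue geometry comes from the chemical component dictionary bundled with
biotite; chains are assembled backbone-first with natural-extension (NeRF)
placement at requested phi/psi, then each residue's sidechain is carried
over by superposing its template backbone. Termini are left neutral (no
OXT / charged amine): the tetrapeptides model interior substrate windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from ._aa import CHI_ATOMS, three_letter
from .core import Structure

# standard backbone geometry (Engh & Huber-like)
BOND_C_N = 1.329
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_O = 1.231
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

#: default extended-backbone torsions for flexible residues
EXTENDED_PHI = -140.0
EXTENDED_PSI = 135.0


@lru_cache(maxsize=None)
def ideal_residue(res_name: str):
    """Heavy-atom template for a residue: (names, elements, coords, bonds).

    ``bonds`` is a list of (i, j) index pairs into the heavy-atom arrays.
    OXT is dropped so residues can be chained.
    """
    tpl = struc_info.residue(res_name)
    if tpl is None:
        raise ValueError(f"no ideal template for residue {res_name!r}")
    keep = (tpl.element != "H") & (tpl.atom_name != "OXT")
    idx_map = {}
    names, elements, coords = [], [], []
    for new, old in enumerate(np.flatnonzero(keep)):
        idx_map[int(old)] = new
        names.append(str(tpl.atom_name[old]))
        elements.append(str(tpl.element[old]).upper())
        coords.append(tpl.coord[old])
    bonds = []
    for i, j, _ in tpl.bonds.as_array():
        if int(i) in idx_map and int(j) in idx_map:
            bonds.append((idx_map[int(i)], idx_map[int(j)]))
    return (
        np.array(names, dtype="U6"),
        np.array(elements, dtype="U2"),
        np.array(coords, dtype=np.float64),
        bonds,
    )


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position atom d given chain a-b-c, |cd|, angle(bcd), dihedral(abcd)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def rotate_coords(coords, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points about an axis through ``origin`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = axis
    v = np.asarray(coords, dtype=float) - origin
    rot = (
        v * np.cos(th)
        + np.cross(k, v) * np.sin(th)
        + np.outer(v @ k, k) * (1 - np.cos(th))
    )
    return rot + origin


@dataclass
class TorsionDef:
    """A rotatable torsion: dihedral quadruple plus the atoms that move.

    ``moving`` atoms are rotated about the j->k axis; a positive rotation
    increases the measured dihedral when the moving set is on the l side
    and decreases it when on the i side (``sign`` records this).
    """

    name: str
    atoms: tuple[int, int, int, int]   # global atom indices (i, j, k, l)
    moving: np.ndarray                 # global atom indices rotated by the move
    sign: float                        # +1 if moving set is on the l side

    def value(self, coords: np.ndarray) -> float:
        i, j, k, l = self.atoms
        return dihedral(coords[i], coords[j], coords[k], coords[l])

    def rotate(self, coords: np.ndarray, delta_deg: float) -> None:
        """Rotate in place so the measured dihedral changes by ``delta_deg``."""
        i, j, k, l = self.atoms
        axis = coords[k] - coords[j]
        coords[self.moving] = rotate_coords(
            coords[self.moving], coords[j], axis, self.sign * delta_deg
        )

    def set_value(self, coords: np.ndarray, target_deg: float) -> None:
        delta = target_deg - self.value(coords)
        self.rotate(coords, delta)


def _component(adjacency: dict[int, set[int]], start: int, cut: tuple[int, int]) -> set[int]:
    """Connected component containing ``start`` with one bond removed."""
    a, b = cut
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adjacency.get(u, ()):
            if {u, v} == {a, b}:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def build_adjacency(bonds) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    return adj


def bond_distance_matrix(n_atoms: int, bonds, max_depth: int = 3) -> np.ndarray:
    """Bond-count separation up to ``max_depth`` (beyond -> max_depth + 1)."""
    adj = build_adjacency(bonds)
    out = np.full((n_atoms, n_atoms), max_depth + 1, dtype=np.int8)
    for s in range(n_atoms):
        out[s, s] = 0
        frontier = [s]
        for depth in range(1, max_depth + 1):
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if out[s, v] > depth:
                        out[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return out


@dataclass
class BuiltPeptide:
    """A constructed peptide: structure plus its bond graph and torsions."""

    structure: Structure
    bonds: list[tuple[int, int]]
    residue_atom_offsets: list[int]

    def chi_torsions(self, residue_index: int) -> list[TorsionDef]:
        """Sidechain chi torsions of one residue (distal atoms move)."""
        s = self.structure
        res_name = str(s.residue_names()[residue_index])
        adj = build_adjacency(self.bonds)
        torsions = []
        for ci, quad in enumerate(CHI_ATOMS.get(res_name, [])):
            try:
                idx = tuple(s.atom_index(residue_index, nm) for nm in quad)
            except KeyError:
                continue
            moving = _component(adj, idx[3], (idx[1], idx[2])) - {idx[2]}
            torsions.append(
                TorsionDef(
                    name=f"chi{ci + 1}:{res_name}{residue_index}",
                    atoms=idx,
                    moving=np.array(sorted(moving), dtype=int),
                    sign=+1.0,
                )
            )
        return torsions

    def backbone_torsions(self, residue_index: int) -> list[TorsionDef]:
        """Phi/psi of one residue, rotating the N-terminal side of the bond.

        Keeping the C-terminal side fixed means the anchored Gly-Pro of a
        docked pose never moves under these torsions.
        """
        s = self.structure
        adj = build_adjacency(self.bonds)
        out = []
        n_res = s.n_residues
        # phi: C(i-1)-N-CA-C ; the quadruple needs the previous residue's C,
        # except for the first residue where a pseudo-phi over (O? no) is skipped
        try:
            n_i = s.atom_index(residue_index, "N")
            ca_i = s.atom_index(residue_index, "CA")
            c_i = s.atom_index(residue_index, "C")
        except KeyError:
            return out
        if residue_index > 0:
            c_prev = s.atom_index(residue_index - 1, "C")
            moving = _component(adj, c_prev, (n_i, ca_i)) - {n_i}
            out.append(
                TorsionDef(
                    name=f"phi:{residue_index}",
                    atoms=(c_prev, n_i, ca_i, c_i),
                    moving=np.array(sorted(moving | {c_prev} - {ca_i}), dtype=int),
                    sign=-1.0,
                )
            )
        if residue_index < n_res - 1:
            n_next = s.atom_index(residue_index + 1, "N")
            moving = _component(adj, n_i, (ca_i, c_i)) - {ca_i}
            out.append(
                TorsionDef(
                    name=f"psi:{residue_index}",
                    atoms=(n_i, ca_i, c_i, n_next),
                    moving=np.array(sorted(moving), dtype=int),
                    sign=-1.0,
                )
            )
        return out


def build_peptide(
    sequence: str,
    phi: dict[int, float] | None = None,
    psi: dict[int, float] | None = None,
    res_ids: list[int] | None = None,
    label: str | None = None,
) -> BuiltPeptide:
    """Build a peptide from a one-letter sequence with ideal geometry.

    ``phi``/``psi`` override the extended-conformation defaults per residue
    (0-based index). Proline phi defaults to -75 regardless.
    """
    phi = dict(phi or {})
    psi = dict(psi or {})
    seq3 = [three_letter(c) for c in sequence]
    n = len(seq3)
    if res_ids is None:
        res_ids = list(range(1, n + 1))

    all_names: list[str] = []
    all_elems: list[str] = []
    all_resid: list[int] = []
    all_resname: list[str] = []
    coords_out: list[np.ndarray] = []
    bonds_out: list[tuple[int, int]] = []
    offsets: list[int] = []
    backbone_pos: list[dict[str, np.ndarray]] = []

    def res_phi(i):
        if i in phi:
            return phi[i]
        return -75.0 if seq3[i] == "PRO" else EXTENDED_PHI

    def res_psi(i):
        return psi.get(i, EXTENDED_PSI)

    offset = 0
    for i, rn in enumerate(seq3):
        names, elems, tcoord, tbonds = ideal_residue(rn)
        name_to_local = {nm: j for j, nm in enumerate(names)}
        t_n = tcoord[name_to_local["N"]]
        t_ca = tcoord[name_to_local["CA"]]
        t_c = tcoord[name_to_local["C"]]
        if i == 0:
            bb = {"N": t_n, "CA": t_ca, "C": t_c}
            rot = np.eye(3)
            trans = np.zeros(3)
        else:
            prev = backbone_pos[-1]
            n_i = place_atom(
                prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, res_psi(i - 1)
            )
            ca_i = place_atom(
                prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS
            )
            c_i = place_atom(
                prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, res_phi(i)
            )
            bb = {"N": n_i, "CA": ca_i, "C": c_i}
            # rigid transform of the template onto the built backbone triad
            from .structures import kabsch_superpose  # local import, no cycle at runtime

            sup = kabsch_superpose(
                np.stack([n_i, ca_i, c_i]), np.stack([t_n, t_ca, t_c])
            )
            rot, trans = sup.rotation, sup.translation
        placed = tcoord @ rot.T + trans
        for nm in ("N", "CA", "C"):
            placed[name_to_local[nm]] = bb[nm]
        backbone_pos.append(bb)

        offsets.append(offset)
        for j, nm in enumerate(names):
            all_names.append(nm)
            all_elems.append(elems[j])
            all_resid.append(res_ids[i])
            all_resname.append(rn)
            coords_out.append(placed[j])
        for bi, bj in tbonds:
            bonds_out.append((offset + bi, offset + bj))
        if i > 0:
            bonds_out.append(
                (offsets[i - 1] + prev_c_local, offset + name_to_local["N"])
            )
        prev_c_local = name_to_local["C"]
        prev_o_index = offset + name_to_local["O"] if "O" in name_to_local else None
        offset += len(names)

    built = BuiltPeptide(
        structure=Structure(
            id=label or sequence,
            chain="P",
            atom_name=np.array(all_names, dtype="U6"),
            element=np.array(all_elems, dtype="U2"),
            res_id=np.array(all_resid, dtype=int),
            res_name=np.array(all_resname, dtype="U3"),
            coord=np.array(coords_out, dtype=np.float64),
        ),
        bonds=bonds_out,
        residue_atom_offsets=offsets,
    )

    # re-place carbonyl O anti to the next residue's N (consistent with psi)
    s = built.structure
    for i in range(n - 1):
        try:
            o_idx = s.atom_index(i, "O")
        except KeyError:
            continue
        n_i = s.coord[s.atom_index(i, "N")]
        ca_i = s.coord[s.atom_index(i, "CA")]
        c_i = s.coord[s.atom_index(i, "C")]
        s.coord[o_idx] = place_atom(
            n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, res_psi(i) + 180.0
        )
    return built
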