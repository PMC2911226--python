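"""Domain comparison: sequence alignment, superposition, residue mapping.

Cross-isoform semantics always go through :class:`ActiveSiteMap` (reference
positions in PPIA numbering); raw author numbers are never compared between
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from ._aa import BACKBONE_ATOMS
from .core import Structure

#: reference (PPIA-numbering) active-site positions: catalytic + gatekeepers
REFERENCE_POSITIONS = (
    55, 60, 61, 63, 73, 81, 82, 101, 103, 107, 110, 111, 113, 121, 122, 126,
)
GATEKEEPER_POSITIONS = {"gk1": 73, "gk2": 82, "gk3": 103}

#: S2-rim subset of the reference positions
RIM_POSITIONS = (73, 81, 82, 103, 107, 110, 111)

#: loop windows in PPIA numbering: beta1-beta2, alpha1-beta3, alpha2-beta8
LOOP_WINDOWS = {"b1b2": (11, 16), "a1b3": (41, 50), "a2b8": (146, 155)}

UNMAPPED = "unmapped"


@dataclass
class DomainAlignment:
    """Residue-level pairing between two domains from a global alignment."""

    pairs: np.ndarray            # (m, 2) int: residue indices in (a, b)
    identity_fraction: float     # identical residue names over aligned columns
    coverage: float              # fraction of a's residues aligned

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs) > 1:
            d = np.diff(self.pairs, axis=0)
            if np.any(d <= 0):
                raise ValueError("alignment pairs must be strictly increasing")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction outside [0, 1]")

    def partner_of_a(self, a_index: int) -> int | None:
        hits = np.flatnonzero(self.pairs[:, 0] == a_index)
        return int(self.pairs[hits[0], 1]) if len(hits) else None

    @classmethod
    def identity(cls, structure: Structure) -> "DomainAlignment":
        n = structure.n_residues
        idx = np.arange(n)
        return cls(np.stack([idx, idx], axis=1), 1.0, 1.0)


@dataclass
class Superposition:
    rotation: np.ndarray     # (3, 3) proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float              # Å over the matched set
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class ActiveSiteMap:
    """PPIA reference position -> (residue name, author number) in a target."""

    entries: dict[int, tuple[str, int] | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(REFERENCE_POSITIONS) - set(self.entries)
        if missing:
            raise ValueError(f"reference positions absent from map: {sorted(missing)}")

    def __getitem__(self, position: int):
        return self.entries[position]

    def is_mapped(self, position: int) -> bool:
        return self.entries[position] != UNMAPPED

    def residue_name(self, position: int) -> str:
        e = self.entries[position]
        if e == UNMAPPED:
            raise KeyError(f"reference position {position} is unmapped")
        return e[0]

    def residue_number(self, position: int) -> int:
        e = self.entries[position]
        if e == UNMAPPED:
            raise KeyError(f"reference position {position} is unmapped")
        return e[1]

    def as_rows(self):
        for pos in REFERENCE_POSITIONS:
            e = self.entries[pos]
            if e == UNMAPPED:
                yield pos, UNMAPPED, ""
            else:
                yield pos, e[0], e[1]


@dataclass
class LoopClassification:
    b1b2: str  # full-length | deleted | unclassifiable
    a1b3: str  # PPIA-class | short | long | unclassifiable
    a2b8: str  # standard | alternate | unclassifiable


# ---------------------------------------------------------------------------


def align_sequences(
    a: Structure,
    b: Structure,
    gap_penalty: tuple[int, int] = (-10, -1),
) -> DomainAlignment:
    """Global alignment (affine gaps, BLOSUM62, free terminal gaps)."""
    if a.n_residues == 0 or b.n_residues == 0:
        raise ValueError("cannot align an empty structure")
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    seq_a = bseq.ProteinSequence(a.sequence().replace("X", "A"))
    seq_b = bseq.ProteinSequence(b.sequence().replace("X", "A"))
    aln = balign.align_optimal(
        seq_a, seq_b, matrix, gap_penalty=gap_penalty, terminal_penalty=False
    )[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    pairs = trace[both]
    names_a = a.residue_names()
    names_b = b.residue_names()
    ident = float(np.mean(names_a[pairs[:, 0]] == names_b[pairs[:, 1]])) if len(pairs) else 0.0
    coverage = len(pairs) / a.n_residues
    return DomainAlignment(pairs, ident, coverage)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rigid transform of ``b`` onto ``a`` (Kabsch).

    Reflections are excluded by sign-correcting the smallest singular
    direction, so the returned rotation always has determinant +1.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise ValueError("at least 3 atoms required for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(a))


def matched_coordinates(
    a: Structure,
    b: Structure,
    alignment: DomainAlignment,
    atom_set: str = "all",
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Coordinates of atoms shared (by name) between aligned residue pairs."""
    if atom_set not in ("all", "ca"):
        raise ValueError("atom_set must be 'all' or 'ca'")
    idx_a: list[int] = []
    idx_b: list[int] = []
    for ia, ib in alignment.pairs:
        sl_a = a.residue_slice(int(ia))
        sl_b = b.residue_slice(int(ib))
        names_a = a.atom_name[sl_a]
        names_b = b.atom_name[sl_b]
        wanted = ("CA",) if atom_set == "ca" else names_a
        for name in wanted:
            ja = np.flatnonzero(names_a == name)
            jb = np.flatnonzero(names_b == name)
            if len(ja) and len(jb):
                idx_a.append(sl_a.start + int(ja[0]))
                idx_b.append(sl_b.start + int(jb[0]))
    return a.coord[idx_a], b.coord[idx_b], list(zip(idx_a, idx_b))


def superpose_domains(
    a: Structure,
    b: Structure,
    alignment: DomainAlignment,
    atom_set: str = "all",
) -> Superposition:
    """Superpose ``b`` onto ``a`` over atoms shared by aligned residue pairs."""
    if len(alignment.pairs) == 0:
        raise ValueError("empty alignment")
    ca_, cb_, matched = matched_coordinates(a, b, alignment, atom_set)
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} matchable atoms; need >= 3")
    return kabsch_superpose(ca_, cb_)


def map_active_site(
    target: Structure,
    ref: Structure,
    alignment: DomainAlignment,
    positions=REFERENCE_POSITIONS,
) -> ActiveSiteMap:
    """Map PPIA reference positions onto a target via a residue alignment.

    ``alignment`` must be ``align_sequences(ref, target)`` (reference first).
    """
    entries: dict[int, tuple[str, int] | str] = {}
    target_ids = target.residue_ids()
    target_names = target.residue_names()
    for pos in positions:
        try:
            ref_index = ref.residue_index(pos)
        except KeyError:
            raise KeyError(
                f"reference structure lacks residue {pos}"
            ) from None
        partner = alignment.partner_of_a(ref_index)
        if partner is None:
            entries[pos] = UNMAPPED
        else:
            entries[pos] = (str(target_names[partner]), int(target_ids[partner]))
    return ActiveSiteMap(entries)


def classify_position121(site_map: ActiveSiteMap) -> tuple[str, str]:
    """CsA-competence label for the position-121 residue.

    Returns ``(label, note)`` with label in {permissive, non-permissive}.
    """
    name = site_map.residue_name(121)
    if name in ("TRP", "HIS"):
        return "permissive", ""
    if name in ("TYR", "GLU"):
        return "non-permissive", ""
    return "non-permissive", "novel residue"


def _window_indices(ref: Structure, lo: int, hi: int) -> np.ndarray:
    ids = ref.residue_ids()
    return np.flatnonzero((ids >= lo) & (ids <= hi))


def classify_loops(
    target: Structure,
    ref: Structure,
    alignment: DomainAlignment,
    a2b8_rmsd_cutoff: float = 1.5,
) -> LoopClassification:
    """Assign the three loop-region class labels relative to the reference.

    beta1-beta2 is "deleted" when >= 2 reference window residues have no
    target partner; alpha1-beta3 is labelled by target loop length relative
    to the reference window; alpha2-beta8 is "standard" when its backbone
    RMSD after whole-domain superposition is within ``a2b8_rmsd_cutoff``.
    """
    # beta1-beta2 deletion
    lo, hi = LOOP_WINDOWS["b1b2"]
    win = _window_indices(ref, lo, hi)
    if len(win) == 0:
        b1b2 = "unclassifiable"
    else:
        gaps = sum(1 for i in win if alignment.partner_of_a(int(i)) is None)
        if gaps == len(win):
            b1b2 = "unclassifiable"
        else:
            b1b2 = "deleted" if gaps >= 2 else "full-length"

    # alpha1-beta3 length class
    lo, hi = LOOP_WINDOWS["a1b3"]
    win = _window_indices(ref, lo, hi)
    a1b3 = "unclassifiable"
    if len(win) > 0:
        aligned_in = [alignment.partner_of_a(int(i)) for i in win]
        if any(p is not None for p in aligned_in):
            # flanking anchors: nearest aligned ref residues outside the window
            before = [alignment.partner_of_a(i) for i in range(int(win[0]) - 1, -1, -1)]
            after = [
                alignment.partner_of_a(i) for i in range(int(win[-1]) + 1, ref.n_residues)
            ]
            t_lo = next((p for p in before if p is not None), None)
            t_hi = next((p for p in after if p is not None), None)
            if t_lo is not None and t_hi is not None:
                target_len = t_hi - t_lo - 1
                ref_len = len(win)
                if target_len == ref_len:
                    a1b3 = "PPIA-class"
                elif target_len < ref_len:
                    a1b3 = "short"
                else:
                    a1b3 = "long"

    # alpha2-beta8 conformation class
    lo, hi = LOOP_WINDOWS["a2b8"]
    win = set(int(i) for i in _window_indices(ref, lo, hi))
    a2b8 = "unclassifiable"
    loop_pairs = [p for p in alignment.pairs if int(p[0]) in win]
    if loop_pairs:
        sup = superpose_domains(ref, target, alignment, atom_set="all")
        moved = sup.apply(target.coord)
        deltas = []
        for ia, ib in loop_pairs:
            sl_a = ref.residue_slice(int(ia))
            sl_b = target.residue_slice(int(ib))
            for name in BACKBONE_ATOMS:
                ja = np.flatnonzero(ref.atom_name[sl_a] == name)
                jb = np.flatnonzero(target.atom_name[sl_b] == name)
                if len(ja) and len(jb):
                    d = moved[sl_b.start + jb[0]] - ref.coord[sl_a.start + ja[0]]
                    deltas.append(d)
        if deltas:
            rmsd = float(np.sqrt(np.mean(np.sum(np.square(deltas), axis=1))))
            a2b8 = "standard" if rmsd <= a2b8_rmsd_cutoff else "alternate"

    return LoopClassification(b1b2=b1b2, a1b3=a1b3, a2b8=a2b8)
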