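"""Core structure model shared by all pipeline stages.

A :class:`Structure` is a flat, array-backed view of one polypeptide chain
(or chain slice): parallel numpy arrays over atoms plus residue bookkeeping.
It deliberately carries no crystallographic metadata beyond what the
pipeline needs (names, elements, residue numbering, coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa import BACKBONE_ATOMS, STANDARD_AA3, one_letter


class StructureError(ValueError):
    """Raised for malformed or inconsistent structure data."""


@dataclass
class Structure:
    """One chain (or slice) of a structure as parallel per-atom arrays."""

    id: str
    chain: str
    atom_name: np.ndarray  # (n,) str
    element: np.ndarray    # (n,) str, upper-case
    res_id: np.ndarray     # (n,) int, author numbering
    res_name: np.ndarray   # (n,) str, 3-letter code
    coord: np.ndarray      # (n, 3) float64, Å
    het_flags: np.ndarray | None = None  # (n,) bool, True for flagged heteroresidues

    # residue index caches, built lazily
    _res_starts: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=np.float64)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise StructureError("coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        n = len(self.coord)
        for name in ("atom_name", "element", "res_id", "res_name"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise StructureError(f"array length mismatch for {name}")
            setattr(self, name, arr)
        starts = self.residue_starts()
        rid = self.res_id[starts]
        if np.any(np.diff(rid) <= 0):
            raise StructureError("residue numbers must be strictly increasing")

    # -- residue-level views -------------------------------------------------

    def residue_starts(self) -> np.ndarray:
        if self._res_starts is None:
            if len(self.res_id) == 0:
                self._res_starts = np.array([], dtype=int)
                return self._res_starts
            change = np.empty(len(self.res_id), dtype=bool)
            change[0] = True
            change[1:] = self.res_id[1:] != self.res_id[:-1]
            self._res_starts = np.flatnonzero(change)
        return self._res_starts

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts())

    def residue_ids(self) -> np.ndarray:
        return self.res_id[self.residue_starts()]

    def residue_names(self) -> np.ndarray:
        return self.res_name[self.residue_starts()]

    def residue_slice(self, index: int) -> slice:
        """Atom slice of the residue at positional ``index``."""
        starts = self.residue_starts()
        lo = starts[index]
        hi = starts[index + 1] if index + 1 < len(starts) else self.n_atoms
        return slice(lo, hi)

    def residue_index(self, res_id: int) -> int:
        """Positional index of the residue with author number ``res_id``."""
        ids = self.residue_ids()
        hits = np.flatnonzero(ids == res_id)
        if len(hits) == 0:
            raise KeyError(f"residue {res_id} not present in {self.id}")
        return int(hits[0])

    def atom_index(self, index: int, atom_name: str) -> int:
        """Global index of the named atom in residue ``index``; KeyError if absent."""
        sl = self.residue_slice(index)
        hits = np.flatnonzero(self.atom_name[sl] == atom_name)
        if len(hits) == 0:
            rid = self.residue_ids()[index]
            raise KeyError(f"atom {atom_name} absent in residue {rid} of {self.id}")
        return sl.start + int(hits[0])

    def sequence(self) -> str:
        """One-letter sequence over residues; unknown residues become 'X'."""
        return "".join(one_letter(n) for n in self.residue_names())

    def sidechain_mask(self, index: int) -> np.ndarray:
        """Global indices of sidechain heavy atoms (Gly: CA) of residue ``index``."""
        sl = self.residue_slice(index)
        names = self.atom_name[sl]
        mask = ~np.isin(names, BACKBONE_ATOMS)
        idx = np.arange(sl.start, sl.stop)[mask]
        if len(idx) == 0:  # glycine: use CA as stand-in
            idx = np.array([self.atom_index(index, "CA")])
        return idx

    # -- geometry ------------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        out = self.copy()
        out.coord = self.coord @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def copy(self) -> "Structure":
        return Structure(
            id=self.id, chain=self.chain,
            atom_name=self.atom_name.copy(), element=self.element.copy(),
            res_id=self.res_id.copy(), res_name=self.res_name.copy(),
            coord=self.coord.copy(),
            het_flags=None if self.het_flags is None else self.het_flags.copy(),
        )

    def extract_residues(self, indices) -> "Structure":
        """Sub-structure containing the residues at the given positional indices."""
        keep = np.concatenate(
            [np.arange(self.residue_slice(i).start, self.residue_slice(i).stop)
             for i in indices]
        ) if len(indices) else np.array([], dtype=int)
        return Structure(
            id=self.id, chain=self.chain,
            atom_name=self.atom_name[keep], element=self.element[keep],
            res_id=self.res_id[keep], res_name=self.res_name[keep],
            coord=self.coord[keep],
            het_flags=None if self.het_flags is None else self.het_flags[keep],
        )

    def is_standard(self) -> np.ndarray:
        """Per-residue bool: residue name is a standard amino acid."""
        return np.isin(self.residue_names(), sorted(STANDARD_AA3))
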