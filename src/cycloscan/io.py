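"""Reading and writing structure files (PDB / mmCIF via biotite)."""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx

from .core import Structure, StructureError


class ChainNotFoundError(KeyError):
    pass


class FormatError(ValueError):
    pass


def _looks_like_cif(text: str) -> bool:
    head = text.lstrip()[:500]
    return head.startswith("data_") or "_atom_site." in head


def _load_atom_array(source: str | Path, model: int = 1) -> struc.AtomArray:
    """Parse PDB/mmCIF text or a file path into a biotite AtomArray.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc identifier order, biotite's default). For NMR
    ensembles the requested model (default: first) is used.
    """
    path_hint = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        path_hint = Path(source)
        text = path_hint.read_text()
    else:
        text = str(source)

    is_cif = _looks_like_cif(text)
    if path_hint is not None and path_hint.suffix.lower() in (".cif", ".mmcif"):
        is_cif = True
    try:
        if is_cif:
            f = pdbx.CIFFile.read(_io.StringIO(text))
            arr = pdbx.get_structure(f, model=model, altloc="occupancy")
        else:
            f = pdb.PDBFile.read(_io.StringIO(text))
            arr = pdb.get_structure(f, model=model, altloc="occupancy")
    except Exception as exc:  # surface the offending record, not a traceback
        raise FormatError(f"cannot parse structure source: {exc}") from exc
    return arr


def read_structure(
    source: str | Path,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    model: int = 1,
    include_het: bool = False,
    id: str | None = None,
) -> Structure:
    """Read one chain (optionally a residue span) from PDB or mmCIF input.

    Parameters
    ----------
    source
        File path, or raw PDB/mmCIF text.
    chain
        Chain identifier; defaults to the first chain in the file.
    residue_range
        Inclusive ``(first, last)`` author residue numbers to retain.
    model
        Model number for multi-model (NMR) entries; 1-based.
    include_het
        If True, heteroresidues (ligands, modified residues) are kept and
        flagged; waters are always discarded.
    """
    arr = _load_atom_array(source, model=model)
    if chain is None:
        chain = str(arr.chain_id[0])
    mask = arr.chain_id == chain
    if not mask.any():
        raise ChainNotFoundError(f"chain not found: {chain!r}")
    arr = arr[mask]
    arr = arr[arr.res_name != "HOH"]
    if not include_het:
        arr = arr[~arr.hetero | (arr.res_name == "MSE")]
    arr = arr[arr.element != "H"]
    if residue_range is not None:
        lo, hi = residue_range
        arr = arr[(arr.res_id >= lo) & (arr.res_id <= hi)]
    if arr.array_length() == 0:
        raise StructureError("no atoms selected")
    return Structure(
        id=id or getattr(source, "stem", None) or "structure",
        chain=chain,
        atom_name=arr.atom_name.astype("U6"),
        element=np.char.upper(arr.element.astype("U2")),
        res_id=arr.res_id.astype(int),
        res_name=arr.res_name.astype("U3"),
        coord=arr.coord.astype(np.float64),
        het_flags=arr.hetero.astype(bool),
    )


def to_atom_array(s: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coord.astype(np.float32)
    arr.chain_id = np.full(s.n_atoms, s.chain[:4] or "A")
    arr.res_id = s.res_id
    arr.res_name = s.res_name
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.hetero = (
        s.het_flags if s.het_flags is not None else np.zeros(s.n_atoms, dtype=bool)
    )
    return arr


def write_pdb(path: str | Path, *structures: Structure) -> None:
    """Write structures as models of one PDB file.

    Models may have different atom contents (e.g. best poses of different
    peptides), so each model's records are emitted independently.
    """
    if len(structures) == 1:
        f = pdb.PDBFile()
        f.set_structure(to_atom_array(structures[0]))
        f.write(str(path))
        return
    chunks = []
    for k, s in enumerate(structures, start=1):
        f = pdb.PDBFile()
        f.set_structure(to_atom_array(s))
        body = "\n".join(
            line for line in f.lines if line.startswith(("ATOM", "HETATM"))
        )
        chunks.append(f"MODEL     {k:>4}\n{body}\nENDMDL")
    Path(path).write_text("\n".join(chunks) + "\nEND\n")


def write_fasta(path: str | Path, entries: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
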