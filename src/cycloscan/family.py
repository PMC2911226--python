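"""Family-wide comparison against the PPIA reference structure.

Utilities to run the vs-reference RMSD / identity / surface-class analysis
over a directory of locally stored deposited structures. Files are looked
up as ``<accession>.pdb`` or ``<accession>.cif`` (lower case).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core import Structure
from .io import read_structure
from .pockets import SurfaceClass, classify_surface
from .structures import align_sequences, map_active_site, superpose_domains

#: reference entry (PPIA)
REFERENCE_ACCESSION = "2CPL"

#: experimentally determined PPIase-domain entries compared against PPIA
FAMILY_ACCESSIONS = {
    "2CPL": "PPIA",
    "2R99": "PPIB",
    "2ESL": "PPIC",
    "2GW2": "PPIE",
    "2BIT": "PPIF",
    "2HQ6": "PPIG",
    "1QOI": "PPIH",
    "1XWN": "PPIL1",
    "1ZKC": "PPIL2",
    "1CYN": "PPIL3",
    "2A2N": "PPWD1",
    "2HE9": "NKTR",
    "2OK3": "SDCCAG10",
}

#: entries whose deposited asymmetric unit needs a specific chain or model
READ_OPTIONS = {
    "1XWN": {"model": 1},  # NMR ensemble: first model
}


@dataclass
class FamilyComparison:
    accession: str
    isoform: str
    rmsd: float
    n_atoms: int
    identity_percent: float
    coverage: float


def load_family_structure(directory: str | Path, accession: str) -> Structure:
    directory = Path(directory)
    for ext in (".pdb", ".cif"):
        p = directory / f"{accession.lower()}{ext}"
        if p.exists():
            opts = READ_OPTIONS.get(accession.upper(), {})
            return read_structure(p, id=accession.upper(), **opts)
    raise FileNotFoundError(
        f"structure {accession} not found under {directory} "
        f"(expected {accession.lower()}.pdb or .cif)"
    )


def compare_to_reference(
    directory: str | Path,
    accessions=None,
    reference: str = REFERENCE_ACCESSION,
) -> list[FamilyComparison]:
    """All-heavy-atom RMSD and sequence identity of each entry vs PPIA."""
    accessions = accessions or [
        a for a in FAMILY_ACCESSIONS if a != reference
    ]
    ref = load_family_structure(directory, reference)
    out = []
    for acc in accessions:
        target = load_family_structure(directory, acc)
        aln = align_sequences(ref, target)
        sup = superpose_domains(ref, target, aln, atom_set="all")
        out.append(
            FamilyComparison(
                accession=acc.upper(),
                isoform=FAMILY_ACCESSIONS.get(acc.upper(), acc.upper()),
                rmsd=sup.rmsd,
                n_atoms=sup.n_atoms,
                identity_percent=100.0 * aln.identity_fraction,
                coverage=aln.coverage,
            )
        )
    return out


def surface_class_for(
    directory: str | Path, accession: str, reference: str = REFERENCE_ACCESSION
) -> SurfaceClass:
    ref = load_family_structure(directory, reference)
    target = load_family_structure(directory, accession)
    aln = align_sequences(ref, target)
    site_map = map_active_site(target, ref, aln)
    return classify_surface(target, site_map)
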