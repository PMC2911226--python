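"""S1'/S2 pocket quantification and gatekeeper-surface classification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._aa import FORMAL_CHARGE
from .core import Structure
from .structures import ActiveSiteMap, RIM_POSITIONS

#: S1' pocket positions (PPIA numbering): base 113 plus pocket sides
S1PRIME_POSITIONS = (60, 61, 113, 122, 126)


@dataclass
class SurfaceThresholds:
    """Decision thresholds for the three-way surface classification.

    Neither value is printed in the source analysis; defaults were chosen
    to reproduce the published class memberships and are configurable.
    """

    occlusion_gap: float = 5.5   # Å; below this the S2 pocket counts as occluded
    acidic_charge: int = -2      # net rim formal charge at or below -> acidic


@dataclass
class SurfaceClass:
    label: str                 # mixed-neutral | acidic | occluded
    net_formal_charge: int
    gap_width: float           # Å, gatekeeper-1 to gatekeeper-3 closest approach


def gatekeeper_gap(target: Structure, site_map: ActiveSiteMap) -> float:
    """Closest heavy-atom approach (Å) between gatekeeper-1 and gatekeeper-3
    sidechains (Cα stands in for glycine)."""
    idx = []
    for pos in (73, 103):
        if not site_map.is_mapped(pos):
            raise KeyError(f"gatekeeper position {pos} is unmapped")
        res_index = target.residue_index(site_map.residue_number(pos))
        atoms = target.sidechain_mask(res_index)
        if len(atoms) == 0:
            raise ValueError(f"no sidechain atoms for gatekeeper at position {pos}")
        idx.append(atoms)
    d = cdist(target.coord[idx[0]], target.coord[idx[1]])
    return float(d.min())


def rim_formal_charge(site_map: ActiveSiteMap) -> int:
    """Net formal sidechain charge over the seven S2-rim positions at pH 7."""
    total = 0
    for pos in RIM_POSITIONS:
        if not site_map.is_mapped(pos):
            warnings.warn(f"rim position {pos} unmapped; counted as 0", stacklevel=2)
            continue
        total += FORMAL_CHARGE.get(site_map.residue_name(pos), 0)
    return total


def classify_surface(
    target: Structure,
    site_map: ActiveSiteMap,
    thresholds: SurfaceThresholds | None = None,
) -> SurfaceClass:
    """Three-way S2-rim surface class; occlusion is tested before acidity."""
    th = thresholds or SurfaceThresholds()
    gap = gatekeeper_gap(target, site_map)
    charge = rim_formal_charge(site_map)
    if gap < th.occlusion_gap:
        label = "occluded"
    elif charge <= th.acidic_charge:
        label = "acidic"
    else:
        label = "mixed-neutral"
    return SurfaceClass(label=label, net_formal_charge=charge, gap_width=gap)
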