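"""Specificity arrays, rankings, and chemistry-class summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import STANDARD_AA1
from .screen import ScreenRecord

#: chemistry classes used for margin summaries (His -> basic, Cys -> polar)
DEFAULT_CLASSES = {
    "acidic": ("D", "E"),
    "basic": ("K", "R", "H"),
    "aromatic": ("F", "W", "Y"),
    "aliphatic-small": ("G", "A", "V", "L", "I", "P", "M"),
    "polar": ("S", "T", "C", "N", "Q"),
}


def validate_classes(classes: dict) -> None:
    seen = [aa for group in classes.values() for aa in group]
    if len(seen) != len(set(seen)):
        raise ValueError("chemistry classes overlap")
    if set(seen) != set(STANDARD_AA1):
        raise ValueError("chemistry classes must partition the 20 amino acids")


@dataclass
class SpecificityArray:
    """P3 (x) by P2 (y) grid of screen metrics."""

    table: pd.DataFrame          # index p2, columns p3, plus companion tables
    e_bind: pd.DataFrame
    d_s2: pd.DataFrame
    n_hb: pd.DataFrame
    e_min: float
    e_max: float
    alphabet: str = STANDARD_AA1

    def cell(self, p3: str, p2: str) -> dict:
        return {
            "e_bind": float(self.e_bind.at[p2, p3]),
            "d_s2": float(self.d_s2.at[p2, p3]),
            "n_hb": int(self.n_hb.at[p2, p3]),
        }


def build_array(
    records: list[ScreenRecord], alphabet: str = STANDARD_AA1
) -> SpecificityArray:
    """Arrange one record per (P3, P2) combination into the 2-D arrays.

    Raises on missing or duplicated combinations, naming the cells.
    """
    letters = sorted(set(alphabet))
    expected = {(x, z) for x in letters for z in letters}
    seen: dict[tuple[str, str], ScreenRecord] = {}
    dupes = []
    for r in records:
        key = (r.peptide.p3, r.peptide.p2)
        if key in seen:
            dupes.append(key)
        seen[key] = r
    missing = sorted(expected - set(seen))
    extra = sorted(set(seen) - expected)
    if dupes:
        raise ValueError(f"duplicate (P3,P2) combinations: {sorted(set(dupes))}")
    if missing or extra:
        raise ValueError(
            f"array incomplete; missing cells: {missing}; unexpected: {extra}"
        )
    idx = pd.Index(letters, name="p2")
    cols = pd.Index(letters, name="p3")
    e = pd.DataFrame(np.nan, index=idx, columns=cols)
    d = pd.DataFrame(np.nan, index=idx, columns=cols)
    h = pd.DataFrame(0, index=idx, columns=cols)
    for (x, z), r in seen.items():
        e.at[z, x] = r.e_bind
        d.at[z, x] = r.d_s2
        h.at[z, x] = r.n_hb
    finite = e.values[np.isfinite(e.values)]
    e_min = float(finite.min()) if len(finite) else float("nan")
    e_max = float(finite.max()) if len(finite) else float("nan")
    return SpecificityArray(
        table=e, e_bind=e, d_s2=d, n_hb=h, e_min=e_min, e_max=e_max,
        alphabet="".join(letters),
    )


def rank_top(records: list[ScreenRecord], n: int, key: str = "energy") -> list[ScreenRecord]:
    """Top-``n`` records ascending by E_bind; ties broken by sequence."""
    if key != "energy":
        raise ValueError(f"unsupported ranking key {key!r}")
    if n > len(records):
        raise ValueError(f"requested top {n} of {len(records)} records")
    return sorted(records, key=lambda r: (r.e_bind, r.peptide.sequence))[:n]


def classify_preferences(
    array: SpecificityArray, classes: dict | None = None
) -> pd.DataFrame:
    """Favored/disfavored chemistry classes per position.

    A class is *favored* at a position when its median E_bind over the
    relevant rows/columns lies below the overall median, *disfavored* when
    above; exact ties are left unflagged.
    """
    classes = classes or DEFAULT_CLASSES
    validate_classes(classes)
    overall = float(np.nanmedian(array.e_bind.values))
    rows = []
    for position, axis in (("P2", "index"), ("P3", "columns")):
        for cname, members in classes.items():
            members = [m for m in members if m in array.alphabet]
            if not members:
                continue
            if axis == "index":
                sub_e = array.e_bind.loc[list(members), :].values
                sub_d = array.d_s2.loc[list(members), :].values
            else:
                sub_e = array.e_bind.loc[:, list(members)].values
                sub_d = array.d_s2.loc[:, list(members)].values
            med_e = float(np.nanmedian(sub_e))
            med_d = float(np.nanmedian(sub_d))
            if med_e < overall:
                flag = "favored"
            elif med_e > overall:
                flag = "disfavored"
            else:
                flag = "neutral"
            rows.append(
                {
                    "position": position, "class": cname,
                    "median_e_bind": med_e, "median_d_s2": med_d,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def scatter_table(records: list[ScreenRecord]) -> pd.DataFrame:
    """Per-peptide energy/distance/H-bond data for scatter rendering."""
    return pd.DataFrame(
        {
            "peptide": [r.peptide.sequence for r in records],
            "e_bind": [r.e_bind for r in records],
            "d_s2": [r.d_s2 for r in records],
            "n_hb": [r.n_hb for r in records],
        }
    )


def infer_alphabet(records: list[ScreenRecord]) -> str:
    return "".join(sorted({r.peptide.p3 for r in records} | {r.peptide.p2 for r in records}))


def qc_report(
    records: list[ScreenRecord],
    top_n: int = 10,
    classes: dict | None = None,
    reference_top: list[str] | None = None,
    alphabet: str | None = None,
) -> dict:
    """Summary dict: top-N list, class summaries, optional Jaccard overlap."""
    ok = [r for r in records if r.status == "ok" and np.isfinite(r.e_bind)]
    arr = None
    summary = None
    try:
        arr = build_array(records, alphabet=alphabet or infer_alphabet(records))
        summary = classify_preferences(arr, classes).to_dict(orient="records")
    except ValueError:
        pass
    top = rank_top(ok, min(top_n, len(ok)))
    out = {
        "top": [r.peptide.sequence for r in top],
        "n_records": len(records),
        "n_failed": sum(1 for r in records if r.status != "ok"),
        "class_summary": summary,
    }
    if reference_top:
        a = {t[:2] for t in out["top"]}
        b = {t[:2] for t in reference_top}
        out["jaccard_vs_reference"] = len(a & b) / len(a | b) if a | b else 0.0
    return out
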