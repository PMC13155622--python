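"""Per-formula molecular descriptors, class assignment and sample summaries.

Descriptors computed per neutral CHNOS formula:

* DBE  = C − H/2 + N/2 + 1 (double-bond equivalents, rings + π bonds),
* NOSC = 4 − (4C + H − 3N − 2O − 2S)/C (nominal oxidation state of carbon,
  −4 for methane to +4 for CO₂),
* AI_mod = [1 + C − 0.5·O − S − 0.5·(N + H)] / (C − 0.5·O − S − N), the
  modified aromaticity index which discounts half the oxygen as
  carbonyl-like (clamped to 0 when numerator or denominator is ≤ 0),
* (DBE − O)/C, an oxygen-corrected unsaturation density,
* elemental class (CHO/CHON/CHOS/CHONS) and a van Krevelen compound class.

Sample-level summaries are intensity-weighted means,
X_w = Σ Xᵢ·Iᵢ / Σ Iᵢ, alongside formula counts per elemental class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula_engine import AssignedPeak, MolecularFormula, exact_mass

__all__ = [
    "dbe",
    "nosc",
    "ai_mod",
    "elemental_class",
    "compound_class",
    "COMPOUND_CLASS_BOXES",
    "describe",
    "SampleSummary",
    "weighted_summary",
]

ELEMENTAL_CLASSES = ("CHO", "CHON", "CHOS", "CHONS")

#: Van Krevelen boxes as (label, h_c_min, h_c_max, o_c_min, o_c_max),
#: evaluated in order with first match winning; shared edges therefore
#: resolve deterministically.
COMPOUND_CLASS_BOXES: tuple[tuple[str, float, float, float, float], ...] = (
    ("aliphatic/proteins", 1.5, 2.2, 0.3, 0.67),
    ("lipids", 1.5, 2.0, 0.0, 0.3),
    ("lignins/CRAM", 0.7, 1.5, 0.1, 0.67),
    ("unsaturated hydrocarbons", 0.7, 1.5, 0.0, 0.1),
    ("carbohydrates", 1.5, 2.4, 0.67, 1.2),
    ("aromatic", 0.2, 0.7, 0.0, 0.67),
    ("tannins", 0.6, 1.5, 0.67, 1.2),
)


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents of the neutral formula."""
    return f.c - f.h / 2 + f.n / 2 + 1


def nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon; requires at least one C."""
    if f.c < 1:
        raise ValueError("NOSC requires c >= 1")
    return 4 - (4 * f.c + f.h - 3 * f.n - 2 * f.o - 2 * f.s) / f.c


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index, clamped to 0 on non-positive
    numerator or denominator."""
    num = 1 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.h)
    den = f.c - 0.5 * f.o - f.s - f.n
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


def elemental_class(f: MolecularFormula) -> str:
    """CHO / CHON / CHOS / CHONS by heteroatom presence; O is mandatory."""
    if f.o < 1:
        raise ValueError(f"formula {f} has no oxygen; outside the CHO* class space")
    if f.n >= 1 and f.s >= 1:
        return "CHONS"
    if f.n >= 1:
        return "CHON"
    if f.s >= 1:
        return "CHOS"
    return "CHO"


def compound_class(h_c: float, o_c: float) -> str:
    """Van Krevelen compound class of an (H/C, O/C) pair; "other" if the
    point falls in none of the seven boxes."""
    if not (np.isfinite(h_c) and np.isfinite(o_c)) or h_c < 0 or o_c < 0:
        raise ValueError(f"invalid ratios ({h_c}, {o_c})")
    for label, hlo, hhi, olo, ohi in COMPOUND_CLASS_BOXES:
        if hlo <= h_c <= hhi and olo <= o_c <= ohi:
            return label
    return "other"


def _record(f: MolecularFormula, mz: float | None, intensity: float) -> dict:
    h_c = f.h / f.c
    o_c = f.o / f.c
    d = dbe(f)
    return {
        "c": f.c,
        "h": f.h,
        "n": f.n,
        "o": f.o,
        "s": f.s,
        "mw": exact_mass(f),
        "mz": mz,
        "o_c": o_c,
        "h_c": h_c,
        "dbe": d,
        "nosc": nosc(f),
        "ai_mod": ai_mod(f),
        "dbe_minus_o_over_c": (d - f.o) / f.c,
        "elemental_class": elemental_class(f),
        "compound_class": compound_class(h_c, o_c),
        "intensity": intensity,
    }


def describe(assigned) -> pd.DataFrame:
    """Descriptor table from assigned peaks.

    Accepts an iterable of :class:`AssignedPeak` or an assigned DataFrame
    with columns ``c,h,n,o,s`` (plus optional ``mz``, ``intensity``).
    """
    rows: list[dict] = []
    if isinstance(assigned, pd.DataFrame):
        if assigned.empty:
            raise ValueError("empty assigned table")
        for t in assigned.itertuples(index=False):
            f = MolecularFormula(int(t.c), int(t.h), int(t.n), int(t.o), int(t.s))
            rows.append(
                _record(f, getattr(t, "mz", None), float(getattr(t, "intensity", 1.0)))
            )
    else:
        assigned = list(assigned)
        if not assigned:
            raise ValueError("empty assigned collection")
        for ap in assigned:
            rows.append(_record(ap.formula, ap.peak.mz, ap.peak.intensity))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample counts and intensity-weighted mean metrics."""

    molecular_number: int
    cho: int
    chon: int
    chos: int
    chons: int
    h_c_w: float
    o_c_w: float
    dbe_w: float
    nosc_w: float
    mz_w: float
    ai_w: float

    def to_dict(self) -> dict:
        return asdict(self)


def weighted_summary(
    records: pd.DataFrame, intensities: Sequence[float] | None = None
) -> SampleSummary:
    """Intensity-weighted molecular metrics and elemental-class counts.

    ``intensities`` defaults to the table's ``intensity`` column.  The
    weighted m/z uses measured m/z where present, else the neutral mass.
    """
    if intensities is None:
        inten = records["intensity"].to_numpy(float)
    else:
        inten = np.asarray(intensities, dtype=float)
    if len(inten) != len(records):
        raise ValueError("intensities length mismatch")
    total = inten.sum()
    if total <= 0:
        raise ValueError("total intensity must be positive")
    w = inten / total

    def wmean(col: str) -> float:
        return float(np.dot(records[col].to_numpy(float), w))

    mz_col = "mz" if ("mz" in records and records["mz"].notna().all()) else "mw"
    counts = records["elemental_class"].value_counts()
    return SampleSummary(
        molecular_number=len(records),
        cho=int(counts.get("CHO", 0)),
        chon=int(counts.get("CHON", 0)),
        chos=int(counts.get("CHOS", 0)),
        chons=int(counts.get("CHONS", 0)),
        h_c_w=wmean("h_c"),
        o_c_w=wmean("o_c"),
        dbe_w=wmean("dbe"),
        nosc_w=wmean("nosc"),
        mz_w=wmean(mz_col),
        ai_w=wmean("ai_mod"),
    )
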