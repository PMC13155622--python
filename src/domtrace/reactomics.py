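"""Paired-mass-distance (PMD) reactomics on removed → produced formula pairs.

Each precursor–product pair whose element-count difference matches an entry
of a reaction-delta library is interpreted as one putative reaction event.
Events are grouped into five reaction types — oxygenation (+O, +O+2H),
cleavage of oxygen-bearing chain fragments (−CnHkOm), dealkylation (−CnH2n,
no oxygen change), carboxyl-related losses (−CO₂, −C₂H₂O₂) — plus "other"
for user-supplied entries outside those four.  The relative abundance of
each type over all matched events is the reaction-type profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._masses import ELEMENT_MASSES
from .formula_engine import MolecularFormula, exact_mass

__all__ = [
    "REACTION_TYPES",
    "ReactionLibraryEntry",
    "ReactionEvent",
    "ReactionTypeProfile",
    "default_library",
    "read_library",
    "formula_delta",
    "match_pairs",
    "match_pairs_by_mass",
    "pmd_profile",
]

REACTION_TYPES = ("oxygenation", "cleavage", "dealkylation", "carboxyl", "other")


@dataclass(frozen=True)
class ReactionLibraryEntry:
    """A named element-count delta (product − precursor) with its type."""

    name: str
    delta: tuple[int, int, int, int, int]  # (dc, dh, dn, do, ds)
    rtype: str

    def __post_init__(self) -> None:
        if self.rtype not in REACTION_TYPES:
            raise ValueError(f"unknown reaction type {self.rtype!r}")
        if all(d == 0 for d in self.delta):
            raise ValueError("all-zero reaction delta")

    @property
    def delta_mass(self) -> float:
        return float(sum(d * m for d, m in zip(self.delta, ELEMENT_MASSES)))


@dataclass(frozen=True)
class ReactionEvent:
    precursor: MolecularFormula
    product: MolecularFormula
    entry: ReactionLibraryEntry


@dataclass(frozen=True)
class ReactionTypeProfile:
    """Relative abundance per reaction type; fractions sum to 1 when any
    event matched, all-zero otherwise."""

    fractions: dict[str, float]
    total: int

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(self.fractions[t] for t in REACTION_TYPES)


def default_library() -> list[ReactionLibraryEntry]:
    """Built-in reaction-delta library.

    Oxygenation: +O, +O+2H.  Carboxyl: −CO₂, −C₂H₂O₂.  Cleavage: loss of
    oxygen-bearing chain fragments −CnHkOm for n = 3..6, k ∈ {2n, 2n+2},
    m = 1..4 (covering both the CnH2n and CnH2n+2 homologous series).
    Dealkylation: −CnH2n for n = 1..3 with no oxygen change.
    """
    lib: list[ReactionLibraryEntry] = [
        ReactionLibraryEntry("+O", (0, 0, 0, 1, 0), "oxygenation"),
        ReactionLibraryEntry("+O+2H", (0, 2, 0, 1, 0), "oxygenation"),
        ReactionLibraryEntry("-CO2", (-1, 0, 0, -2, 0), "carboxyl"),
        ReactionLibraryEntry("-C2H2O2", (-2, -2, 0, -2, 0), "carboxyl"),
    ]
    for n in range(3, 7):
        for k in (2 * n, 2 * n + 2):
            for m in range(1, 5):
                lib.append(
                    ReactionLibraryEntry(
                        f"-C{n}H{k}O{m}", (-n, -k, 0, -m, 0), "cleavage"
                    )
                )
    for n in range(1, 4):
        name = "-CH2" if n == 1 else f"-C{n}H{2 * n}"
        lib.append(ReactionLibraryEntry(name, (-n, -2 * n, 0, 0, 0), "dealkylation"))
    return lib


def read_library(path: str | Path) -> list[ReactionLibraryEntry]:
    """Load a user library from CSV with columns ``name,dc,dh,dn,do,ds,rtype``."""
    df = pd.read_csv(path)
    return [
        ReactionLibraryEntry(
            str(r.name_), (int(r.dc), int(r.dh), int(r.dn), int(r.do), int(r.ds)), str(r.rtype)
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def formula_delta(
    precursor: MolecularFormula, product: MolecularFormula
) -> tuple[int, int, int, int, int]:
    """Element-wise product − precursor."""
    return tuple(int(b - a) for a, b in zip(precursor, product))  # type: ignore[return-value]


def match_pairs(
    removed: Iterable[MolecularFormula],
    produced: Iterable[MolecularFormula],
    library: Sequence[ReactionLibraryEntry] | None = None,
) -> list[ReactionEvent]:
    """All precursor–product pairs whose delta matches a library entry.

    Matching is exhaustive over removed × produced (a formula may take part
    in several events); implemented as a hash lookup per (precursor, entry).
    """
    if library is None:
        library = default_library()
    produced_set = set(produced)
    events: list[ReactionEvent] = []
    for f in removed:
        for entry in library:
            prod = MolecularFormula(*(a + d for a, d in zip(f, entry.delta)))
            if prod in produced_set:
                events.append(ReactionEvent(f, prod, entry))
    return events


def match_pairs_by_mass(
    removed: Iterable[MolecularFormula],
    produced: Iterable[MolecularFormula],
    library: Sequence[ReactionLibraryEntry] | None = None,
    tol_da: float = 0.0005,
) -> list[ReactionEvent]:
    """Mass-difference variant of :func:`match_pairs`.

    Pairs whose exact-mass difference lies within ``tol_da`` of a library
    delta mass are matched; usable when element counts are unavailable.
    On noise-free data this agrees with the element-count route.
    """
    if library is None:
        library = default_library()
    removed = list(removed)
    produced = list(produced)
    rm = np.array([exact_mass(f) for f in removed])
    pm = np.array([exact_mass(f) for f in produced])
    order = np.argsort(pm)
    pm_sorted = pm[order]
    events: list[ReactionEvent] = []
    for i, f in enumerate(removed):
        for entry in library:
            target = rm[i] + entry.delta_mass
            i0 = np.searchsorted(pm_sorted, target - tol_da, side="left")
            i1 = np.searchsorted(pm_sorted, target + tol_da, side="right")
            for j in order[i0:i1]:
                events.append(ReactionEvent(f, produced[j], entry))
    return events


def pmd_profile(events: Iterable[ReactionEvent]) -> ReactionTypeProfile:
    """Relative abundance of each reaction type over matched events."""
    counts = Counter(e.entry.rtype for e in events)
    total = sum(counts.values())
    if total == 0:
        return ReactionTypeProfile({t: 0.0 for t in REACTION_TYPES}, 0)
    return ReactionTypeProfile(
        {t: counts.get(t, 0) / total for t in REACTION_TYPES}, total
    )


def events_to_frame(events: Iterable[ReactionEvent]) -> pd.DataFrame:
    """Long-format event table for export."""
    rows = [
        {
            "precursor": str(e.precursor),
            "product": str(e.product),
            "reaction": e.entry.name,
            "rtype": e.entry.rtype,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=["precursor", "product", "reaction", "rtype"])
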