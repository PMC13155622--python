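"""CHNOS molecular-formula assignment for deprotonated ([M-H]⁻) ions.

Negative-mode exact masses are converted to neutral masses and matched
against all chemically plausible CHNOS formulas within configurable element
bounds and a ppm tolerance.  When several candidates fall inside the
tolerance the one with the fewest heteroatoms (N+S) is preferred, with the
smallest absolute mass error as tiebreak — the standard selection rule for
dissolved-organic-matter spectra.

Two routes are provided: :func:`enumerate_candidates` is a transparent
brute-force enumeration (the reference oracle), while :class:`FormulaIndex`
precomputes the whole candidate space once and answers queries by binary
search.  Both are guaranteed to return the same winner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from ._masses import MASS_C, MASS_H, MASS_N, MASS_O, MASS_PROTON, MASS_S
from .peak_io import Peak, PeakList

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularFormula",
    "AssignedPeak",
    "ElementBounds",
    "FormulaIndex",
    "exact_mass",
    "neutral_mass_from_mz",
    "mz_from_formula",
    "is_chemically_valid",
    "enumerate_candidates",
    "assign_formula",
    "assign_peaklist",
]


class MolecularFormula(NamedTuple):
    """Neutral CHNOS formula as element counts."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __str__(self) -> str:
        parts = []
        for sym, cnt in zip("CHNOS", self):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts) or "empty"


def exact_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return (
        f.c * MASS_C + f.h * MASS_H + f.n * MASS_N + f.o * MASS_O + f.s * MASS_S
    )


def neutral_mass_from_mz(mz: float, ion: str = "deprotonated") -> float:
    """Neutral mass of a singly charged ion; only [M-H]⁻ is supported."""
    if ion != "deprotonated":
        raise ValueError(f"unsupported ion type: {ion!r}")
    if mz <= 0:
        raise ValueError("mz must be positive")
    return mz + MASS_PROTON


def mz_from_formula(f: MolecularFormula) -> float:
    """Noise-free [M-H]⁻ m/z of a neutral formula."""
    return exact_mass(f) - MASS_PROTON


@dataclass(frozen=True)
class ElementBounds:
    """Element-count ranges, ppm tolerance and validity-filter settings.

    Defaults cover the CHO/CHON/CHOS/CHONS space typical of natural
    dissolved organic matter in the 100–800 Da window.
    """

    c_min: int = 1
    c_max: int = 60
    h_min: int = 1
    h_max: int = 120
    n_min: int = 0
    n_max: int = 3
    o_min: int = 1
    o_max: int = 25
    s_min: int = 0
    s_max: int = 2
    tol_ppm: float = 1.0
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2
    dbe_max: float = 25.0
    require_integer_dbe: bool = True
    mass_max: float = 820.0

    def __post_init__(self) -> None:
        for el in "chnos":
            if getattr(self, f"{el}_min") > getattr(self, f"{el}_max"):
                raise ValueError(f"{el}_min > {el}_max")
        if self.tol_ppm < 0:
            raise ValueError("tol_ppm must be >= 0")

    def contains(self, f: MolecularFormula) -> bool:
        return (
            self.c_min <= f.c <= self.c_max
            and self.h_min <= f.h <= self.h_max
            and self.n_min <= f.n <= self.n_max
            and self.o_min <= f.o <= self.o_max
            and self.s_min <= f.s <= self.s_max
        )


DEFAULT_BOUNDS = ElementBounds()


def _dbe(f: MolecularFormula) -> float:
    return f.c - f.h / 2 + f.n / 2 + 1


def is_chemically_valid(f: MolecularFormula, bounds: ElementBounds = DEFAULT_BOUNDS) -> bool:
    """Standard plausibility filters: H/C in [0.3, 2.5], O/C ≤ 1.2, integer
    DBE in [0, 25] (even-electron neutral species), element bounds."""
    if not bounds.contains(f):
        return False
    if f.c < 1:
        return False
    hc = f.h / f.c
    if not (bounds.hc_min <= hc <= bounds.hc_max):
        return False
    if f.o / f.c > bounds.oc_max:
        return False
    d = _dbe(f)
    if d < 0 or d > bounds.dbe_max:
        return False
    if bounds.require_integer_dbe and (f.h - f.n) % 2 != 0:
        return False
    return True


@dataclass(frozen=True)
class AssignedPeak:
    """A peak with its selected neutral formula and signed ppm mass error."""

    peak: Peak
    formula: MolecularFormula
    neutral_mass: float
    error_ppm: float


def _candidate_key(f: MolecularFormula, err_ppm: float) -> tuple:
    # Smallest |mass error| first, fewest heteroatoms (N+S) as tiebreak.
    # CHNOS space contains sub-ppm isobaric doublets (e.g. exchanging
    # C8 for H4N2O2S shifts the mass by only 0.65 mDa), so a strict
    # heteroatom-minimisation rule would overwrite exact matches for
    # heteroatom-rich formulas above ~650 Da; error-first keeps the
    # assignment faithful while heteroatom count resolves genuine ties.
    return (abs(err_ppm), f.n + f.s, f.c, f.h, f.n, f.o, f.s)


def enumerate_candidates(
    neutral_mass: float, bounds: ElementBounds = DEFAULT_BOUNDS
) -> list[tuple[MolecularFormula, float]]:
    """Brute-force enumeration of all valid formulas within ±tol_ppm.

    Sorted by (heteroatom count N+S ascending, |ppm| ascending, element
    counts); the head of the list is the assignment winner.  Deliberately
    simple — this is the reference oracle for the indexed lookup.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    tol_da = neutral_mass * bounds.tol_ppm * 1e-6
    out: list[tuple[MolecularFormula, float]] = []
    for c in range(bounds.c_min, bounds.c_max + 1):
        if c * MASS_C > neutral_mass + tol_da:
            break
        for n in range(bounds.n_min, bounds.n_max + 1):
            for s in range(bounds.s_min, bounds.s_max + 1):
                base = c * MASS_C + n * MASS_N + s * MASS_S
                if base > neutral_mass + tol_da:
                    continue
                for o in range(bounds.o_min, bounds.o_max + 1):
                    rem = neutral_mass - base - o * MASS_O
                    if rem < bounds.h_min * MASS_H - tol_da:
                        break
                    h_lo = math.ceil((rem - tol_da) / MASS_H)
                    h_hi = math.floor((rem + tol_da) / MASS_H)
                    for h in range(h_lo, h_hi + 1):
                        f = MolecularFormula(c, h, n, o, s)
                        if not is_chemically_valid(f, bounds):
                            continue
                        m = exact_mass(f)
                        err = (m - neutral_mass) / neutral_mass * 1e6
                        if abs(err) <= bounds.tol_ppm:
                            out.append((f, err))
    out.sort(key=lambda t: _candidate_key(t[0], t[1]))
    return out


class FormulaIndex:
    """Precomputed table of every valid formula within bounds, sorted by mass.

    Queries are answered with a binary search over the mass column, then the
    same selection rule as the brute-force path.
    """

    def __init__(self, bounds: ElementBounds = DEFAULT_BOUNDS):
        self.bounds = bounds
        cols = {k: [] for k in "chnos"}
        b = bounds
        for c in range(b.c_min, b.c_max + 1):
            o_hi = min(b.o_max, int(b.oc_max * c))
            h_lo = max(b.h_min, math.ceil(b.hc_min * c))
            if o_hi < b.o_min:
                continue
            for n in range(b.n_min, b.n_max + 1):
                # DBE >= 0 requires h <= 2c + n + 2
                h_hi = min(b.h_max, math.floor(b.hc_max * c), 2 * c + n + 2)
                if h_hi < h_lo:
                    continue
                for s in range(b.s_min, b.s_max + 1):
                    for o in range(b.o_min, o_hi + 1):
                        base = c * MASS_C + n * MASS_N + s * MASS_S + o * MASS_O
                        if base + h_lo * MASS_H > b.mass_max:
                            break
                        for h in range(h_lo, h_hi + 1):
                            f = MolecularFormula(c, h, n, o, s)
                            if not is_chemically_valid(f, b):
                                continue
                            if base + h * MASS_H > b.mass_max:
                                break
                            for k, v in zip("chnos", f):
                                cols[k].append(v)
        arr = {k: np.array(v, dtype=np.int16) for k, v in cols.items()}
        mass = (
            arr["c"] * MASS_C
            + arr["h"].astype(float) * MASS_H
            + arr["n"] * MASS_N
            + arr["o"] * MASS_O
            + arr["s"] * MASS_S
        )
        order = np.argsort(mass, kind="stable")
        self.mass = mass[order]
        self.counts = np.column_stack([arr[k][order] for k in "chnos"])
        logger.info("formula index: %d candidates", len(self.mass))

    def __len__(self) -> int:
        return len(self.mass)

    def query(self, neutral_mass: float) -> list[tuple[MolecularFormula, float]]:
        """All candidates within ±tol_ppm, in selection order."""
        tol_da = neutral_mass * self.bounds.tol_ppm * 1e-6
        i0 = np.searchsorted(self.mass, neutral_mass - tol_da, side="left")
        i1 = np.searchsorted(self.mass, neutral_mass + tol_da, side="right")
        out = []
        for i in range(i0, i1):
            f = MolecularFormula(*(int(x) for x in self.counts[i]))
            err = (self.mass[i] - neutral_mass) / neutral_mass * 1e6
            if abs(err) <= self.bounds.tol_ppm:
                out.append((f, err))
        out.sort(key=lambda t: _candidate_key(t[0], t[1]))
        return out


@lru_cache(maxsize=4)
def _cached_index(bounds: ElementBounds) -> FormulaIndex:
    return FormulaIndex(bounds)


def assign_formula(
    peak: Peak,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    index: FormulaIndex | None = None,
) -> AssignedPeak | None:
    """Assign the best CHNOS formula to a [M-H]⁻ peak, or None.

    Selection: fewest heteroatoms (N+S) first, then smallest |ppm error|.
    """
    if index is None:
        index = _cached_index(bounds)
    m = neutral_mass_from_mz(peak.mz)
    cands = index.query(m)
    if not cands:
        return None
    f, err = cands[0]
    return AssignedPeak(peak=peak, formula=f, neutral_mass=exact_mass(f), error_ppm=err)


def assign_peaklist(
    pl: PeakList,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    index: FormulaIndex | None = None,
) -> pd.DataFrame:
    """Assign every peak in a list; returns the assigned table.

    Columns: ``mz,intensity,c,h,n,o,s,neutral_mass,error_ppm``.  Unassigned
    peaks are dropped and their count logged.
    """
    if index is None:
        index = _cached_index(bounds)
    rows = []
    n_unassigned = 0
    for p in pl:
        ap = assign_formula(p, bounds, index)
        if ap is None:
            n_unassigned += 1
            continue
        rows.append(
            (p.mz, p.intensity, *ap.formula, ap.neutral_mass, ap.error_ppm)
        )
    logger.info("%s: %d assigned, %d unassigned", pl.sample_id, len(rows), n_unassigned)
    return pd.DataFrame(
        rows,
        columns=["mz", "intensity", "c", "h", "n", "o", "s", "neutral_mass", "error_ppm"],
    )


def iter_valid_formulas(bounds: ElementBounds = DEFAULT_BOUNDS) -> Iterator[MolecularFormula]:
    """Iterate the full valid-formula space of a bounds object (index order)."""
    idx = _cached_index(bounds)
    for row in idx.counts:
        yield MolecularFormula(*(int(x) for x in row))
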