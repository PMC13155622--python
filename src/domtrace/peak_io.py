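"""Reading, validation and filtering of centroided peak lists.

A peak list is the starting point of the pipeline: one centroided
(m/z, intensity) table per sample or per procedural blank, singly charged
negative-mode ions assumed.  This module canonicalizes the table (sorted,
duplicate centroids merged), removes blank-matched contaminant peaks within
a ppm tolerance, and restricts the mass window before formula assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakList",
    "PeakListError",
    "MissingFileError",
    "NonNumericError",
    "NegativeIntensityError",
    "EmptyPeakListError",
    "read_peaklist",
    "subtract_blank",
    "restrict_mz",
]


class PeakListError(ValueError):
    """Base class for peak-list validation failures."""


class MissingFileError(PeakListError):
    """The peak-list file does not exist."""


class NonNumericError(PeakListError):
    """A cell in the mz/intensity columns could not be parsed as a number."""


class NegativeIntensityError(PeakListError):
    """An intensity value is negative."""


class EmptyPeakListError(PeakListError):
    """The file contains no peak rows."""


@dataclass(frozen=True)
class Peak:
    """One centroided observation: m/z in Da (singly charged) and intensity."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mz) and np.isfinite(self.intensity)):
            raise PeakListError(f"non-finite peak ({self.mz}, {self.intensity})")
        if self.mz <= 0:
            raise PeakListError(f"non-positive mz {self.mz}")
        if self.intensity < 0:
            raise NegativeIntensityError(f"negative intensity {self.intensity}")


@dataclass
class PeakList:
    """A canonicalized peak list: strictly increasing m/z, no duplicates.

    ``temperature_label`` distinguishes the two treatments of a paired
    experiment (e.g. ``"T_low"`` / ``"T_high"``) or marks a procedural blank.
    """

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    temperature_label: str | None = None

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise PeakListError("peaks must be strictly increasing in mz")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        mz: np.ndarray,
        intensity: np.ndarray,
        temperature_label: str | None = None,
    ) -> "PeakList":
        """Build a canonical PeakList: sort by mz, merge duplicate centroids
        by intensity summation."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        if len(uniq) < len(mz):
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, intensity)
            logger.info("merged %d duplicate centroids", len(mz) - len(uniq))
            mz, intensity = uniq, summed
        peaks = [Peak(m, i) for m, i in zip(mz, intensity)]
        return cls(sample_id=sample_id, peaks=peaks, temperature_label=temperature_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})


def read_peaklist(path: str | Path, sample_id: str | None = None) -> PeakList:
    """Read a delimited peak-list file with columns ``mz,intensity``.

    CSV vs TSV is chosen from the file extension (``.tsv``/``.txt`` → tab,
    anything else → comma).  Duplicate m/z rows are merged by intensity
    summation.  An optional ``sample`` column is ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"peak list not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if "sample" in df.columns:
        logger.warning("%s: 'sample' column ignored", path.name)
        df = df.drop(columns=["sample"])
    if df.shape[1] < 2:
        raise PeakListError(f"{path.name}: expected two columns mz,intensity")
    cols = list(df.columns[:2])
    if "mz" in df.columns and "intensity" in df.columns:
        cols = ["mz", "intensity"]
    data = df[cols]
    if data.empty:
        raise EmptyPeakListError(f"{path.name}: no peak rows")
    numeric = data.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = data[numeric.isna().any(axis=1)].index[0]
        raise NonNumericError(f"{path.name}: non-numeric cell in row {bad}")
    mz = numeric.iloc[:, 0].to_numpy(float)
    inten = numeric.iloc[:, 1].to_numpy(float)
    if (inten < 0).any():
        raise NegativeIntensityError(f"{path.name}: negative intensity")
    if (mz <= 0).any() or not np.isfinite(mz).all() or not np.isfinite(inten).all():
        raise PeakListError(f"{path.name}: mz must be positive and finite")
    pl = PeakList.from_arrays(sample_id or path.stem, mz, inten)
    logger.info("%s: read %d rows -> %d peaks", path.name, len(df), len(pl))
    return pl


def subtract_blank(sample: PeakList, blank: PeakList, tol_ppm: float = 1.0) -> PeakList:
    """Remove sample peaks matching any procedural-blank peak within ±tol_ppm.

    The ppm window is taken relative to the blank peak's m/z.  Applying the
    subtraction twice with the same blank is a no-op the second time.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(blank) == 0 or len(sample) == 0:
        return PeakList(sample.sample_id, list(sample.peaks), sample.temperature_label)
    smz = sample.mz
    bmz = blank.mz
    # window per blank peak: bmz * (1 ± tol_ppm*1e-6)
    lo = bmz * (1 - tol_ppm * 1e-6)
    hi = bmz * (1 + tol_ppm * 1e-6)
    # a sample peak is removed if it falls inside any [lo, hi] interval
    idx = np.searchsorted(bmz, smz)
    removed = np.zeros(len(smz), dtype=bool)
    for shift in (0, -1, 1):
        j = np.clip(idx + shift, 0, len(bmz) - 1)
        removed |= (smz >= lo[j]) & (smz <= hi[j])
    kept = [p for p, r in zip(sample.peaks, removed) if not r]
    logger.info("%s: blank subtraction removed %d peaks", sample.sample_id, int(removed.sum()))
    return PeakList(sample.sample_id, kept, sample.temperature_label)


def restrict_mz(pl: PeakList, lo: float = 100.0, hi: float = 800.0) -> PeakList:
    """Keep peaks with lo ≤ m/z ≤ hi (closed interval, default 100–800 Da)."""
    if lo >= hi:
        raise ValueError(f"invalid mz window [{lo}, {hi}]")
    kept = [p for p in pl.peaks if lo <= p.mz <= hi]
    if not kept and len(pl):
        logger.warning("%s: all peaks outside [%g, %g]", pl.sample_id, lo, hi)
    return PeakList(pl.sample_id, kept, pl.temperature_label)
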