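"""Molecular fate across a two-treatment (reference vs perturbed) pair.

Fate is presence/absence logic on assigned formulas: a formula detected only
in the reference treatment is *removed*, only in the perturbed treatment
*produced*, and in both *resistant*.  Cross-tabulations of class →
descriptor bin → fate (the data behind Sankey/alluvial figures) are exported
as flow tables.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formula_engine import MolecularFormula

logger = logging.getLogger(__name__)

__all__ = ["FATE_LABELS", "classify_fate", "fate_counts", "crosstab"]

FATE_LABELS = ("removed", "resistant", "produced")


def classify_fate(
    set_low: Iterable[MolecularFormula], set_high: Iterable[MolecularFormula]
) -> dict[MolecularFormula, str]:
    """Label every formula of the union by its fate.

    removed = low \\ high; produced = high \\ low; resistant = low ∩ high.
    Formula identity is exact element-count equality.
    """
    low = set(set_low)
    high = set(set_high)
    if not low and not high:
        raise ValueError("both formula sets are empty")
    fates: dict[MolecularFormula, str] = {}
    for f in low - high:
        fates[f] = "removed"
    for f in low & high:
        fates[f] = "resistant"
    for f in high - low:
        fates[f] = "produced"
    return fates


def fate_counts(fates: Mapping[MolecularFormula, str]) -> tuple[int, int, int]:
    """(n_removed, n_resistant, n_produced); sums to the union size."""
    if not fates:
        raise ValueError("empty fate map")
    vals = list(fates.values())
    return (vals.count("removed"), vals.count("resistant"), vals.count("produced"))


def _bin_labels(n: int, descriptor: str) -> list[str]:
    if n == 3:
        return [f"{descriptor}:low", f"{descriptor}:mid", f"{descriptor}:high"]
    return [f"{descriptor}:bin{i + 1}" for i in range(n)]


def crosstab(
    records: pd.DataFrame,
    class_column: str = "elemental_class",
    descriptor: str = "nosc",
    n_bins: int = 3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flow table for class → descriptor-bin → fate paths.

    ``records`` needs columns ``class_column``, ``descriptor`` and ``fate``.
    Descriptor bins are quantiles over the pooled records (terciles by
    default); with fewer distinct values than requested bins the binning
    falls back to 2 bins with a warning.  Returns (flows, bin_edges) where
    flows has columns ``source,target,count`` and each layer's counts sum to
    the total record count.
    """
    for col in (class_column, descriptor, "fate"):
        if col not in records.columns:
            raise KeyError(f"records missing column {col!r}")
    x = records[descriptor].to_numpy(float)
    n_distinct = len(np.unique(x))
    if n_distinct < n_bins:
        logger.warning(
            "%s has %d distinct values < %d bins; falling back to 2 bins",
            descriptor, n_distinct, n_bins,
        )
        n_bins = 2
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # constant descriptor: one bin spanning the value
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    labels = _bin_labels(len(edges) - 1, descriptor)
    binned = pd.cut(x, bins=edges, labels=labels, include_lowest=True)
    df = records.assign(_bin=binned)
    left = (
        df.groupby([class_column, "_bin"], observed=True)
        .size()
        .reset_index(name="count")
        .rename(columns={class_column: "source", "_bin": "target"})
    )
    right = (
        df.groupby(["_bin", "fate"], observed=True)
        .size()
        .reset_index(name="count")
        .rename(columns={"_bin": "source", "fate": "target"})
    )
    flows = pd.concat([left, right], ignore_index=True)
    flows["source"] = flows["source"].astype(str)
    flows["target"] = flows["target"].astype(str)
    return flows, edges
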