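"""Ground-truthed synthetic datasets for the whole pipeline.

The generator emulates the statistical structure of a paired-temperature
(reference vs warmed) leachate experiment measured by ultrahigh-resolution
negative-mode mass spectrometry:

* a pool of unique CHNOS formulas rejection-sampled from the van Krevelen
  compound-class boxes with a configurable class mixture,
* log-normal peak intensities,
* a planted reaction layer: a configurable fraction of formulas is removed
  on warming, each removed precursor emitting one product through a reaction
  drawn from a typed delta library (oxygenation / cleavage / dealkylation /
  carboxyl / other) with exact type quotas,
* [M-H]⁻ peak lists with Gaussian ppm-scale mass error and shared blank
  contaminant peaks,
* an optional planted multinomial-logistic fate rule on (O/C, NOSC) with a
  known Bayes-optimal accuracy.

Every output is deterministic under the mandatory seed, and the returned
ground truth lets each downstream stage be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from ._masses import MASS_PROTON
from .descriptors import COMPOUND_CLASS_BOXES, compound_class
from .formula_engine import (
    DEFAULT_BOUNDS,
    ElementBounds,
    MolecularFormula,
    exact_mass,
    is_chemically_valid,
)
from .peak_io import PeakList
from .reactomics import (
    REACTION_TYPES,
    ReactionEvent,
    ReactionLibraryEntry,
    default_library,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "planted_library",
    "sample_formula_pool",
    "apply_planted_reactions",
    "formulas_to_peaklist",
    "plant_fate_rule",
    "generate_dataset",
]

#: Default class mixture: the bulk of the pool sits in the partially
#: oxidized lignin/CRAM-like core (O/C ≈ 0.1–0.6, H/C ≈ 0.7–1.8) typical of
#: coal-derived leachates, with smaller carbohydrate-like (high O/C),
#: condensed-aromatic (low H/C) and aliphatic fringes.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "lignins/CRAM": 0.55,
    "aliphatic/proteins": 0.12,
    "tannins": 0.10,
    "carbohydrates": 0.08,
    "aromatic": 0.07,
    "lipids": 0.04,
    "unsaturated hydrocarbons": 0.04,
}

#: Reaction-type mixture for the planted transformation layer.
DEFAULT_REACTION_MIXTURE: dict[str, float] = {
    "oxygenation": 0.40,
    "cleavage": 0.30,
    "dealkylation": 0.15,
    "carboxyl": 0.10,
    "other": 0.05,
}

#: Default 3-class logistic rule on z-scored (O/C, NOSC): oxidized,
#: high-NOSC formulas tend to be produced, reduced ones removed, the middle
#: band resistant.
DEFAULT_FATE_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "removed": (-2.0, -2.0, 0.0),
    "resistant": (0.0, 0.0, 1.0),
    "produced": (2.0, 2.0, 0.0),
}

#: Common negative-mode background masses (m/z) used as blank contaminants.
DEFAULT_BLANK_CONTAMINANTS: tuple[float, ...] = (
    112.9856,
    255.2330,
    283.2643,
    311.1687,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; the seed is mandatory."""

    seed: int
    n_formulas: int = 5000
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    bounds: ElementBounds = DEFAULT_BOUNDS
    intensity_meanlog: float = 13.8  # median intensity ≈ 1e6 counts
    intensity_sdlog: float = 1.0
    ppm_sigma: float = 0.3
    fraction_removed: float = 0.30
    reaction_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REACTION_MIXTURE)
    )
    fate_coefficients: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FATE_COEFFICIENTS)
    )
    blank_contaminants: tuple[float, ...] = DEFAULT_BLANK_CONTAMINANTS
    mz_min: float = 100.0
    mz_max: float = 800.0
    # carbon-number distribution: discretized Gaussian, giving a formula
    # cloud centred near 350-450 Da as in natural DOM spectra
    carbon_mean: float = 18.0
    carbon_sd: float = 6.0
    carbon_min: int = 5
    carbon_max: int = 40
    # per-formula oxygen cap: natural DOM clouds are wedge-shaped (large
    # molecules are not extremely oxygenated); keeps the pool's weighted
    # O/C in the 0.2-0.4 range observed for coal leachates
    max_oxygen: int = 13

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_removed <= 1:
            raise ValueError("fraction_removed must be in [0, 1]")
        if abs(sum(self.class_mixture.values()) - 1) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if abs(sum(self.reaction_mixture.values()) - 1) > 1e-9:
            raise ValueError("reaction mixture must sum to 1")
        unknown = set(self.class_mixture) - {b[0] for b in COMPOUND_CLASS_BOXES}
        if unknown:
            raise ValueError(f"unknown compound classes {unknown}")
        if set(self.reaction_mixture) - set(REACTION_TYPES):
            raise ValueError("unknown reaction types in mixture")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    fates: dict[MolecularFormula, str]
    events: list[ReactionEvent]
    reaction_quotas: dict[str, int]
    fate_rule: dict | None = None


@dataclass
class SyntheticDataset:
    """A full paired-treatment dataset with ground truth."""

    pool: pd.DataFrame  # formula pool with intensity and true class
    set_low: set[MolecularFormula]
    set_high: set[MolecularFormula]
    intensities_low: dict[MolecularFormula, float]
    intensities_high: dict[MolecularFormula, float]
    peaklist_low: PeakList
    peaklist_high: PeakList
    blank: PeakList
    truth: GroundTruth


def planted_library() -> list[ReactionLibraryEntry]:
    """Built-in library plus a dehydration entry for the "other" type."""
    return default_library() + [
        ReactionLibraryEntry("-H2O", (0, -2, 0, -1, 0), "other")
    ]


def _quotas(mixture: Mapping[str, float], total: int, keys: Sequence[str]) -> dict[str, int]:
    """Largest-remainder apportionment: integer quotas summing to total."""
    fracs = np.array([mixture.get(k, 0.0) for k in keys])
    raw = fracs * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return {k: int(q) for k, q in zip(keys, base)}


def _mass_ok(f: MolecularFormula, cfg: SyntheticConfig) -> bool:
    # margin keeps ppm-jittered peaks inside the downstream m/z window
    m = exact_mass(f)
    return cfg.mz_min + MASS_PROTON + 0.2 <= m <= cfg.mz_max + MASS_PROTON - 0.2


def _sample_formula_in_class(
    label: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> MolecularFormula | None:
    """One attempt at drawing a valid, in-window formula inside a class box."""
    box = next(b for b in COMPOUND_CLASS_BOXES if b[0] == label)
    _, hlo, hhi, olo, ohi = box
    b = cfg.bounds
    c = int(round(rng.normal(cfg.carbon_mean, cfg.carbon_sd)))
    if not (cfg.carbon_min <= c <= cfg.carbon_max):
        return None
    n = int(rng.choice(4, p=[0.45, 0.25, 0.20, 0.10]))
    s = int(rng.choice(3, p=[0.70, 0.25, 0.05]))
    o_lo = max(b.o_min, math.ceil(olo * c))
    o_hi = min(b.o_max, cfg.max_oxygen, math.floor(ohi * c))
    if o_hi < o_lo:
        return None
    o = int(rng.integers(o_lo, o_hi + 1))
    h_lo = max(b.h_min, math.ceil(hlo * c))
    h_hi = min(b.h_max, math.floor(hhi * c))
    if h_hi < h_lo:
        return None
    h = int(rng.integers(h_lo, h_hi + 1))
    if (h - n) % 2 != 0:  # integer-DBE parity
        h += 1 if h + 1 <= h_hi else -1
    f = MolecularFormula(c, h, n, o, s)
    if not is_chemically_valid(f, b) or not _mass_ok(f, cfg):
        return None
    if compound_class(h / c, o / c) != label:
        return None
    return f


def sample_formula_pool(config: SyntheticConfig) -> pd.DataFrame:
    """Rejection-sample a pool of unique formulas matching the class mixture.

    Returns a DataFrame with columns ``c,h,n,o,s,intensity,true_class``;
    exactly ``n_formulas`` rows, deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    classes = [b[0] for b in COMPOUND_CLASS_BOXES if config.class_mixture.get(b[0], 0) > 0]
    quotas = _quotas(config.class_mixture, config.n_formulas, classes)
    seen: set[MolecularFormula] = set()
    rows = []
    for label in classes:
        need = quotas[label]
        attempts = 0
        while need > 0:
            attempts += 1
            if attempts > 200_000:
                raise RuntimeError(f"class box {label!r} infeasible under bounds")
            f = _sample_formula_in_class(label, config, rng)
            if f is None or f in seen:
                continue
            seen.add(f)
            intensity = float(
                np.exp(rng.normal(config.intensity_meanlog, config.intensity_sdlog))
            )
            rows.append((*f, intensity, label))
            need -= 1
    df = pd.DataFrame(rows, columns=["c", "h", "n", "o", "s", "intensity", "true_class"])
    return df.sample(frac=1.0, random_state=config.seed).reset_index(drop=True)


def _pool_formulas(pool: pd.DataFrame) -> list[MolecularFormula]:
    return [
        MolecularFormula(int(r.c), int(r.h), int(r.n), int(r.o), int(r.s))
        for r in pool.itertuples(index=False)
    ]


def apply_planted_reactions(
    pool: pd.DataFrame, config: SyntheticConfig
) -> tuple[set[MolecularFormula], set[MolecularFormula], GroundTruth]:
    """Split the pool into removed/resistant and emit reaction products.

    Exact per-type event quotas are drawn from the reaction mixture; each
    removed precursor yields one product via a randomly chosen entry of its
    assigned type.  Products must be valid, inside the mass window and
    distinct from every pool formula and other product; precursors for which
    no entry of the requested type gives a valid product stay resistant and
    the next candidate is tried.

    To keep the planted reaction of every event identifiable from the
    emitted data, a product is additionally required to be reachable from
    exactly one pool formula via exactly one library delta (its own
    precursor).  Without this constraint, exhaustive precursor–product
    matching over a homologous-series-rich pool picks up coincidental
    pairs and the planted mixture would not be recoverable from the data.
    """
    rng = np.random.default_rng(config.seed + 1)
    formulas = _pool_formulas(pool)
    pool_set = set(formulas)
    n_removed = round(config.fraction_removed * len(formulas))
    quotas = _quotas(config.reaction_mixture, n_removed, list(REACTION_TYPES))
    lib = planted_library()
    by_type: dict[str, list[ReactionLibraryEntry]] = {t: [] for t in REACTION_TYPES}
    for e in lib:
        by_type[e.rtype].append(e)

    order = rng.permutation(len(formulas))
    removed: set[MolecularFormula] = set()
    produced: set[MolecularFormula] = set()
    events: list[ReactionEvent] = []
    todo = [(t, quotas[t]) for t in REACTION_TYPES if quotas[t] > 0]
    ti = 0
    remaining = quotas.copy()
    for i in order:
        if ti >= len(todo):
            break
        rtype = todo[ti][0]
        f = formulas[i]
        entries = by_type[rtype]
        for j in rng.permutation(len(entries)):
            entry = entries[j]
            prod = MolecularFormula(*(a + d for a, d in zip(f, entry.delta)))
            if min(prod) < 0:
                continue
            if not is_chemically_valid(prod, config.bounds) or not _mass_ok(prod, config):
                continue
            if prod in pool_set or prod in produced:
                continue
            # identifiability: the product must trace back to exactly one
            # pool precursor through exactly one library reaction
            n_routes = 0
            for e2 in lib:
                back = MolecularFormula(*(a - d for a, d in zip(prod, e2.delta)))
                if min(back) >= 0 and back in pool_set:
                    n_routes += 1
                    if n_routes > 1:
                        break
            if n_routes != 1:
                continue
            removed.add(f)
            produced.add(prod)
            events.append(ReactionEvent(f, prod, entry))
            remaining[rtype] -= 1
            if remaining[rtype] == 0:
                ti += 1
            break
    unfilled = {t: q for t, q in remaining.items() if q > 0}
    if unfilled:
        raise RuntimeError(f"could not fill reaction quotas: {unfilled}")
    resistant = pool_set - removed
    set_low = pool_set
    set_high = resistant | produced
    fates = {f: "removed" for f in removed}
    fates.update({f: "resistant" for f in resistant})
    fates.update({f: "produced" for f in produced})
    truth = GroundTruth(fates=fates, events=events, reaction_quotas=quotas)
    return set_low, set_high, truth


def formulas_to_peaklist(
    formulas: Sequence[MolecularFormula],
    intensities: Sequence[float],
    ppm_sigma: float,
    seed: int,
    sample_id: str = "synthetic",
    temperature_label: str | None = None,
    extra_mz: Sequence[float] = (),
    extra_intensity: Sequence[float] = (),
) -> PeakList:
    """[M-H]⁻ peak list with multiplicative Gaussian ppm mass error.

    ``extra_mz`` peaks (e.g. blank contaminants) are appended unjittered.
    """
    rng = np.random.default_rng(seed)
    mass = np.array([exact_mass(f) for f in formulas])
    eps = rng.normal(0.0, ppm_sigma * 1e-6, size=len(mass)) if ppm_sigma > 0 else 0.0
    mz = (mass - MASS_PROTON) * (1.0 + eps)
    mz = np.concatenate([mz, np.asarray(extra_mz, dtype=float)])
    inten = np.concatenate(
        [np.asarray(intensities, dtype=float), np.asarray(extra_intensity, dtype=float)]
    )
    return PeakList.from_arrays(sample_id, mz, inten, temperature_label)


def plant_fate_rule(
    records: pd.DataFrame,
    coefficients: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Draw 3-class fate labels from a multinomial-logistic rule on
    (O/C, NOSC) and return (labels, Bayes-optimal accuracy).

    Class score_k = w1_k·z(O/C) + w2_k·z(NOSC) + b_k on z-scored features;
    labels are sampled from the softmax probabilities, so the best possible
    classifier accuracy is E[max_k p_k] — returned alongside the labels.
    Labels are coded 0 = removed, 1 = resistant, 2 = produced.
    """
    if coefficients is None:
        coefficients = DEFAULT_FATE_COEFFICIENTS
    rng = np.random.default_rng(seed)
    u = records["o_c"].to_numpy(float)
    v = records["nosc"].to_numpy(float)
    u = (u - u.mean()) / (u.std() or 1.0)
    v = (v - v.mean()) / (v.std() or 1.0)
    order = ("removed", "resistant", "produced")
    scores = np.column_stack(
        [coefficients[k][0] * u + coefficients[k][1] * v + coefficients[k][2] for k in order]
    )
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)
    cum = p.cumsum(axis=1)
    r = rng.random(len(p))[:, None]
    labels = (r > cum[:, :-1]).sum(axis=1)
    bayes = float(p.max(axis=1).mean())
    return labels.astype(int), bayes


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full paired-treatment dataset: pool, fates, peak lists and blank."""
    pool = sample_formula_pool(config)
    set_low, set_high, truth = apply_planted_reactions(pool, config)
    rng = np.random.default_rng(config.seed + 2)
    base_int = {
        f: float(i)
        for f, i in zip(_pool_formulas(pool), pool["intensity"].to_numpy(float))
    }
    intensities_low = {f: base_int[f] for f in set_low}
    intensities_high = {}
    for f in sorted(set_high):
        if f in base_int:
            intensities_high[f] = base_int[f] * float(
                np.exp(rng.normal(0.0, 0.2))
            )  # mild run-to-run variation
        else:
            intensities_high[f] = float(
                np.exp(rng.normal(config.intensity_meanlog, config.intensity_sdlog))
            )
    n_blank = len(config.blank_contaminants)
    blank_int = np.exp(rng.normal(config.intensity_meanlog, 0.5, size=n_blank))
    low_sorted = sorted(set_low)
    high_sorted = sorted(set_high)
    pl_low = formulas_to_peaklist(
        low_sorted,
        [intensities_low[f] for f in low_sorted],
        config.ppm_sigma,
        config.seed + 3,
        sample_id="synthetic-T_low",
        temperature_label="T_low",
        extra_mz=config.blank_contaminants,
        extra_intensity=blank_int,
    )
    pl_high = formulas_to_peaklist(
        high_sorted,
        [intensities_high[f] for f in high_sorted],
        config.ppm_sigma,
        config.seed + 4,
        sample_id="synthetic-T_high",
        temperature_label="T_high",
        extra_mz=config.blank_contaminants,
        extra_intensity=blank_int,
    )
    blank = PeakList.from_arrays(
        "synthetic-blank",
        np.asarray(config.blank_contaminants, dtype=float),
        blank_int,
        temperature_label="blank",
    )
    return SyntheticDataset(
        pool=pool,
        set_low=set_low,
        set_high=set_high,
        intensities_low=intensities_low,
        intensities_high=intensities_high,
        peaklist_low=pl_low,
        peaklist_high=pl_high,
        blank=blank,
        truth=truth,
    )
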