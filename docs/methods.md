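# Methods

## Scope and model

`domtrace` analyzes how a dissolved-organic-matter (DOM) pool changes
between two treatments — in the motivating application, coal leachate held
at a shallow-aquifer reference temperature versus a geothermal one — using
only what ultrahigh-resolution negative-mode mass spectrometry provides:
centroided (m/z, intensity) peak lists. The pipeline starts *after*
instrument calibration and peak picking; vendor file parsing, spectral
recalibration and isotopologue verification are out of scope.

All ions are treated as singly charged deprotonated molecules, so the
neutral mass is M = m/z + 1.00727646 Da. Formulas are limited to C, H, N,
O, S — the elements that define the four heteroatom classes (CHO, CHON,
CHOS, CHONS) used throughout leachate fingerprinting.

## Formula assignment

Candidates for a neutral mass are all element-count combinations within
configurable bounds (defaults: C 1–60, H 1–120, N 0–3, O 1–25, S 0–2) that
pass standard plausibility filters: 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2, and an
integer DBE in [0, 25], where DBE = C − H/2 + N/2 + 1. Integer DBE on the
neutral molecule is equivalent to the nitrogen rule for even-electron
species. The DBE ceiling excludes hydrogen-starved carbon clusters
(DBE ≳ 26 below 800 Da) that no leachate plausibly contains but that would
otherwise shadow legitimate oxygen-rich formulas (see below). All bounds
and filters are user-configurable (`ElementBounds`).

**Selection rule.** Within the ±1 ppm tolerance the candidate with the
smallest |mass error| wins; the heteroatom count N+S breaks exact ties,
then lexicographic element counts. Minimizing heteroatoms *before* mass
error — the other common reading of "fewest heteroatoms and/or smallest
error" — is not viable at a 1 ppm tolerance: the CHNOS space contains
isobaric doublets far below 1 mDa, e.g. exchanging C₈ for H₄N₂O₂S shifts
the mass by 0.65 mDa and exchanging C₂₁ for H₁₂O₁₃S by 0.14 mDa, so a
heteroatom-first rule silently replaces exact CHONS matches above ~650 Da
with CHO imposters. Error-first assignment recovers every formula exactly
at zero mass error and degrades only through genuine ambiguity as noise
grows.

**Two routes, one answer.** `enumerate_candidates` is a direct brute-force
enumeration kept deliberately simple; `FormulaIndex` precomputes the
~2.4×10⁵ valid formulas once (about a second) and answers queries by binary
search on the mass column. The test suite asserts the two routes return
identical candidate lists; the index is the production path.

## Descriptors and classes

Per formula: O/C, H/C, DBE, NOSC = 4 − (4C + H − 3N − 2O − 2S)/C (−4 for
methane, +4 for CO₂), the modified aromaticity index
AI_mod = [1 + C − 0.5·O − S − 0.5·(N + H)]/(C − 0.5·O − S − N) with the
usual clamp to 0 when numerator or denominator is non-positive, the
oxygen-corrected unsaturation density (DBE − O)/C, and the neutral
monoisotopic mass. Compound classes are the seven van Krevelen boxes
(aliphatic/proteins, lipids, lignins/CRAM, unsaturated hydrocarbons,
carbohydrates, aromatic, tannins) tested in that fixed order with first
match winning, which resolves shared box edges deterministically; points
in no box are "other". Sample summaries weight every metric by intensity,
X_w = Σ Xᵢ·Iᵢ / Σ Iᵢ; the weighted m/z uses measured m/z when available
and the neutral mass otherwise. Intensities are never renormalized
upstream of this weighting.

## Molecular fate and flow tables

Fate is presence/absence logic on exact element-count identity: removed =
low \ high, produced = high \ low, resistant = the intersection. Intensity
plays no role in membership. Matching on formula identity rather than m/z
eliminates tolerance ambiguity; both treatments must therefore pass
through the same assignment configuration. Flow tables for Sankey-style
summaries bin one descriptor into terciles over the pooled pair (falling
back to two bins, with a warning, when there are too few distinct values)
and count records along class → bin → fate paths; each layer's counts sum
to the total record count, and bin edges are returned for transparency.

## PMD reactomics

Removed→produced pairs whose element-count difference equals a library
delta are counted as reaction events. The built-in library contains
oxygenation (+O, +O+2H), carboxyl losses (−CO₂, −C₂H₂O₂), chain cleavage
−CnHkOm for n = 3..6, k ∈ {2n, 2n+2}, m = 1..4 (both homologous series,
since the saturated and unsaturated forms are both observed in practice),
and dealkylation −CnH2n for n ≤ 3 with no oxygen change; dealkylation is
distinguished from cleavage by ΔO = 0 versus ΔO ≤ −1 with ΔC ≤ −3.
Libraries are plain CSV and fully overridable; events from user entries
outside the four named types count as "other". Pairing is exhaustive
many-to-many (no one-to-one assignment), and profiles are pair counts, not
intensity-weighted. A mass-difference matching mode (±0.5 mDa) exists for
unassigned peaks and agrees with the element-count mode on noise-free
data.

Chance matching is the known weakness of exhaustive PMD analysis: in a
dense, homologous-series-rich formula set, some removed×produced pairs
differ by a library delta coincidentally. Real spectra contain such pairs;
the synthetic generator deliberately excludes them (below), so recovered
profiles on synthetic data are cleaner than on real data.

## Fate classifier and Shapley interpretation

The classifier is XGBoost (`multi:softprob`, 3 classes) on 12 features:
O/C, H/C, NOSC, AI_mod, MW, DBE, (DBE−O)/C, nC, nH, nN, nO, nS. Labels can
be fate (removed/resistant/produced), elemental class (CHO/CHON/CHOS) or
compound category (lignins-CRAM/tannins/aromatic). Hyperparameters —
learning rate {0.05, 0.1, 0.3}, depth {3, 5, 7}, min child weight
{1, 3, 5} by default — are chosen by grid search minimizing mean
multinomial log loss under stratified k-fold CV (k = 10 default) on the
training 80%, then refit and scored on the stratified held-out 20%.
Determinism under a fixed seed is part of the contract (single-threaded
hist trees). Class imbalance is handled by stratification only.

Attributions are exact tree-path Shapley values in margin (pre-softmax)
space, computed with XGBoost's native TreeSHAP. Two numerical details
matter for the additivity contract (base + Σφ = margin to 1e−6 relative):
the native float32 running sums over hundreds of trees carry ~1e−6 noise,
so (i) per-round contributions are accumulated in float64 (TreeSHAP is
additive over trees), and (ii) the reference margin is re-derived in
float64 from the visited leaves of the model dump. Measured additivity
error is then a few 1e−7. Global importance is mean |φ| over samples and
classes, ties broken alphabetically. Because nO, nC and MW are partial
re-encodings of O/C, a planted two-driver rule on (O/C, NOSC) leaves a few
percent of total attribution on those correlated features; the drivers
still dominate every other feature severalfold. Dependence surfaces export
per-sample (x, φ, color) triples plus a 20×20 binned-mean grid for numeric
tests.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions end to end and returns the
ground truth for every stage.

* **Formula pool.** Unique CHNOS formulas rejection-sampled from the van
  Krevelen boxes. The default mixture is lignin/CRAM-dominated (55%, the
  partially oxidized O/C 0.1–0.6 core) with aliphatic (12%), tannin (10%),
  carbohydrate (8%), aromatic (7%) and small lipid/unsaturated fringes —
  the domain structure of coal leachates. Carbon number is a discretized
  Gaussian (mean 18, sd 6, range 5–40) and oxygen is capped at 13 per
  formula, emulating the wedge shape of natural DOM clouds (large
  molecules are not extremely oxygenated). The resulting pool has
  intensity-weighted m/z ≈ 380–420, O/C_w ≈ 0.44, H/C_w ≈ 1.23 and
  DBE_w ≈ 8.6, in the range such leachates show. Heteroatom counts are
  drawn with P(N = 0..3) = (0.45, 0.25, 0.20, 0.10) and
  P(S = 0..2) = (0.70, 0.25, 0.05), giving all four elemental classes in
  realistic proportion. Intensities are log-normal (meanlog 13.8 ≈ 10⁶
  counts median, sdlog 1.0).
* **Planted reactions.** 30% of formulas (default) are removed, with exact
  per-type event quotas from the mixture oxygenation 0.40 / cleavage 0.30 /
  dealkylation 0.15 / carboxyl 0.10 / other 0.05 ("other" is dehydration
  −H₂O). Each removed precursor emits one product that must be valid,
  inside the mass window, distinct from every pool formula and other
  product, and — so that each event's true reaction is identifiable from
  the emitted data — reachable from exactly one pool precursor via exactly
  one library delta. Real data offer no such guarantee; this is the main
  idealization of the generator and the reason exhaustive PMD matching
  recovers the planted mixture exactly here but not on real spectra.
* **Peak lists.** m/z = (M − 1.00727646)·(1 + ε) with ε ~ N(0, 0.3 ppm)
  by default; four common background masses are injected into both sample
  and blank lists to exercise blank subtraction. At 0.3 ppm, ~99.4% of
  10,000 formulas are recovered through the full
  clean-assign pipeline; the residual losses are genuine sub-ppm
  ambiguities (almost exclusively ≥14-oxygen formulas above 500 Da) plus
  the Gaussian tail beyond 1 ppm.
* **Planted fate rule.** Independently of the reaction layer, a
  multinomial-logistic rule on z-scored (O/C, NOSC) — scores −2(u+v), 1,
  +2(u+v) for removed/resistant/produced — draws labels and reports its
  Bayes-optimal accuracy E[max_k p_k] (≈ 0.78 at the defaults), the yard-
  stick for classifier recovery. Oxidized, high-NOSC formulas therefore
  tend to be produced and reduced ones removed, with a resistant middle
  band, mirroring the qualitative behavior of warmed leachates.

Passing tests on this generator demonstrate correctness of the pipeline's
logic and numerics, not instrument realities: no isotopologues, ion
suppression, resolution-dependent peak shapes, chance PMD pairs, or
replicate-to-replicate presence/absence flicker (replicate consensus
rules are not modeled).

## Numerical and design choices

* m/z window endpoints are inclusive (100 ≤ m/z ≤ 800).
* Blank matching uses ppm distance relative to the blank peak's m/z;
  default tolerance 1.0 ppm (calibration-grade accuracy); duplicate
  centroids within a list merge by intensity summation.
* The printed AI variant with the 0.5·O discount is implemented as the
  single function `ai_mod`; no separate unmodified-AI function exists.
* Descriptor binning for flow tables defaults to terciles; the planted
  logistic rule standardizes features before applying coefficients so the
  rule's strength is scale-free.
* Quota apportionment (class mixture, reaction mixture) uses largest
  remainders, so integer counts always sum exactly to the target.
* Grid-search and acceptance runs in the test suite use a reduced grid
  (η ∈ {0.1, 0.3}, depth ∈ {3, 5}, mcw 1, 5-fold, 150 trees) and problem
  sizes of 2,000–10,000 formulas; the library defaults remain the full
  grid with 10-fold CV and 300 trees.

## Known limitations

* At a 1 ppm tolerance, assignment above ~650 Da is intrinsically
  ambiguous for heteroatom- and oxygen-rich formulas (sub-mDa doublets);
  isotopologue verification, the standard remedy, is out of scope.
* Fate logic has no replicate-consensus rule; a formula flickering at the
  detection limit will oscillate between fates.
* Exhaustive PMD matching counts coincidental pairs on real data; treat
  profiles as relative, not absolute, reaction intensities.
* The classifier's attributions are explanatory, not causal; correlated
  descriptors share credit.
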