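# domtrace

Molecular-fingerprint analysis of dissolved organic matter (DOM) from
ultrahigh-resolution, negative-mode mass spectrometry — built for tracing
how a DOM pool (for example, coal-derived leachate in a warming aquifer)
changes between two treatments.

Given centroided peak lists for a reference and a perturbed sample plus a
procedural blank, the pipeline

1. **cleans** the peak lists (blank subtraction within a ppm tolerance,
   100–800 Da window),
2. **assigns** neutral CHNOS molecular formulas to [M−H]⁻ peaks
   (M = m/z + 1.00727646 Da) within a 1 ppm tolerance,
3. **computes** per-formula descriptors — O/C, H/C,
   DBE = C − H/2 + N/2 + 1, NOSC = 4 − (4C + H − 3N − 2O − 2S)/C,
   the modified aromaticity index
   AI_mod = [1 + C − 0.5·O − S − 0.5·(N + H)] / (C − 0.5·O − S − N),
   (DBE − O)/C — plus elemental (CHO/CHON/CHOS/CHONS) and van Krevelen
   compound classes, and intensity-weighted sample summaries
   X_w = Σ Xᵢ·Iᵢ / Σ Iᵢ,
4. **labels molecular fate**: formulas detected only in the reference are
   *removed*, only in the perturbed sample *produced*, in both *resistant*,
5. **infers reactions** by paired-mass-distance (PMD) matching of
   removed → produced pairs against a delta library (oxygenation +O/+O+2H,
   chain cleavage −CnHkOm, dealkylation −CnH2n, carboxyl losses
   −CO₂/−C₂H₂O₂, other), and
6. **models fate from structure** with a grid-searched, cross-validated
   XGBoost 3-class classifier on 12 descriptors, explained by exact
   tree-path Shapley attributions (global importance and 2-D dependence
   surfaces).

A fully ground-truthed synthetic-data generator
(`domtrace.synthetic_data`) stands in for instrument data: it plants known
reactions, fates and classifier rules so every stage can be verified
end-to-end.

## Worked example

```python
from domtrace.synthetic_data import SyntheticConfig, generate_dataset, planted_library
from domtrace.peak_io import subtract_blank, restrict_mz
from domtrace.formula_engine import assign_peaklist, MolecularFormula
from domtrace.descriptors import describe, weighted_summary
from domtrace.fate import classify_fate, fate_counts
from domtrace.reactomics import match_pairs, pmd_profile

ds = generate_dataset(SyntheticConfig(seed=42, n_formulas=2000))

def process(pl):
    pl = restrict_mz(subtract_blank(pl, ds.blank, tol_ppm=1.0), 100, 800)
    return assign_peaklist(pl)

low, high = process(ds.peaklist_low), process(ds.peaklist_high)
print(f"assigned formulas: {len(low)} at 25 degC, {len(high)} at 50 degC")

s = weighted_summary(describe(low))
print(f"25 degC summary: n={s.molecular_number}  CHO={s.cho} CHON={s.chon} "
      f"CHOS={s.chos} CHONS={s.chons}")
print(f"  H/C_w={s.h_c_w:.3f}  O/C_w={s.o_c_w:.3f}  DBE_w={s.dbe_w:.3f}  "
      f"NOSC_w={s.nosc_w:.3f}  m/z_w={s.mz_w:.0f}  AI_w={s.ai_w:.3f}")

to_set = lambda df: {MolecularFormula(int(r.c), int(r.h), int(r.n), int(r.o), int(r.s))
                     for r in df.itertuples(index=False)}
fates = classify_fate(to_set(low), to_set(high))
n_rm, n_rs, n_pr = fate_counts(fates)
print(f"fate: removed={n_rm}  resistant={n_rs}  produced={n_pr}")

removed = {f for f, v in fates.items() if v == "removed"}
produced = {f for f, v in fates.items() if v == "produced"}
profile = pmd_profile(match_pairs(removed, produced, planted_library()))
print("reaction profile:", {k: round(v, 3) for k, v in profile.fractions.items()})
```

Output:

```
assigned formulas: 1997 at 25 degC, 2000 at 50 degC
25 degC summary: n=1997  CHO=598 CHON=779 CHOS=277 CHONS=343
  H/C_w=1.271  O/C_w=0.440  DBE_w=8.056  NOSC_w=-0.143  m/z_w=371  AI_w=0.281
fate: removed=603  resistant=1394  produced=606
reaction profile: {'oxygenation': 0.395, 'cleavage': 0.304, 'dealkylation': 0.15,
                   'carboxyl': 0.101, 'other': 0.049}
```

Reading this: of 2000 planted formulas, blank subtraction and assignment
recover nearly all (three 25 °C peaks were lost to blank overlap/ambiguity
at 0.3 ppm mass error); the weighted metrics summarize the sample the way
leachate studies tabulate them; the fate split recovers the planted 30%
removal; and the reaction-type profile recovers the planted
0.40/0.30/0.15/0.10/0.05 mixture to within the mass-error-induced noise.

The same steps are available from the shell:

```bash
domtrace simulate --seed 42 --n-formulas 2000 --out-dir sim/
domtrace assign --sample sim/peaks_T_low.csv --blank sim/peaks_blank.csv --out low.csv
domtrace describe --in low.csv --out descriptors.csv --summary summary.json
domtrace fate --low low_formulas.csv --high high_formulas.csv
domtrace pmd --removed removed.csv --produced produced.csv
domtrace train --features descriptors_with_fate.csv --dimension fate --seed 7
```

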