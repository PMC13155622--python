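import numpy as np
import pandas as pd
import pytest

from domtrace.descriptors import compound_class, describe
from domtrace.formula_engine import MolecularFormula, assign_peaklist, is_chemically_valid
from domtrace.synthetic_data import (
    SyntheticConfig,
    apply_planted_reactions,
    formulas_to_peaklist,
    generate_dataset,
    plant_fate_rule,
    planted_library,
    sample_formula_pool,
)


def formulas_of(df: pd.DataFrame) -> set[MolecularFormula]:
    return {
        MolecularFormula(int(r.c), int(r.h), int(r.n), int(r.o), int(r.s))
        for r in df.itertuples(index=False)
    }


class TestSampleFormulaPool:
    def test_exact_count_and_uniqueness(self):
        cfg = SyntheticConfig(seed=3, n_formulas=300)
        pool = sample_formula_pool(cfg)
        assert len(pool) == 300
        assert len(formulas_of(pool[["c", "h", "n", "o", "s"]])) == 300

    def test_single_class_mixture_satisfies_box(self):
        cfg = SyntheticConfig(
            seed=3, n_formulas=60, class_mixture={"lipids": 1.0}
        )
        pool = sample_formula_pool(cfg)
        for r in pool.itertuples(index=False):
            assert compound_class(r.h / r.c, r.o / r.c) == "lipids"

    def test_all_formulas_chemically_valid(self):
        pool = sample_formula_pool(SyntheticConfig(seed=4, n_formulas=200))
        for f in formulas_of(pool[["c", "h", "n", "o", "s"]]):
            assert is_chemically_valid(f)

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=8, n_formulas=150)
        assert sample_formula_pool(cfg).equals(sample_formula_pool(cfg))

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, class_mixture={"lipids": 0.5})


class TestApplyPlantedReactions:
    def test_oxygenation_only_mixture(self):
        cfg = SyntheticConfig(
            seed=5,
            n_formulas=200,
            fraction_removed=0.2,
            reaction_mixture={"oxygenation": 1.0},
        )
        pool = sample_formula_pool(cfg)
        set_low, set_high, truth = apply_planted_reactions(pool, cfg)
        for e in truth.events:
            assert e.entry.rtype == "oxygenation"
            assert e.product.o - e.precursor.o == 1

    def test_zero_removed_fraction_all_resistant(self):
        cfg = SyntheticConfig(seed=5, n_formulas=100, fraction_removed=0.0)
        pool = sample_formula_pool(cfg)
        set_low, set_high, truth = apply_planted_reactions(pool, cfg)
        assert set_low == set_high
        assert all(v == "resistant" for v in truth.fates.values())

    def test_quotas_match_mixture(self, small_dataset):
        quotas = small_dataset.truth.reaction_quotas
        n_removed = sum(quotas.values())
        mix = SyntheticConfig(seed=0).reaction_mixture
        for t, q in quotas.items():
            assert abs(q - mix[t] * n_removed) <= 1.0

    def test_fate_sets_disjointness(self, small_dataset):
        ds = small_dataset
        removed = {f for f, v in ds.truth.fates.items() if v == "removed"}
        produced = {f for f, v in ds.truth.fates.items() if v == "produced"}
        assert removed <= ds.set_low and not removed & ds.set_high
        assert produced <= ds.set_high and not produced & ds.set_low


class TestFormulasToPeaklist:
    def test_noise_free_round_trip_through_assignment(self, small_dataset):
        pool = small_dataset.pool
        fs = sorted(formulas_of(pool[["c", "h", "n", "o", "s"]]))
        pl = formulas_to_peaklist(fs, np.ones(len(fs)), ppm_sigma=0.0, seed=1)
        rec = formulas_of(assign_peaklist(pl)[["c", "h", "n", "o", "s"]])
        assert rec == set(fs)

    def test_deterministic_under_seed(self):
        fs = [MolecularFormula(10, 12, 0, 4, 0), MolecularFormula(12, 16, 0, 5, 0)]
        a = formulas_to_peaklist(fs, [1.0, 2.0], 0.5, seed=9)
        b = formulas_to_peaklist(fs, [1.0, 2.0], 0.5, seed=9)
        assert list(a.mz) == list(b.mz)

    def test_contaminants_appended(self):
        fs = [MolecularFormula(10, 12, 0, 4, 0)]
        pl = formulas_to_peaklist(
            fs, [1.0], 0.0, seed=1, extra_mz=[255.233], extra_intensity=[9.0]
        )
        assert len(pl) == 2


class TestPlantFateRule:
    def _records(self, n, seed=0):
        pool = sample_formula_pool(SyntheticConfig(seed=seed, n_formulas=n))
        return describe(pool)

    def test_zero_coefficients_give_chance_labels(self):
        recs = self._records(3000)
        zero = {k: (0.0, 0.0, 0.0) for k in ("removed", "resistant", "produced")}
        labels, bayes = plant_fate_rule(recs, zero, seed=2)
        assert bayes == pytest.approx(1 / 3)
        props = np.bincount(labels, minlength=3) / len(labels)
        assert np.allclose(props, 1 / 3, atol=0.05)

    def test_huge_coefficients_deterministic(self):
        recs = self._records(500)
        big = {
            "removed": (-80.0, -80.0, 0.0),
            "resistant": (0.0, 0.0, 0.0),
            "produced": (80.0, 80.0, 0.0),
        }
        labels, bayes = plant_fate_rule(recs, big, seed=2)
        assert bayes > 0.99

    def test_label_proportions_match_generating_probabilities(self):
        recs = self._records(5000)
        labels, bayes = plant_fate_rule(recs, seed=3)
        # re-derive generating probabilities independently
        u = recs["o_c"].to_numpy()
        v = recs["nosc"].to_numpy()
        u = (u - u.mean()) / u.std()
        v = (v - v.mean()) / v.std()
        s = np.column_stack([-2 * (u + v), np.ones(len(u)), 2 * (u + v)])
        p = np.exp(s - s.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        expected = p.mean(axis=0)
        observed = np.bincount(labels, minlength=3) / len(labels)
        se = np.sqrt(expected * (1 - expected) / len(labels))
        assert np.all(np.abs(observed - expected) < 2.5 * se + 1e-3)
        assert 1 / 3 < bayes <= 1.0


class TestFullClosure:
    def test_generate_dataset_deterministic(self):
        cfg = SyntheticConfig(seed=21, n_formulas=120, ppm_sigma=0.2)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert list(a.peaklist_low.mz) == list(b.peaklist_low.mz)
        assert a.truth.fates == b.truth.fates

    def test_blank_contains_contaminants_shared_with_samples(self, small_dataset):
        ds = small_dataset
        blank_mz = set(ds.blank.mz)
        assert blank_mz <= set(ds.peaklist_low.mz)
        assert blank_mz <= set(ds.peaklist_high.mz)

    def test_truth_consistent_with_emitted_sets(self, small_dataset):
        ds = small_dataset
        for f, v in ds.truth.fates.items():
            if v == "removed":
                assert f in ds.set_low and f not in ds.set_high
            elif v == "produced":
                assert f in ds.set_high and f not in ds.set_low
            else:
                assert f in ds.set_low and f in ds.set_high
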