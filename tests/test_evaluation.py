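"""Assay math, folds, Spearman, cross-validation and class contrasts."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stratvep.alphabet import AA20, Mutation
from stratvep.evaluation import (
    VariantRecord,
    compare_classes,
    compute_lod,
    cross_validate,
    make_position_stratified_folds,
    make_random_folds,
    normalize_plate,
    normalize_screen,
    rank_sum_test,
    spearman,
)
from stratvep.models import ModelContext


class TestPlateMath:
    def test_hand_arithmetic(self):
        assert normalize_plate([0.30, 0.32, 0.31], [0.10, 0.12]) == pytest.approx(0.20)

    def test_null_signal(self):
        assert normalize_plate([0.11, 0.11, 0.11], [0.10, 0.12]) == pytest.approx(0.0)

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            normalize_plate([], [0.1])
        with pytest.raises(ValueError):
            normalize_plate([0.1], [])

    def test_lod_formula(self):
        blanks = [0.010, 0.012, 0.008, 0.014]
        assert compute_lod(blanks) == pytest.approx(3 * np.std(blanks, ddof=1))
        assert compute_lod([0.01, 0.01, 0.01]) == 0.0

    def test_lod_homogeneity(self):
        blanks = np.array([0.01, 0.013, 0.009])
        assert compute_lod(blanks * 5) == pytest.approx(5 * compute_lod(blanks))
        with pytest.raises(ValueError):
            compute_lod([0.01])


class TestFolds:
    def test_random_folds_exact_partition(self):
        folds = make_random_folds(100, k=10, seed=1)
        assert np.bincount(folds).tolist() == [10] * 10
        assert np.array_equal(make_random_folds(100, 10, seed=1), folds)  # deterministic
        with pytest.raises(ValueError):
            make_random_folds(5, k=10)

    @staticmethod
    def single_mut_records(counts: dict[int, int]) -> list[VariantRecord]:
        recs = []
        for pos, n in counts.items():
            for j in range(n):
                alt = AA20[(j + 1) % 20] if AA20[(j + 1) % 20] != "A" else "C"
                recs.append(
                    VariantRecord(
                        variant_id=f"p{pos}_{j}",
                        mutations=frozenset({Mutation(pos, "A", alt)}),
                        activity=0.0,
                    )
                )
        return recs

    def test_stratified_exact_split_for_k_variants(self):
        recs = self.single_mut_records({7: 10})
        folds = make_position_stratified_folds(recs, k=10, seed=0)
        assert sorted(folds) == list(range(10))  # one variant per fold

    def test_no_test_only_positions(self):
        """Every position with >= 2 variants appears in >= 2 folds, so it is
        always present in the training complement of any test fold."""
        rng = np.random.default_rng(2)
        counts = {pos: int(rng.integers(2, 15)) for pos in range(1, 40)}
        recs = self.single_mut_records(counts)
        folds = make_position_stratified_folds(recs, k=10, seed=3)
        by_pos = {}
        for rec, f in zip(recs, folds):
            by_pos.setdefault(next(iter(rec.positions)), set()).add(f)
        for pos, fold_set in by_pos.items():
            assert len(fold_set) >= 2
            assert len(fold_set) == min(counts[pos], 10)

    def test_partition_property_and_determinism(self):
        recs = self.single_mut_records({p: 5 for p in range(1, 21)})
        folds = make_position_stratified_folds(recs, k=10, seed=4)
        assert len(folds) == len(recs)
        assert set(folds) <= set(range(10))
        assert np.array_equal(make_position_stratified_folds(recs, 10, seed=4), folds)

    def test_singleton_position_flagged(self):
        recs = self.single_mut_records({1: 1, 2: 12})
        with pytest.warns(UserWarning, match="single variant"):
            make_position_stratified_folds(recs, k=10, seed=0)

    def test_multi_mutation_variant_rejected(self):
        rec = VariantRecord(
            "x", frozenset({Mutation(1, "A", "C"), Mutation(2, "A", "C")}), activity=0.0
        )
        with pytest.raises(ValueError):
            make_position_stratified_folds([rec], k=2)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_midrank_oracle_under_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=40).astype(float)  # heavy ties
        y = x + rng.integers(0, 3, size=40)

        def midrank(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        expected = np.corrcoef(midrank(x), midrank(y))[0, 1]
        assert spearman(x, y) == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))
        assert spearman(x, y**3) == pytest.approx(spearman(x, y))

    def test_constant_input_flagged_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_length_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


def _records_from_library(reference, positions, n, rng, activity_fn):
    recs = []
    for i in range(n):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(positions, size=k, replace=False)
        muts = set()
        for p in chosen:
            wt = reference[p - 1]
            alt = rng.choice([a for a in AA20 if a != wt])
            muts.add(Mutation(int(p), wt, alt))
        muts = frozenset(muts)
        recs.append(VariantRecord(f"v{i}", muts, activity=activity_fn(muts)))
    return recs


class TestCrossValidate:
    REF = "".join(np.random.default_rng(9).choice(list(AA20), size=40))

    def test_realizable_target_scores_one(self):
        """Noiseless activity linear in the indicator encoding -> rho = 1.

        Positions are cycled so every indicator column is seen in every
        training complement (a position absent from training would otherwise
        get zero weight and break realizability).
        """
        rng = np.random.default_rng(10)
        effects = {p: rng.normal() for p in range(1, 41)}
        recs = []
        for i in range(120):
            positions = [(2 * i) % 40 + 1, (2 * i + 1) % 40 + 1]
            muts = frozenset(
                Mutation(p, self.REF[p - 1],
                         "W" if self.REF[p - 1] != "W" else "F")
                for p in positions
            )
            recs.append(VariantRecord(f"v{i}", muts,
                                      activity=sum(effects[p] for p in positions)))
        folds = make_random_folds(120, k=10, seed=0)
        scores = cross_validate(
            "residue_agnostic", recs, folds, ModelContext(reference=self.REF, alpha=1e-6)
        )
        assert len(scores) == 10
        assert min(scores) > 0.99

    def test_null_target_scores_near_zero(self):
        rng = np.random.default_rng(11)
        recs = _records_from_library(
            self.REF, np.arange(1, 41), 120, rng, lambda muts: float(rng.normal())
        )
        folds = make_random_folds(120, k=10, seed=1)
        scores = cross_validate(
            "residue_agnostic", recs, folds, ModelContext(reference=self.REF)
        )
        assert abs(np.mean(scores)) < 0.25  # Monte-Carlo noise around zero

    def test_small_fold_rejected(self):
        rng = np.random.default_rng(12)
        recs = _records_from_library(self.REF, np.arange(1, 41), 8, rng, lambda m: 0.1)
        with pytest.raises(ValueError):
            cross_validate("residue_agnostic", recs, np.arange(8) % 4,
                           ModelContext(reference=self.REF))


class TestCompareClasses:
    def test_identical_scores_null(self):
        r = compare_classes([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_clear_separation(self):
        r = compare_classes([0.8, 0.81, 0.79], [0.2, 0.21, 0.19])
        assert r.significant and r.mean_difference == pytest.approx(0.6)

    def test_matches_textbook_welch(self):
        a = [2.1, 2.5, 2.3, 2.2]
        b = [1.8, 1.9, 2.0]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        r = compare_classes(a, b)
        assert r.t_statistic == pytest.approx(float(t))
        assert r.p_value == pytest.approx(float(p))

    def test_antisymmetric(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0.6, 0.1, 10), rng.normal(0.4, 0.1, 10)
        r1, r2 = compare_classes(a, b), compare_classes(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_nan_scores_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            r = compare_classes([0.5, 0.6, np.nan], [0.4, 0.5, 0.45])
        assert r.n_positive == 2


class TestRankSum:
    def test_complete_separation(self):
        a = list(np.linspace(10, 11, 12))
        b = list(np.linspace(0, 1, 12))
        r = rank_sum_test(a, b)
        assert r.p_value < 0.001 and r.significant

    def test_identical_samples(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        r = rank_sum_test(x, x)
        assert r.p_value > 0.9

    def test_matches_exact_enumeration_on_small_instance(self):
        """Normal-approximation p close to the exact permutation-null p."""
        a, b = [3.1, 4.2, 6.5, 7.1], [1.0, 2.2, 2.9, 5.0]
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2
        n = len(pooled)
        us = []
        for comb in itertools.combinations(range(n), len(a)):
            u = ranks[list(comb)].sum() - len(a) * (len(a) + 1) / 2
            us.append(u)
        us = np.array(us)
        mu = len(a) * len(b) / 2
        exact_p = np.mean(np.abs(us - mu) >= abs(u_obs - mu))
        r = rank_sum_test(a, b)
        assert r.statistic == pytest.approx(u_obs)
        assert r.p_value == pytest.approx(exact_p, abs=0.05)

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning, match="tied"):
            r = rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])
        assert not r.significant


def test_normalize_screen_roundtrip(tmp_path):
    import pandas as pd

    raw = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "b1", "b2"],
            "mutations": ["A1C", "A1D;G3W", "", ""],
            "plate": ["P1"] * 4,
            "rep1": [0.30, 0.25, 0.10, 0.11],
            "rep2": [0.32, 0.24, 0.09, 0.12],
            "rep3": [0.31, 0.26, 0.11, 0.10],
            "is_blank": [False, False, True, True],
        }
    )
    path = tmp_path / "screen.csv"
    raw.to_csv(path, index=False)
    from stratvep.evaluation import read_screen_csv

    records, lods = normalize_screen(read_screen_csv(path))
    assert len(records) == 2
    blank_mean = np.mean([0.10, 0.09, 0.11, 0.11, 0.12, 0.10])
    assert records[0].activity == pytest.approx(np.mean([0.30, 0.32, 0.31]) - blank_mean)
    assert "P1" in lods and lods["P1"] > 0
    assert records[1].mutations == frozenset({Mutation(1, "A", "D"), Mutation(3, "G", "W")})
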