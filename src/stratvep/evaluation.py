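"""Assay preprocessing, cross-validation and predictability contrasts.

Activity preprocessing follows the plate protocol: each variant is measured
in triplicate, two wells per plate hold enzyme-free blanks, and the
normalized activity is mean(replicates) − mean(plate blanks). Assay
sensitivity is summarized per plate as LOD = 3·σ_blank.

Model evaluation uses 10-fold cross-validation with Spearman rank
correlation between predictions and measurements per test fold. For
single-mutation data, folds are position-stratified: each position's
variants are dealt across folds, so no test fold contains positions unseen
in its training complement (for positions with ≥ 2 variants). Predictability
contrasts between a characteristic's positive and negative variant classes
use Welch's two-sample t-test on the fold-score distributions; activity
distributions between classes are contrasted with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .alphabet import Mutation, apply_mutations, parse_mutations
from .models import ModelContext, make_model
from .partitioning import CHARACTERISTICS, BinaryProfile, split_variants

__all__ = [
    "VariantRecord",
    "ContrastResult",
    "RankSumResult",
    "EvaluationReport",
    "normalize_plate",
    "compute_lod",
    "normalize_screen",
    "make_random_folds",
    "make_position_stratified_folds",
    "spearman",
    "cross_validate",
    "compare_classes",
    "rank_sum_test",
    "predictability_report",
    "read_screen_csv",
]


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    mutations: frozenset[Mutation]
    replicates: tuple[float, ...] = ()
    plate: str = ""
    activity: float | None = None

    def sequence(self, reference: str) -> str:
        return apply_mutations(reference, self.mutations)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)


def normalize_plate(replicates: Sequence[float], blanks: Sequence[float]) -> float:
    """mean(replicates) − mean(blanks)."""
    if len(replicates) == 0 or len(blanks) == 0:
        raise ValueError("need at least one replicate and one blank")
    return float(np.mean(replicates) - np.mean(blanks))


def compute_lod(blanks: Sequence[float]) -> float:
    """Limit of detection for one plate: 3 × sample SD of its blank wells."""
    if len(blanks) < 2:
        raise ValueError("need at least 2 blank values")
    return 3.0 * float(np.std(blanks, ddof=1))


def read_screen_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw plate table: variant_id, mutations, plate, rep1.., is_blank."""
    df = pd.read_csv(path, dtype={"variant_id": str, "plate": str})
    required = {"variant_id", "mutations", "plate", "is_blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen CSV missing columns: {sorted(missing)}")
    if not any(c.startswith("rep") for c in df.columns):
        raise ValueError("screen CSV has no replicate columns (rep1..)")
    return df


def normalize_screen(raw: pd.DataFrame) -> tuple[list[VariantRecord], dict[str, float]]:
    """Turn raw plate measurements into normalized records plus per-plate LODs.

    Blank rows (``is_blank``) are averaged per plate and subtracted from each
    variant's replicate mean on that plate.
    """
    rep_cols = [c for c in raw.columns if c.startswith("rep")]
    records: list[VariantRecord] = []
    lods: dict[str, float] = {}
    for plate, grp in raw.groupby("plate", sort=True):
        blanks = grp[grp["is_blank"].astype(bool)]
        if blanks.empty:
            raise ValueError(f"plate {plate} has no blank wells")
        blank_means = blanks[rep_cols].mean(axis=1).to_numpy()
        blank_values = blanks[rep_cols].to_numpy().ravel()
        if len(blank_values) >= 2:
            lods[str(plate)] = compute_lod(blank_values)
        for _, row in grp[~grp["is_blank"].astype(bool)].iterrows():
            reps = tuple(float(row[c]) for c in rep_cols if np.isfinite(row[c]))
            records.append(
                VariantRecord(
                    variant_id=str(row["variant_id"]),
                    mutations=parse_mutations(str(row["mutations"]) if pd.notna(row["mutations"]) else ""),
                    replicates=reps,
                    plate=str(plate),
                    activity=normalize_plate(reps, blank_means),
                )
            )
    return records, lods


def make_random_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Near-equal random partition of ``range(n)`` into k folds."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    rng.shuffle(folds)
    return folds


def make_position_stratified_folds(
    records: Sequence[VariantRecord], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Fold assignment for single-mutation records, stratified by position.

    Each position's variants are shuffled and dealt round-robin from a random
    starting fold, so every position with ≥ k variants appears in every fold
    and every position with ≥ 2 variants appears in at least two folds —
    hence never only in a test fold. Positions with a single variant land in
    one fold and are flagged with a warning.
    """
    rng = np.random.default_rng(seed)
    by_position: dict[int, list[int]] = {}
    for idx, rec in enumerate(records):
        pos = rec.positions
        if len(pos) != 1:
            raise ValueError(
                f"position-stratified folds require single-mutation variants; "
                f"{rec.variant_id} has {len(pos)} mutated positions"
            )
        by_position.setdefault(next(iter(pos)), []).append(idx)
    folds = np.empty(len(records), dtype=int)
    singletons = 0
    for pos in sorted(by_position):
        members = np.array(by_position[pos])
        rng.shuffle(members)
        start = int(rng.integers(k))
        for j, idx in enumerate(members):
            folds[idx] = (start + j) % k
        if len(members) < 2:
            singletons += 1
    if singletons:
        warnings.warn(f"{singletons} position(s) have a single variant and occupy only one fold")
    return folds


def spearman(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Spearman rank correlation; NaN (with a warning) for constant input."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.allclose(predicted, predicted[0]) or np.allclose(observed, observed[0]):
        warnings.warn("Spearman undefined for constant input; returning NaN")
        return float("nan")
    return float(stats.spearmanr(predicted, observed).statistic)


def cross_validate(
    model,
    records: Sequence[VariantRecord],
    folds: np.ndarray,
    context: ModelContext,
) -> list[float]:
    """Per-fold test Spearman for one model over one record set.

    ``model`` is a model name (see :func:`stratvep.models.make_model`) or a
    ready pipeline; a fresh clone is fitted per fold on the complement.
    """
    pipeline = make_model(model, context) if isinstance(model, str) else model
    folds = np.asarray(folds)
    if len(folds) != len(records):
        raise ValueError("fold assignment length mismatch")
    seqs = [r.sequence(context.reference) for r in records]
    y = np.array([r.activity for r in records], dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("records must carry normalized activities")
    scores: list[float] = []
    for f in sorted(set(folds.tolist())):
        test = folds == f
        if test.sum() < 3:
            raise ValueError(f"fold {f} too small to score (<3)")
        est = clone(pipeline)
        est.fit([s for s, t in zip(seqs, test) if not t], y[~test])
        pred = np.asarray(est.predict([s for s, t in zip(seqs, test) if t]))
        scores.append(spearman(pred, y[test]))
    return scores


@dataclass(frozen=True)
class ContrastResult:
    t_statistic: float
    p_value: float
    mean_difference: float  # mean(positive) − mean(negative)
    significant: bool
    n_positive: int
    n_negative: int


def compare_classes(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> ContrastResult:
    """Welch's independent-samples t-test between two fold-score samples.

    NaN scores (constant-prediction folds) are dropped with a warning.
    """
    a = np.asarray(scores_pos, dtype=float)
    b = np.asarray(scores_neg, dtype=float)
    dropped = int(np.isnan(a).sum() + np.isnan(b).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} NaN fold score(s) from the contrast")
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite scores per class")
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        equal = np.isclose(a.mean(), b.mean())
        return ContrastResult(
            t_statistic=0.0 if equal else float("inf") * np.sign(a.mean() - b.mean()),
            p_value=1.0 if equal else 0.0,
            mean_difference=float(a.mean() - b.mean()),
            significant=not equal,
            n_positive=len(a),
            n_negative=len(b),
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ContrastResult(
        t_statistic=float(t),
        p_value=float(p),
        mean_difference=float(a.mean() - b.mean()),
        significant=bool(p < 0.05),
        n_positive=len(a),
        n_negative=len(b),
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    significant: bool


def rank_sum_test(activities_pos: Sequence[float], activities_neg: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected)."""
    a = np.asarray(activities_pos, dtype=float)
    b = np.asarray(activities_neg, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.allclose(np.concatenate([a, b]).std(), 0):
        warnings.warn("all observations tied; rank-sum test degenerate")
        return RankSumResult(statistic=float(len(a) * len(b) / 2), p_value=1.0, significant=False)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), significant=bool(res.pvalue < 0.05)
    )


def _stratified_subsample(recs: list, n_target: int, rng: np.random.Generator) -> list:
    """Subsample to ``n_target`` preserving the mutation-count mix."""
    by_m: dict[int, list[int]] = {}
    for i, r in enumerate(recs):
        by_m.setdefault(len(r.mutations), []).append(i)
    frac = n_target / len(recs)
    chosen: list[int] = []
    quotas = {m: frac * len(idx) for m, idx in by_m.items()}
    take = {m: int(np.floor(q)) for m, q in quotas.items()}
    # distribute the remainder to the largest fractional parts (deterministic)
    short = n_target - sum(take.values())
    for m in sorted(quotas, key=lambda m: quotas[m] - take[m], reverse=True)[:short]:
        take[m] += 1
    for m, idx in by_m.items():
        picked = rng.choice(len(idx), size=take[m], replace=False)
        chosen.extend(idx[i] for i in picked)
    return [recs[i] for i in sorted(chosen)]


@dataclass
class EvaluationReport:
    """Fold scores and contrasts for every model × characteristic × class."""

    fold_scores: dict[tuple[str, str, str], list[float]]  # (model, characteristic, class) -> scores
    contrasts: dict[tuple[str, str], ContrastResult]  # (model, characteristic)
    activity_tests: dict[str, RankSumResult]  # characteristic
    excluded_counts: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for (model, char, cls), scores in sorted(self.fold_scores.items()):
            for k, s in enumerate(scores):
                rows.append(
                    {"model": model, "characteristic": char, "class": cls, "fold": k, "spearman": s}
                )
        return pd.DataFrame(rows)

    def contrasts_frame(self) -> pd.DataFrame:
        rows = []
        for (model, char), c in sorted(self.contrasts.items()):
            rows.append(
                {
                    "model": model,
                    "characteristic": char,
                    "t_statistic": c.t_statistic,
                    "p_value": c.p_value,
                    "mean_difference": c.mean_difference,
                    "significant": c.significant,
                }
            )
        return pd.DataFrame(rows)

    def mean_score(self, model: str, characteristic: str, cls: str) -> float:
        return float(np.nanmean(self.fold_scores[(model, characteristic, cls)]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "excluded_counts": self.excluded_counts,
            "fold_scores": [
                {"model": m, "characteristic": c, "class": k, "scores": s}
                for (m, c, k), s in sorted(self.fold_scores.items())
            ],
            "contrasts": [
                {"model": m, "characteristic": c, **vars(r)}
                for (m, c), r in sorted(self.contrasts.items())
            ],
            "activity_tests": {c: vars(r) for c, r in sorted(self.activity_tests.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def predictability_report(
    records: Sequence[VariantRecord],
    binary: BinaryProfile,
    model_names: Sequence[str],
    context: ModelContext,
    characteristics: Sequence[str] = CHARACTERISTICS,
    k: int = 10,
    seed: int = 0,
    balance_classes: bool = True,
) -> EvaluationReport:
    """Cross of model × characteristic × class with fold scores and contrasts.

    Folds are shared across models (one seeded assignment per class) so model
    comparisons are paired on identical splits. With ``balance_classes`` the
    larger class is subsampled (seeded) to the smaller one's size, so a
    contrast never reflects one class simply having more training data.
    """
    fold_scores: dict[tuple[str, str, str], list[float]] = {}
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    activity_tests: dict[str, RankSumResult] = {}
    excluded_counts: dict[str, int] = {}
    balance_rng = np.random.default_rng(seed + 2_000_003)
    for char in characteristics:
        pos_recs, neg_recs, excluded = split_variants(records, binary, char)
        excluded_counts[char] = len(excluded)
        if balance_classes:
            n_min = min(len(pos_recs), len(neg_recs))
            for cls_recs in (pos_recs, neg_recs):
                if len(cls_recs) > n_min:
                    cls_recs[:] = _stratified_subsample(cls_recs, n_min, balance_rng)
        for cls, recs in (("positive", pos_recs), ("negative", neg_recs)):
            if len(recs) < k:
                raise ValueError(
                    f"class {char}/{cls} has {len(recs)} records, fewer than {k} folds"
                )
        activity_tests[char] = rank_sum_test(
            [r.activity for r in pos_recs], [r.activity for r in neg_recs]
        )
        folds_pos = make_random_folds(len(pos_recs), k=k, seed=seed)
        folds_neg = make_random_folds(len(neg_recs), k=k, seed=seed + 1)
        for model in model_names:
            sp = cross_validate(model, pos_recs, folds_pos, context)
            sn = cross_validate(model, neg_recs, folds_neg, context)
            fold_scores[(model, char, "positive")] = sp
            fold_scores[(model, char, "negative")] = sn
            contrasts[(model, char)] = compare_classes(sp, sn)
    return EvaluationReport(
        fold_scores=fold_scores,
        contrasts=contrasts,
        activity_tests=activity_tests,
        excluded_counts=excluded_counts,
        config={
            "models": list(model_names),
            "characteristics": list(characteristics),
            "folds": k,
            "seed": seed,
            "alpha": context.alpha,
            "n_components": context.n_components,
            "significance_level": 0.05,
            "multiple_testing_correction": "none",
        },
    )
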