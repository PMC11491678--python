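"""The four variant-effect regressors as scikit-learn pipelines.

==================  =================  ==============  =============
model               encoding           regressor       dimensionality
==================  =================  ==============  =============
residue_agnostic    indicator          ridge           L
pls                 one-hot            PLS (20 comps)  L*20
augmented_potts     one-hot + energy   ridge           L*20 + 1
embedding           embedder-defined   ridge           embedder-defined
==================  =================  ==============  =============

Ridge regularization defaults to alpha = 0.1, selected from the grid
{0.001, 0.01, 0.1, 0.9} by best mean cross-validated Spearman across
datasets (``select_alpha``). The Potts-energy column is standardized on the
training fold before ridge: one raw-scale column against thousands of binary
columns would otherwise be regularized away. One-hot/indicator features are
used unstandardized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline

from .encoding import (
    AugmentedPottsEncoder,
    Embedder,
    EmbeddingEncoder,
    IndicatorEncoder,
    OneHotEncoder,
)
from .potts import PottsModel

__all__ = [
    "MODEL_NAMES",
    "ModelContext",
    "LinearModel",
    "fit_ridge",
    "fit_pls",
    "select_alpha",
    "make_model",
    "ALPHA_GRID",
]

MODEL_NAMES = ("residue_agnostic", "pls", "augmented_potts", "embedding")
ALPHA_GRID = (0.001, 0.01, 0.1, 0.9)


@dataclass
class ModelContext:
    """Everything the encoding schemes may need to build a model."""

    reference: str
    potts: PottsModel | None = None
    embedder: Embedder | None = None
    alpha: float = 0.1
    n_components: int = 20


@dataclass
class LinearModel:
    """Serializable flat view of a fitted linear regressor."""

    weights: np.ndarray
    intercept: float
    scheme: str
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all() or not np.isfinite(self.intercept):
            raise ValueError("non-finite model parameters")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scheme": self.scheme,
                    "intercept": self.intercept,
                    "weights": self.weights.tolist(),
                    "meta": self.meta,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            intercept=float(d["intercept"]),
            scheme=d["scheme"],
            meta=d.get("meta", {}),
        )


def fit_ridge(X: np.ndarray, y: np.ndarray, alpha: float, scheme: str = "ridge") -> LinearModel:
    """L2-penalized least squares with unpenalized intercept (closed form)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    reg = Ridge(alpha=alpha, solver="cholesky" if alpha > 0 else "svd")
    if alpha == 0:
        from sklearn.linear_model import LinearRegression

        reg = LinearRegression()
    reg.fit(X, y)
    return LinearModel(
        weights=np.ravel(reg.coef_),
        intercept=float(reg.intercept_),
        scheme=scheme,
        meta={"alpha": alpha, "n_train": int(len(y))},
    )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int = 20, scheme: str = "pls") -> LinearModel:
    """Latent-component (NIPALS) regression, expressed as linear weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(y.std(), 0):
        raise ValueError("zero-variance response")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(f"n_components truncated from {n_components} to {max_comp}")
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    # flatten to y = X @ w + b (sklearn's PLS predict centers X internally)
    intercept = float(np.ravel(pls.predict(np.zeros((1, X.shape[1]))))[0])
    return LinearModel(
        weights=np.ravel(pls.coef_),
        intercept=intercept,
        scheme=scheme,
        meta={"n_components": n_components, "n_train": int(len(y))},
    )


class _EnergyColumnScaler(TransformerMixin, BaseEstimator):
    """Center and unit-scale the last column on the training fold only."""

    def fit(self, X, y=None):
        last = np.asarray(X)[:, -1]
        self.mean_ = float(last.mean())
        self.scale_ = float(last.std()) or 1.0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        X[:, -1] = (X[:, -1] - self.mean_) / self.scale_
        return X


class _PLSRegressorFlat(PLSRegression):
    """PLSRegression returning 1-D predictions, with rank-safe components."""

    def fit(self, X, y):
        max_comp = min(np.asarray(X).shape[0] - 1, np.asarray(X).shape[1])
        if self.n_components > max_comp:
            warnings.warn(f"n_components truncated from {self.n_components} to {max_comp}")
            self.n_components = max_comp
        return super().fit(X, y)

    def predict(self, X):
        return np.ravel(super().predict(X))


def make_model(name: str, context: ModelContext) -> Pipeline:
    """Bind the scheme's encoder to its regressor as a sklearn pipeline.

    The pipeline consumes iterables of variant sequence strings.
    """
    if name == "residue_agnostic":
        return Pipeline(
            [
                ("encode", IndicatorEncoder(context.reference)),
                ("ridge", Ridge(alpha=context.alpha)),
            ]
        )
    if name == "pls":
        return Pipeline(
            [
                ("encode", OneHotEncoder(context.reference)),
                ("pls", _PLSRegressorFlat(n_components=context.n_components, scale=False)),
            ]
        )
    if name == "augmented_potts":
        if context.potts is None:
            raise ValueError("augmented_potts requires a fitted PottsModel in the context")
        return Pipeline(
            [
                ("encode", AugmentedPottsEncoder(context.reference, context.potts)),
                ("scale_energy", _EnergyColumnScaler()),
                ("ridge", Ridge(alpha=context.alpha)),
            ]
        )
    if name == "embedding":
        if context.embedder is None:
            raise ValueError("embedding model requires an embedder in the context")
        return Pipeline(
            [
                ("encode", EmbeddingEncoder(context.embedder)),
                ("ridge", Ridge(alpha=context.alpha)),
            ]
        )
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _cv_spearman(X: np.ndarray, y: np.ndarray, alpha: float, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        reg = Ridge(alpha=alpha).fit(X[tr], y[tr])
        rho = spearmanr(reg.predict(X[te]), y[te]).statistic
        if np.isfinite(rho):
            scores.append(rho)
    return float(np.mean(scores)) if scores else float("nan")


def select_alpha(
    datasets: Sequence[tuple[np.ndarray, np.ndarray]],
    grid: Sequence[float] = ALPHA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the single grid value with best mean CV Spearman across datasets.

    This is a deliberately optimistic ("best case") selection over whole
    datasets, not a nested per-fold search.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    if not len(grid):
        raise ValueError("empty alpha grid")
    means = []
    for alpha in grid:
        per_ds = [
            _cv_spearman(np.asarray(X, dtype=float), np.asarray(y, dtype=float), alpha, folds, seed)
            for X, y in datasets
        ]
        means.append(np.nanmean(per_ds))
    return float(grid[int(np.nanargmax(means))])
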