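"""The three habitat-model families: linear, smooth, and boosted trees.

All three model presence (1) vs pseudo-absence (0) as a binomial response on
the environmental covariates:

``linear``
    Logistic regression with linear terms per covariate plus a ridge-shrunken
    per-animal random intercept — the GLMM analogue. Shrinkage toward zero is
    what makes the group intercepts "random" rather than fixed effects.
``smooth``
    Same penalized backbone with a B-spline basis (default dimension 5 per
    covariate, the "knots = 5" convention) replacing the linear terms — the
    GAMM analogue.
``trees``
    Stochastic gradient boosting (learning rate 0.005, bag fraction 0.75,
    interaction depth 5, 2000 trees — the standard slow-learning BRT recipe
    for telemetry SDMs). No random effect; individual heterogeneity is left
    to the trees.

Predictions are always on the probability scale in [0, 1] and, for the mixed
families, population-level (random intercept set to zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from statsmodels.gam.smooth_basis import BSplines

from .covariates import EnvironmentStack

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "smooth", "trees")

_EPS = 1e-10


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one habitat-model family."""

    family: str = "linear"
    basis_df: int = 5           # spline basis dimension per covariate (smooth family)
    ridge_lambda: float = 1.0   # shrinkage on per-animal intercepts (mixed families)
    learning_rate: float = 0.005
    bag_fraction: float = 0.75
    interaction_depth: int = 5
    n_trees: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        if self.basis_df < 3:
            raise ValueError("basis_df must be >= 3")
        for name in ("ridge_lambda", "learning_rate", "bag_fraction", "interaction_depth", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _null_deviance(y: np.ndarray) -> float:
    return _binomial_deviance(y, np.full_like(y, y.mean(), dtype=float))


def _irls(X: np.ndarray, y: np.ndarray, penalty: np.ndarray, max_iter: int = 100, tol: float = 1e-9):
    """Penalized IRLS for a binomial logit: minimizes deviance + beta' P beta."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    dev = np.inf
    P = np.diag(penalty)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, _EPS, 1.0 - _EPS)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X + P, XtW @ z)
        eta = X @ beta_new
        dev_new = _binomial_deviance(y, 1.0 / (1.0 + np.exp(-eta)))
        if abs(dev - dev_new) < tol * (abs(dev_new) + 1.0):
            beta = beta_new
            break
        beta, dev = beta_new, dev_new
    return beta


class FittedHabitatModel:
    """A fitted habitat model: opaque state + schema-checked prediction."""

    def __init__(
        self,
        family: str,
        covariate_names: list[str],
        predict_fn: Callable[[pd.DataFrame], np.ndarray],
        null_deviance: float,
        residual_deviance: float,
        config: ModelConfig,
        feature_importance: pd.Series | None = None,
        training_means: pd.Series | None = None,
    ) -> None:
        self.family = family
        self.covariate_names = list(covariate_names)
        self._predict_fn = predict_fn
        self.null_deviance = null_deviance
        self.residual_deviance = residual_deviance
        self.config = config
        self.feature_importance = feature_importance
        self.training_means = training_means

    def predict_points(self, table: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] per row; errors list any missing columns."""
        missing = [c for c in self.covariate_names if c not in table.columns]
        if missing:
            raise ValueError(f"prediction table missing covariate columns: {missing}")
        p = self._predict_fn(table[self.covariate_names])
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def response_curve(self, name: str, values: np.ndarray) -> np.ndarray:
        """Fitted response over ``values`` of one covariate, others at training mean."""
        if name not in self.covariate_names:
            raise ValueError(f"unknown covariate {name!r}")
        values = np.asarray(values, dtype=float)
        df = pd.DataFrame(
            {c: np.full(len(values), self.training_means[c]) for c in self.covariate_names}
        )
        df[name] = values
        return self.predict_points(df)

    def predict_grid(self, env: EnvironmentStack, month: int | None = None) -> np.ndarray:
        """Suitability raster over the environment grid (NaN at missing cells)."""
        if env.has_monthly:
            if month is None:
                raise ValueError("month (1-12) is required with monthly layers")
            if not 1 <= int(month) <= 12:
                raise ValueError(f"month must be in 1..12, got {month}")
        grid = env.grid
        cols = {}
        for name in self.covariate_names:
            if name not in env.layers:
                raise ValueError(f"environment lacks layer {name!r}")
            cols[name] = env.slice_of(name, month).ravel()
        table = pd.DataFrame(cols)
        ok = table.notna().all(axis=1).to_numpy()
        out = np.full(len(table), np.nan)
        if ok.any():
            out[ok] = self.predict_points(table.loc[ok])
        return out.reshape(grid.n_rows, grid.n_cols)


# ---------------------------------------------------------------------------


def _covariate_columns(table: pd.DataFrame) -> list[str]:
    from .covariates import BOOKKEEPING_COLUMNS

    return [c for c in table.columns if c not in BOOKKEEPING_COLUMNS]


def fit(table: pd.DataFrame, config: ModelConfig) -> FittedHabitatModel:
    """Fit one habitat-model family on a presence/pseudo-absence table.

    ``table`` must carry a binary ``label`` column, an ``animal_id`` column
    (grouping for the random intercept), and one column per covariate.
    """
    if "label" not in table.columns:
        raise ValueError("table must have a 'label' column")
    y = table["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("table must contain both labels")
    names = _covariate_columns(table)
    if not names:
        raise ValueError("table has no covariate columns")
    X_cov = table[names].to_numpy(dtype=float)
    means = table[names].mean()

    if config.family == "trees":
        clf = GradientBoostingClassifier(
            learning_rate=config.learning_rate,
            subsample=config.bag_fraction,
            max_depth=config.interaction_depth,
            n_estimators=config.n_trees,
            random_state=config.seed,
        )
        clf.fit(X_cov, y)
        mu = clf.predict_proba(X_cov)[:, 1]
        importance = pd.Series(clf.feature_importances_, index=names)

        def predict_trees(df: pd.DataFrame) -> np.ndarray:
            return clf.predict_proba(df[names].to_numpy(dtype=float))[:, 1]

        return FittedHabitatModel(
            "trees",
            names,
            predict_trees,
            _null_deviance(y),
            _binomial_deviance(y, mu),
            config,
            feature_importance=importance,
            training_means=means,
        )

    # mixed families share a penalized-IRLS backbone
    animals = table["animal_id"].astype(str).to_numpy() if "animal_id" in table.columns else None
    if animals is None or len(np.unique(animals)) < 2:
        if config.family in ("linear", "smooth"):
            logger.warning(
                "fit(%s): fewer than 2 animals; fitting without a random intercept",
                config.family,
            )
        animals = None

    if config.family == "smooth":
        lo = X_cov.min(axis=0)
        hi = X_cov.max(axis=0)
        basis = BSplines(
            X_cov,
            df=[config.basis_df] * len(names),
            degree=[3] * len(names),
            include_intercept=False,
        )
        X_terms = basis.basis

        def transform(df: pd.DataFrame) -> np.ndarray:
            x = df[names].to_numpy(dtype=float)
            x = np.clip(x, lo, hi)  # spline basis is undefined beyond training range
            return basis.transform(x)

    else:
        X_terms = X_cov

        def transform(df: pd.DataFrame) -> np.ndarray:
            return df[names].to_numpy(dtype=float)

    blocks = [np.ones((len(y), 1)), X_terms]
    penalty = [np.zeros(1 + X_terms.shape[1])]
    if animals is not None:
        uniq = np.unique(animals)
        dummies = (animals[:, None] == uniq[None, :]).astype(float)
        blocks.append(dummies)
        penalty.append(np.full(len(uniq), config.ridge_lambda))
    X = np.hstack(blocks)
    pen = np.concatenate(penalty)
    beta = _irls(X, y, pen)
    n_fixed = 1 + X_terms.shape[1]
    beta_fixed = beta[:n_fixed]
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))

    # population-level prediction: random intercept = 0
    def predict_mixed(df: pd.DataFrame) -> np.ndarray:
        Xt = np.hstack([np.ones((len(df), 1)), transform(df)])
        return 1.0 / (1.0 + np.exp(-(Xt @ beta_fixed)))

    return FittedHabitatModel(
        config.family,
        names,
        predict_mixed,
        _null_deviance(y),
        _binomial_deviance(y, mu),
        config,
        training_means=means,
    )
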