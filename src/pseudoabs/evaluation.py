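"""Skill metrics, environmental-separation statistics, and the experiment loop.

Metrics: rank-based AUC (Mann-Whitney, ties counted one-half), the True
Skill Statistic maximized over classification thresholds, and the fraction
of binomial deviance explained. Environmental separation between presence
and pseudo-absence covariate samples is measured by the Bhattacharyya
coefficient over shared histogram bins (1 = identical distributions, 0 =
disjoint). The headline analysis regresses AUC on the Bhattacharyya
coefficient, pooled over pseudo-absence methods and the most influential
covariates, per model family: a negative slope means greater environmental
separation buys apparent predictive skill.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models
from .covariates import BOOKKEEPING_COLUMNS, build_table
from .models import FittedHabitatModel, ModelConfig
from .movement import MoveDistribution, empirical_moves, mode_step_length
from .pseudoabsence import METHODS, generate
from .synthetic_world import StudyDataset

logger = logging.getLogger(__name__)

SCHEMES = ("full", "random75", "monthly")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes (labels 0 and 1) must be present")
    return labels


def auc(labels, scores) -> float:
    """Rank-based AUC: P(random presence outscores random absence), ties 1/2."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss(labels, scores, return_threshold: bool = False):
    """True Skill Statistic maximized over thresholds.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores, plus one below the minimum and one above the maximum; presence is
    predicted when score >= threshold.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    pos = labels == 1
    n1 = pos.sum()
    n0 = (~pos).sum()
    best = -np.inf
    best_thr = candidates[0]
    for thr in candidates:
        pred = scores >= thr
        sens = (pred & pos).sum() / n1
        spec = (~pred & ~pos).sum() / n0
        val = sens + spec - 1.0
        if val > best:
            best, best_thr = val, thr
    if return_threshold:
        return float(best), float(best_thr)
    return float(best)


def explained_deviance(model: FittedHabitatModel) -> float:
    """(null - residual) / null binomial deviance on training data, clipped at 0."""
    if model.null_deviance <= 0:
        raise ValueError("zero null deviance: degenerate training labels")
    frac = (model.null_deviance - model.residual_deviance) / model.null_deviance
    if frac < 0:
        logger.warning("explained deviance %.4f < 0; clipping to 0", frac)
        frac = 0.0
    return float(frac)


def bhattacharyya(sample_p, sample_q, n_bins: int = 50) -> float:
    """Bhattacharyya coefficient over shared equal-width bins.

    Bins span the pooled range of both samples; BC = sum_i sqrt(p_i q_i)
    of the two samples' bin proportions. 1 for identical distributions,
    0 for disjoint supports.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    p = p[np.isfinite(p)]
    q = q[np.isfinite(q)]
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both samples must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if lo == hi:  # all mass in one point for both samples
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    return float(np.sum(np.sqrt((hp / hp.sum()) * (hq / hq.sum()))))


# ---------------------------------------------------------------------------
# Cross-validation schemes


def split(table: pd.DataFrame, scheme: str, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Folds of (train_idx, test_idx) positional indices for a CV scheme.

    ``full``: one fold, train = test = all rows. ``random75``: one seeded
    75/25 row split. ``monthly``: leave-one-month-out — one fold per calendar
    month present, testing that month and training on the rest.
    """
    n = len(table)
    idx = np.arange(n)
    if scheme == "full":
        return [(idx, idx)]
    if scheme == "random75":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train = int(round(0.75 * n))
        return [(np.sort(perm[:n_train]), np.sort(perm[n_train:]))]
    if scheme == "monthly":
        if "timestamp" not in table.columns:
            raise ValueError("monthly scheme requires a timestamp column")
        months = pd.to_datetime(table["timestamp"]).dt.month.to_numpy()
        uniq = np.unique(months)
        if len(uniq) < 2:
            raise ValueError(
                "monthly scheme needs >= 2 distinct months (static/one-month data "
                "cannot support a temporal leave-one-out)"
            )
        return [(idx[months != m], idx[months == m]) for m in uniq]
    raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")


def separation_skill_regression(points: Sequence[tuple[float, float]]):
    """OLS of AUC on Bhattacharyya coefficient: (slope, intercept, p_value).

    ``points`` are (BC, AUC) pairs; the p-value is the two-sided test of a
    zero slope.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("regression needs >= 3 (BC, AUC) points")
    bc = pts[:, 0]
    skill = pts[:, 1]
    if np.allclose(bc, bc[0]):
        raise ValueError("all BC values identical: regression undefined")
    res = stats.linregress(bc, skill)
    return float(res.slope), float(res.intercept), float(res.pvalue)


# ---------------------------------------------------------------------------
# Experiment orchestration


@dataclass
class SkillReport:
    """Results of a full methods x families x schemes experiment.

    metrics: one row per (method, family, scheme) with R2, AUC, TSS, mean
    prediction at presences / pseudo-absences, and the TSS threshold.
    bc: per (covariate, method) Bhattacharyya coefficient between the
    presence and pseudo-absence covariate samples.
    regressions: per family, the OLS of AUC on BC pooled over methods and
    the top covariates.
    """

    metrics: pd.DataFrame
    bc: pd.DataFrame
    regressions: pd.DataFrame
    top_covariates: list[str]
    provenance: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "skill_metrics.csv", index=False)
        self.bc.to_csv(outdir / "bhattacharyya.csv", index=False)
        self.regressions.to_csv(outdir / "separation_skill_regression.csv", index=False)
        manifest = dict(self.provenance, top_covariates=self.top_covariates)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    @classmethod
    def load(cls, outdir) -> "SkillReport":
        from pathlib import Path

        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        top = manifest.pop("top_covariates")
        return cls(
            metrics=pd.read_csv(outdir / "skill_metrics.csv"),
            bc=pd.read_csv(outdir / "bhattacharyya.csv"),
            regressions=pd.read_csv(outdir / "separation_skill_regression.csv"),
            top_covariates=top,
            provenance=manifest,
        )


def _fold_metrics(model, train, test, seed_tag):
    scores = model.predict_points(test)
    labels = test["label"].to_numpy()
    t, thr = tss(labels, scores, return_threshold=True)
    return {
        "r2": explained_deviance(model),
        "auc": auc(labels, scores),
        "tss": t,
        "tss_threshold": thr,
        "mean_pred_presence": float(scores[labels == 1].mean()),
        "mean_pred_absence": float(scores[labels == 0].mean()),
    }


def evaluate_experiment(
    study: StudyDataset,
    methods: Sequence[str] = METHODS,
    families: Sequence[str] = _models.FAMILIES,
    schemes: Sequence[str] = ("full",),
    seed: int = 0,
    n_bins: int = 50,
    n_top_covariates: int = 3,
    model_configs: dict[str, ModelConfig] | None = None,
    moves: MoveDistribution | None = None,
    buffer_radius_km: float | None = None,
) -> SkillReport:
    """Run the full pseudo-absence comparison on a synthetic (or real) study.

    For every method: generate the 1:1 pseudo-absence set, build the model
    table, and compute per-covariate Bhattacharyya coefficients between the
    presence and pseudo-absence samples. For every method x family x scheme:
    fit on the train fold(s), score the test fold(s), and record fold-mean
    AUC, TSS, explained deviance, and mean predictions at presences and
    pseudo-absences. Finally, per family, regress AUC (full scheme) on BC
    pooled over methods and the ``n_top_covariates`` most influential
    covariates (ranked by mean trees-family feature importance).

    The buffer radius defaults to the mode step length of the empirical move
    distribution, and the CRWs resample that same distribution — both as the
    movement-aware methods prescribe.
    """
    methods = list(methods)
    families = list(families)
    schemes = list(schemes)
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; valid: {METHODS}")
    if moves is None:
        moves = empirical_moves(study.tracks, pooling="pooled")
    if buffer_radius_km is None:
        buffer_radius_km = mode_step_length(moves)
    model_configs = model_configs or {}

    presences = study.presences
    method_seeds = {
        m: int(s)
        for m, s in zip(methods, np.random.SeedSequence(seed).generate_state(len(methods)) % (2**31))
    }

    metric_rows = []
    bc_rows = []
    tables = {}
    importances = []

    for method in methods:
        pa = generate(
            method,
            study.tracks,
            study.domain,
            method_seeds[method],
            radius_km=buffer_radius_km,
            moves=moves,
        )
        table = build_table(presences, pa.records, study.env)
        tables[method] = table
        cov_names = [c for c in table.columns if c not in BOOKKEEPING_COLUMNS]
        for name in cov_names:
            bc_rows.append(
                {
                    "covariate": name,
                    "method": method,
                    "bc": bhattacharyya(
                        table.loc[table["label"] == 1, name],
                        table.loc[table["label"] == 0, name],
                        n_bins=n_bins,
                    ),
                }
            )

        for family in families:
            config = model_configs.get(family, ModelConfig(family=family, seed=seed))
            for scheme in schemes:
                try:
                    folds = split(table, scheme, seed=seed)
                except ValueError as err:
                    raise ValueError(f"[{method} x {family} x {scheme}] {err}") from err
                fold_vals = []
                for train_idx, test_idx in folds:
                    train = table.iloc[train_idx]
                    test = table.iloc[test_idx]
                    try:
                        model = _models.fit(train, config)
                        fold_vals.append(_fold_metrics(model, train, test, seed))
                    except ValueError as err:
                        raise ValueError(f"[{method} x {family} x {scheme}] {err}") from err
                agg = pd.DataFrame(fold_vals).mean().to_dict()
                metric_rows.append(
                    {"method": method, "family": family, "scheme": scheme, **agg}
                )
                if family == "trees" and scheme == "full":
                    importances.append(model.feature_importance)

    metrics = pd.DataFrame(metric_rows)
    bc_table = pd.DataFrame(bc_rows)

    # rank covariates by mean trees-family influence over methods (full fits)
    if importances:
        mean_imp = pd.concat(importances, axis=1).mean(axis=1).sort_values(ascending=False)
    else:  # trees family not requested: fall back to BC spread across methods
        mean_imp = (
            bc_table.pivot(index="covariate", columns="method", values="bc")
            .std(axis=1)
            .sort_values(ascending=False)
        )
    top = list(mean_imp.index[:n_top_covariates])

    reg_rows = []
    reg_scheme = "full" if "full" in schemes else schemes[0]
    full_auc = metrics[metrics["scheme"] == reg_scheme].set_index(["method", "family"])["auc"]
    bc_lookup = bc_table.set_index(["covariate", "method"])["bc"]
    for family in families:
        pts = [
            (float(bc_lookup[(cov, m)]), float(full_auc[(m, family)]))
            for m in methods
            for cov in top
        ]
        slope, intercept, pval = separation_skill_regression(pts)
        reg_rows.append(
            {
                "family": family,
                "slope": slope,
                "intercept": intercept,
                "p_value": pval,
                "n_points": len(pts),
            }
        )
    regressions = pd.DataFrame(reg_rows)

    provenance = {
        "seed": seed,
        "study_seed": study.seed,
        "methods": methods,
        "families": families,
        "schemes": schemes,
        "method_seeds": method_seeds,
        "buffer_radius_km": float(buffer_radius_km),
        "n_bins": n_bins,
        "n_presences": int(len(presences)),
    }
    return SkillReport(
        metrics=metrics,
        bc=bc_table,
        regressions=regressions,
        top_covariates=top,
        provenance=provenance,
    )
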