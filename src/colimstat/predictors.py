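"""Environmental prediction of limitation presence/absence.

Pipeline: impute missing covariates by predictive mean matching (PMM), fit a
grid-tuned random-forest classifier per element on an 80/20 stratified
split, gate on performance (out-of-bag training misclassification < 30% and
held-out accuracy above the no-information rate), then read thresholds off
partial-dependence curves of the top predictors.

PMM never fabricates values: a missing cell receives the *observed* value of
one of the k donors whose regression-predicted values are closest to the
missing cell's own prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .tables import CovariateTable


@dataclass(frozen=True)
class ImputationSpec:
    """PMM configuration: donor pool size and RNG seed."""

    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("donor count k must be >= 1")


def impute_pmm(wide: pd.DataFrame, spec: ImputationSpec = ImputationSpec()) -> pd.DataFrame:
    """Predictive-mean-matching imputation of a streams x variables matrix.

    For each incomplete variable, an ordinary least-squares regression on the
    fully observed variables predicts the variable for all rows; each missing
    cell takes the observed value of one of the ``k`` donors with the nearest
    predictions (random choice among them, seeded).  Variables with fewer
    than ``k + 1`` observed values fall back to the observed median, with a
    warning.
    """
    out = wide.copy().astype(float)
    incomplete = [c for c in out.columns if out[c].isna().any()]
    if not incomplete:
        return out
    complete = [c for c in out.columns if not out[c].isna().any()]
    rng = np.random.default_rng(spec.seed)

    for col in incomplete:
        frac = out[col].isna().mean()
        if frac > 0.10:
            warnings.warn(f"variable {col!r} is {frac:.0%} missing; PMM may be unreliable")
        obs_mask = out[col].notna().to_numpy()
        y_obs = out.loc[obs_mask, col].to_numpy()
        if len(y_obs) < spec.k + 1 or not complete:
            if len(y_obs) == 0:
                raise ValueError(f"variable {col!r} has no observed values")
            warnings.warn(f"variable {col!r}: too few donors for PMM, using observed median")
            out.loc[~obs_mask, col] = float(np.median(y_obs))
            continue
        X = out[complete].to_numpy()
        X = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(X[obs_mask], y_obs, rcond=None)
        pred = X @ beta
        pred_obs = pred[obs_mask]
        for idx in np.flatnonzero(~obs_mask):
            dist = np.abs(pred_obs - pred[idx])
            donors = np.argsort(dist, kind="stable")[: spec.k]
            out.iloc[idx, out.columns.get_loc(col)] = float(y_obs[rng.choice(donors)])
    return out


def impute_covariates(table: CovariateTable, spec: ImputationSpec = ImputationSpec()) -> pd.DataFrame:
    """Convenience wrapper: long covariate table in, complete wide matrix out."""
    return impute_pmm(table.to_wide(), spec)


@dataclass(frozen=True)
class TuningGrid:
    """Candidate values for the three tuned random-forest parameters."""

    variables_per_split: tuple = ("sqrt", 1 / 3, 0.1)
    max_nodes: tuple = (4, 8, 16, None)
    tree_count: tuple = (250, 500, 1000)

    def __post_init__(self) -> None:
        if not (self.variables_per_split and self.max_nodes and self.tree_count):
            raise ValueError("tuning grid axes must be non-empty")


@dataclass
class PartialDependenceCurve:
    feature: str
    grid: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_value": self.grid, "probability": self.probability})


@dataclass(frozen=True)
class ThresholdResult:
    feature: str
    value: float
    direction: str  # "increase" or "decrease"


@dataclass
class PredictorReport:
    """Diagnostics of a fitted presence/absence model for one element."""

    element: str
    train_misclassification: float
    test_accuracy: float
    no_information_rate: float
    well_performing: bool
    importance: pd.Series
    tuning: dict
    n_train: int
    n_test: int
    curves: dict = field(default_factory=dict)  # feature -> PartialDependenceCurve
    thresholds: dict = field(default_factory=dict)  # feature -> ThresholdResult | None
    model: Optional[RandomForestClassifier] = None
    features: Optional[pd.DataFrame] = None

    def to_json(self) -> str:
        payload = {
            "element": self.element,
            "train_misclassification": self.train_misclassification,
            "test_accuracy": self.test_accuracy,
            "no_information_rate": self.no_information_rate,
            "well_performing": self.well_performing,
            "tuning": {k: (v if v is None or isinstance(v, (int, str)) else float(v)) for k, v in self.tuning.items()},
            "n_train": self.n_train,
            "n_test": self.n_test,
            "importance_ranking": {k: float(v) for k, v in self.importance.items()},
            "thresholds": {
                f: (None if t is None else {"value": t.value, "direction": t.direction})
                for f, t in self.thresholds.items()
            },
        }
        return json.dumps(payload, indent=2)


class DegenerateLabelsError(ValueError):
    """All labels belong to one class; no model can be assessed."""


def fit_presence_model(
    features: pd.DataFrame,
    labels: pd.Series,
    element: str = "",
    grid: TuningGrid = TuningGrid(),
    split_fraction: float = 0.8,
    seed: int = 0,
    importance_mode: str = "impurity",
    top_predictors: int = 4,
) -> PredictorReport:
    """Grid-tuned random-forest presence/absence model with a stratified holdout.

    Tuning selects the (variables-per-split, max-nodes, tree-count) combination
    with the best out-of-bag score on the training split.  The training
    misclassification rate reported is the out-of-bag error of the selected
    model; test accuracy is measured on the held-out streams and compared to
    the no-information rate (majority-class share of the test set).
    """
    if len(features) < 10:
        raise ValueError("need at least 10 streams to fit a presence model")
    y = labels.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(f"labels for {element or 'model'} are single-class")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split_fraction, stratify=y, random_state=seed
    )

    best = None
    for mf in grid.variables_per_split:
        for mn in grid.max_nodes:
            for nt in grid.tree_count:
                rf = RandomForestClassifier(
                    n_estimators=nt,
                    max_features=mf,
                    max_leaf_nodes=mn,
                    oob_score=True,
                    random_state=seed,
                    n_jobs=1,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # tiny OOB samples can warn
                    rf.fit(X_tr, y_tr)
                score = rf.oob_score_
                if best is None or score > best[0]:
                    best = (score, {"variables_per_split": mf, "max_nodes": mn, "tree_count": nt}, rf)

    oob_score, tuning, model = best
    train_mis = 1.0 - oob_score
    test_acc = float((model.predict(X_te) == y_te).mean())
    nir = float(max(np.mean(y_te), 1.0 - np.mean(y_te)))
    well = train_mis < 0.30 and test_acc > nir

    if importance_mode == "permutation":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perm = permutation_importance(model, X_te, y_te, n_repeats=20, random_state=seed)
        imp = pd.Series(perm.importances_mean, index=features.columns)
    else:
        imp = pd.Series(model.feature_importances_, index=features.columns)
    imp = imp.sort_values(ascending=False)

    report = PredictorReport(
        element=element,
        train_misclassification=float(train_mis),
        test_accuracy=test_acc,
        no_information_rate=nir,
        well_performing=bool(well),
        importance=imp,
        tuning=tuning,
        n_train=len(y_tr),
        n_test=len(y_te),
        model=model,
        features=features,
    )
    for feat in imp.index[:top_predictors]:
        curve = partial_dependence(model, features, feat)
        report.curves[feat] = curve
        report.thresholds[feat] = detect_threshold(curve)
    return report


def partial_dependence(
    model: RandomForestClassifier,
    features: pd.DataFrame,
    feature: str,
    grid_points: int = 50,
) -> PartialDependenceCurve:
    """Average predicted presence probability as one feature is swept.

    The grid spans the 2.5th-97.5th percentile of the observed feature with
    ``grid_points`` even steps; at each grid value the feature is overwritten
    for every stream and the predicted probabilities averaged.
    """
    values = features[feature].to_numpy(dtype=float)
    lo, hi = np.percentile(values, [2.5, 97.5])
    if lo == hi:
        warnings.warn(f"feature {feature!r} is constant over its inner quantile range")
        grid = np.full(grid_points, lo)
    else:
        grid = np.linspace(lo, hi, grid_points)
    X = features.to_numpy(dtype=float).copy()
    j = features.columns.get_loc(feature)
    probs = np.empty(grid_points)
    for i, v in enumerate(grid):
        X[:, j] = v
        probs[i] = model.predict_proba(X)[:, 1].mean()
    return PartialDependenceCurve(feature, grid, probs)


def detect_threshold(curve: PartialDependenceCurve) -> Optional[ThresholdResult]:
    """Locate the sharpest change in a partial-dependence curve.

    Returns the midpoint of the grid interval with the maximum absolute first
    difference and the direction of change, or None for a flat curve.
    """
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points to detect a threshold")
    diffs = np.diff(curve.probability)
    if np.all(diffs == 0):
        return None
    i = int(np.argmax(np.abs(diffs)))
    midpoint = float((curve.grid[i] + curve.grid[i + 1]) / 2.0)
    direction = "increase" if diffs[i] > 0 else "decrease"
    return ThresholdResult(curve.feature, midpoint, direction)


def screen_by_thresholds(
    wide: pd.DataFrame,
    rules: Sequence,
    labels: Optional[pd.Series] = None,
) -> dict:
    """Count streams satisfying a conjunction of (variable, direction, cut) rules.

    ``rules`` accepts ``RuleClause``-like objects or ``(variable, direction,
    cut)`` tuples with direction ``gt``/``lt``.  With labels given, a
    cross-tabulation of rule satisfaction against limitation status is added.
    """
    mask = pd.Series(True, index=wide.index)
    for rule in rules:
        if isinstance(rule, tuple):
            variable, direction, cut = rule
        else:
            variable, direction, cut = rule.variable, rule.direction, rule.cut
        if variable not in wide.columns:
            raise KeyError(f"unknown covariate {variable!r}")
        col = wide[variable]
        mask &= col > cut if direction == "gt" else col < cut
    result = {
        "n_streams": int(mask.sum()),
        "stream_ids": list(wide.index[mask]),
    }
    if labels is not None:
        aligned = labels.reindex(wide.index)
        result["crosstab"] = pd.crosstab(mask, aligned.astype("Int64"))
    return result
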