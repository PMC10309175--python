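"""Nested logistic prediction models for ICS response.

Three logistic models are trained on the discovery cohort and scored
on the replication cohort without refitting: a clinical/demographic
model (M1), a model of the replicated miRNAs alone (M2), and their
combination (M3). Accuracy is the rank (Mann-Whitney) AUC with a
percentile-bootstrap confidence interval over replication subjects;
nested models are compared by the analysis-of-deviance chi-square
(likelihood-ratio) test on the cohort where both were fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import build_covariate_design
from .stats import DegenerateInputError, auc_rank, fit_logistic


@dataclass
class FittedModel:
    model_id: str
    predictors: list[str]  # column names in the subject feature table
    coef: dict[str, float]  # design-column name -> coefficient (incl. intercept)
    deviance: float
    loglik: float
    n_obs: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "predictors": self.predictors,
            "coef": self.coef,
            "deviance": self.deviance,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


@dataclass
class PredictionEval:
    model_id: str
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_obs: int


def _design(features: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    missing = [p for p in predictors if p not in features.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    sub = features[predictors]
    complete = sub.dropna(axis=0, how="any")
    return build_covariate_design(complete, complete.index)


def fit_models(
    features: pd.DataFrame,
    outcome: pd.Series,
    model_specs: dict[str, list[str]],
) -> dict[str, FittedModel]:
    """Fit each named logistic model on the discovery cohort.

    ``features`` holds all candidate predictors per subject (clinical
    columns and miRNA expression columns); ``outcome`` is 1 for poor
    response. Each model uses complete cases for its own predictor set.
    """
    fits = {}
    for model_id, predictors in model_specs.items():
        design = _design(features, predictors)
        subjects = design.index.intersection(outcome.dropna().index)
        design = design.loc[subjects]
        y = outcome.loc[subjects].astype(float).to_numpy()
        fit = fit_logistic(design.to_numpy(), y, names=list(design.columns))
        fits[model_id] = FittedModel(
            model_id=model_id,
            predictors=list(predictors),
            coef=dict(zip(fit.names, map(float, fit.coefs))),
            deviance=fit.deviance,
            loglik=fit.loglik,
            n_obs=fit.n_obs,
            converged=fit.converged,
        )
    return fits


def linear_predictor(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Score subjects with frozen coefficients (no refitting)."""
    design = _design(features, model.predictors)
    missing = [c for c in model.coef if c not in design.columns]
    if missing:
        raise KeyError(f"replication data lacks design column(s): {missing}")
    lp = sum(b * design[c] for c, b in model.coef.items())
    return pd.Series(lp, index=design.index, name=f"lp_{model.model_id}")


def evaluate_frozen(
    model: FittedModel,
    features: pd.DataFrame,
    outcome: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionEval:
    """AUC of the frozen model on a replication cohort, with a
    percentile bootstrap CI over replication subjects."""
    lp = linear_predictor(model, features)
    subjects = lp.index.intersection(outcome.dropna().index)
    scores = lp.loc[subjects].to_numpy()
    y = outcome.loc[subjects].astype(float).to_numpy()
    auc = auc_rank(scores, y)

    rng = np.random.default_rng(seed)
    n = len(subjects)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            boots[b] = np.nan
            continue
        boots[b] = auc_rank(scores[idx], y[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PredictionEval(
        model_id=model.model_id,
        auc=float(auc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_obs=n,
    )


def compare_models(
    fit_small: FittedModel,
    fit_big: FittedModel,
    features: pd.DataFrame,
    outcome: pd.Series,
) -> tuple[float, float]:
    """Analysis-of-deviance test between nested logistic models.

    Both models are refit on the shared complete-case subjects of the
    given cohort so the deviances are comparable; the statistic is the
    deviance difference on chi-square df = added-parameter count. A
    non-nested pair (e.g. clinical-only vs miRNA-only) is refused: the
    deviance test is undefined there.
    """
    if not set(fit_small.predictors) <= set(fit_big.predictors):
        raise ValueError(
            f"{fit_small.model_id} is not nested in {fit_big.model_id}: "
            "the analysis-of-deviance comparison is only defined for nested "
            "logistic models (compare each against the combined model instead)"
        )
    big_design = _design(features, fit_big.predictors)
    subjects = big_design.index.intersection(outcome.dropna().index)
    y = outcome.loc[subjects].astype(float).to_numpy()
    small_design = _design(features, fit_small.predictors).loc[subjects]
    big_design = big_design.loc[subjects]
    small = fit_logistic(small_design.to_numpy(), y, names=list(small_design.columns))
    big = fit_logistic(big_design.to_numpy(), y, names=list(big_design.columns))
    df = big_design.shape[1] - small_design.shape[1]
    stat = max(small.deviance - big.deviance, 0.0)
    if df == 0:
        return float(stat), 1.0
    return float(stat), float(sps.chi2.sf(stat, df))
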