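"""Per-miRNA logistic association with ICS response, BH FDR, replication.

Each miRNA is tested one at a time in a covariate-adjusted logistic
regression of responder class (poor = 1, good = 0) on its normalized
log2 expression. Poor response is the event, so OR > 1 means higher
circulating abundance goes with worse steroid response. Discovery hits
(BH q below the FDR threshold) replicate when the second cohort gives
p < alpha with the same direction of effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caster import CasterResult
from .mirna import NormalizedMatrix
from .stats import DegenerateInputError, bh_adjust, fit_logistic, wald_p

ASSOC_COLUMNS = [
    "beta", "se", "z", "p", "q", "or_", "ci_low", "ci_high", "n_used", "converged",
]


def build_covariate_design(
    covariates: pd.DataFrame | None, subjects: pd.Index
) -> pd.DataFrame:
    """Intercept + numeric covariates + indicator contrasts for categoricals.

    Categorical columns are expanded to dummies with the largest
    category as the reference level.
    """
    design = pd.DataFrame({"intercept": 1.0}, index=subjects)
    if covariates is None:
        return design
    cov = covariates.loc[subjects]
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "ifub":
            design[col] = s.astype(float)
        else:
            ref = s.value_counts().idxmax()
            for level in sorted(x for x in s.unique() if x != ref):
                design[f"{col}[{level}]"] = (s == level).astype(float)
    return design


def logistic_assoc(
    expr: NormalizedMatrix | pd.DataFrame,
    pheno: CasterResult | pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_within_converged: bool = True,
) -> pd.DataFrame:
    """Fit one adjusted logistic regression per miRNA.

    Parameters
    ----------
    expr : normalized expression, miRNA x subject (use the log2(x+1)
        transform for Table-2-scale per-unit odds ratios).
    pheno : CASTER result (or a per-subject "poor"/"good" Series).
    covariates : per-subject adjustment columns (e.g. age, sex).

    Returns
    -------
    DataFrame indexed by miRNA with beta/se/z/p/q/or_/ci_low/ci_high,
    n_used and a converged flag. Constant-predictor or separated fits
    are kept with NaN statistics and ``converged=False``; they do not
    enter the BH adjustment (m = number of converged tests).
    """
    values = expr.values if isinstance(expr, NormalizedMatrix) else expr
    if isinstance(pheno, CasterResult):
        poor = pheno.poor_mask.astype(float)
    else:
        poor = (pd.Series(pheno) == "poor").astype(float)

    subjects = values.columns.intersection(poor.index)
    if len(subjects) == 0:
        raise ValueError("no subjects shared between expression and phenotype")
    y = poor.loc[subjects].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("phenotype has a single class")

    base = build_covariate_design(covariates, subjects)
    rows = {}
    for mirna, row in values[subjects].iterrows():
        x = row.to_numpy(dtype=float)
        rec = dict.fromkeys(ASSOC_COLUMNS, np.nan)
        rec["n_used"] = len(subjects)
        rec["converged"] = False
        if np.ptp(x) == 0:
            rows[mirna] = rec
            continue
        X = np.column_stack([base.to_numpy(), x])
        try:
            fit = fit_logistic(X, y, names=[*base.columns, "mirna"])
        except DegenerateInputError:
            rows[mirna] = rec
            continue
        if fit.converged:
            beta = fit.coefs[-1]
            se = fit.se[-1]
            rec.update(
                beta=beta,
                se=se,
                z=beta / se,
                p=wald_p(beta / se),
                or_=np.exp(beta),
                ci_low=np.exp(beta - 1.96 * se),
                ci_high=np.exp(beta + 1.96 * se),
                converged=True,
            )
        rows[mirna] = rec

    table = pd.DataFrame.from_dict(rows, orient="index")[ASSOC_COLUMNS]
    table.index.name = "mirna"
    ok = table["converged"].astype(bool)
    if ok.any():
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def replicate(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    fdr: float = 0.10,
    alpha: float = 0.05,
) -> list[str]:
    """miRNAs significant in discovery (q < fdr), nominally significant
    in replication (p < alpha), with the same direction of effect."""
    shared = discovery.index.intersection(replication.index)
    if len(shared) == 0:
        raise ValueError("discovery and replication share no miRNA identifiers")
    d = discovery.loc[shared]
    r = replication.loc[shared]
    hits = (
        (d["q"] < fdr)
        & (r["p"] < alpha)
        & (np.sign(d["beta"]) == np.sign(r["beta"]))
        & d["converged"].astype(bool)
        & r["converged"].astype(bool)
    )
    return list(shared[hits.fillna(False)])


def table_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """OR and 95% Wald CI from a log-odds estimate (presentation helper)."""
    return float(np.exp(beta)), float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))


def p_from_z(z: float) -> float:
    """Two-sided normal p from a Wald z (Table-2 style column check)."""
    return float(2.0 * sps.norm.sf(abs(z)))
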