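"""Weighted co-expression network analysis for the paired DEX-sham design.

The stages mirror the WGCNA recipe: a probe-probe correlation matrix,
soft-thresholded into an adjacency by the scale-free criterion, the
topological overlap matrix (TOM), average-linkage clustering of
1 - TOM into modules, module eigengenes (first principal component of
each module's standardized expression), and mixed-model association
of eigengenes with miRNA levels or clinical traits.

Because every subject contributes a dexamethasone and a sham sample,
plain Pearson correlation across all samples is inflated by shared
subject effects. The paired correlation used here splits each probe
into a between-subject component (pair means) and a within-subject
component (pair half-differences, free of any per-subject offset) and
averages the two component correlations with their degrees-of-freedom
weights; with one sample per subject it reduces exactly to Pearson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats as sps

from .lcl import PairedExprSet
from .stats import DegenerateInputError, bh_adjust, fit_lmm_random_intercept

GREY = "grey"

#: WGCNA size-ranked module colour vocabulary (largest module first)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


def _safe_corr(a: np.ndarray) -> np.ndarray:
    """Row-wise correlation with zero for constant rows (instead of NaN)."""
    sd = a.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(a)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    bad = sd == 0
    c[bad, :] = 0.0
    c[:, bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def paired_correlation(
    x: PairedExprSet | pd.DataFrame,
    subjects: pd.Series | None = None,
    method: str = "paired",
) -> pd.DataFrame:
    """Probe-probe correlation accounting for the DEX-sham pairing.

    With ``method="pearson"`` the plain correlation across all samples
    is returned (exposed so the modification's impact is measurable).
    For the paired estimate, r = (df_b * r_between + df_w * r_within) /
    (df_b + df_w) where r_between correlates pair means, r_within
    correlates pair half-differences, and both df equal n_subjects - 1
    for balanced pairs. Unpaired input (a plain DataFrame, one sample
    per subject) yields exactly Pearson.
    """
    if isinstance(x, pd.DataFrame):
        vals = x
        c = _safe_corr(vals.to_numpy(dtype=float))
        return pd.DataFrame(c, index=vals.index, columns=vals.index)
    if method == "pearson":
        c = _safe_corr(x.values.to_numpy(dtype=float))
        return pd.DataFrame(c, index=x.values.index, columns=x.values.index)
    if method != "paired":
        raise ValueError(f"unknown correlation method: {method!r}")

    means = x.paired_means().to_numpy(dtype=float)
    halfdiffs = x.paired_differences().to_numpy(dtype=float) / 2.0
    n_subj = means.shape[1]
    r_b = _safe_corr(means)
    r_w = _safe_corr(halfdiffs)
    # constant within-component rows (e.g. no treatment variation) fall
    # back to the between component alone, and vice versa
    w_b = np.full_like(r_b, float(n_subj - 1))
    w_w = np.full_like(r_w, float(n_subj - 1))
    const_b = means.std(axis=1) == 0
    const_w = halfdiffs.std(axis=1) == 0
    w_b[const_b, :] = 0.0
    w_b[:, const_b] = 0.0
    w_w[const_w, :] = 0.0
    w_w[:, const_w] = 0.0
    denom = w_b + w_w
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (w_b * r_b + w_w * r_w) / denom
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    probes = x.values.index
    return pd.DataFrame(r, index=probes, columns=probes)


def adjacency_from_correlation(
    cor: pd.DataFrame | np.ndarray, power: int, signed: bool = False
) -> np.ndarray:
    c = np.asarray(cor, dtype=float)
    base = (1.0 + c) / 2.0 if signed else np.abs(c)
    return base ** power


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log degree-distribution regression."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    res = sps.linregress(xs, ys)
    return float(res.rvalue**2), float(res.slope)


def pick_soft_power(
    cor: pd.DataFrame | np.ndarray,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold power reaching scale-free fit R^2 >= target.

    If no power reaches the target (with a negative slope), the power
    maximizing R^2 is returned with a warning. Also returns the per-
    power diagnostics table (r2, slope, mean connectivity).
    """
    c = np.asarray(cor, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or not np.all(np.isfinite(c)):
        raise DegenerateInputError("correlation matrix must be square and finite")
    diag = []
    chosen = None
    for p in powers:
        a = adjacency_from_correlation(c, p, signed=signed)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        diag.append({"power": p, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
        if chosen is None and r2 >= r2_target and slope < 0:
            chosen = p
    table = pd.DataFrame(diag).set_index("power")
    if chosen is None:
        chosen = int(table["r2"].idxmax())
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_target}; "
            f"using power {chosen} (R^2 = {table.loc[chosen, 'r2']:.3f})",
            stacklevel=2,
        )
    return int(chosen), table


def topological_overlap(adj: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the connectivity (row sum, zero diagonal); diagonal set to 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(
    tom: np.ndarray | pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.95,
    values: pd.DataFrame | None = None,
    kme_threshold: float = 0.3,
    probe_ids: pd.Index | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM into colour-labelled modules.

    Clusters from a static height cut; clusters below
    ``min_module_size`` fall into "grey" (unassigned). When the
    expression matrix ``values`` is supplied, a module-membership
    refinement pass follows (the PAM-like stage of dynamic hybrid
    cutting): every probe joins the module whose eigengene it
    correlates with most strongly in absolute value, provided |kME| >=
    ``kme_threshold``; otherwise it is grey. For a paired design pass
    the within-pair difference matrix as ``values`` — it is free of the
    shared per-subject offset that would otherwise couple every probe
    to every eigengene. Labels follow the WGCNA size-ranked colour
    vocabulary.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    t = np.asarray(tom, dtype=float)
    if probe_ids is None:
        probe_ids = (
            tom.index if isinstance(tom, pd.DataFrame) else pd.RangeIndex(len(t))
        )
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = np.asarray(raw)
    sizes = pd.Series(labels).value_counts()
    keep = sizes[sizes >= min_module_size].index
    assigned = np.where(np.isin(labels, keep), labels, -1)

    if values is not None and len(keep) > 0:
        vals = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else values
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (vals - mu) / sd
        for _ in range(2):
            module_ids = [m for m in pd.unique(assigned) if m != -1]
            if not module_ids:
                break
            kme = np.empty((len(assigned), len(module_ids)))
            for j, m in enumerate(module_ids):
                sub = z[assigned == m]
                _, _, vt = np.linalg.svd(sub, full_matrices=False)
                me = vt[0]
                kme[:, j] = np.abs(z @ me) / (
                    np.linalg.norm(z, axis=1) * np.linalg.norm(me)
                )
            best = np.argmax(kme, axis=1)
            new = np.where(
                kme[np.arange(len(assigned)), best] >= kme_threshold,
                np.asarray(module_ids)[best],
                -1,
            )
            if np.array_equal(new, assigned):
                break
            assigned = new
        sizes = pd.Series(assigned[assigned != -1]).value_counts()
        small = sizes[sizes < min_module_size].index
        assigned = np.where(np.isin(assigned, small), -1, assigned)

    # size-ranked colour labels, ties broken by first occurrence
    final_sizes = pd.Series(assigned[assigned != -1]).value_counts()
    order = sorted(
        final_sizes.index,
        key=lambda m: (-final_sizes[m], int(np.argmax(assigned == m))),
    )
    color_of = {}
    for rank, m in enumerate(order):
        color_of[m] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        )
    out = pd.Series(
        [GREY if m == -1 else color_of[m] for m in assigned],
        index=probe_ids,
        name="module",
    )
    return out


def module_eigengene(
    values: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Rows of the result are modules, columns are samples; each eigengene
    has unit variance (ddof=1) and is oriented to correlate positively
    with the module's mean standardized profile.
    """
    eig = {}
    for module in [m for m in assignment.unique() if m != GREY]:
        probes = assignment.index[assignment == module]
        if len(probes) == 0:
            raise ValueError(f"empty module {module!r}")
        sub = values.loc[probes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        pc_sd = pc.std(ddof=1)
        eig[module] = pc / pc_sd if pc_sd > 0 else pc
    out = pd.DataFrame(eig, index=values.columns).T
    out.index.name = "module"
    return out


def _assoc_lmm(
    eigengenes: pd.DataFrame,
    predictor_levels: pd.DataFrame,
    covariates: pd.DataFrame | None,
    samples: pd.DataFrame,
    fdr: float,
) -> pd.DataFrame:
    sample_order = list(eigengenes.columns)
    groups = samples.loc[sample_order, "subject_id"].to_numpy()
    if pd.Series(groups).value_counts().min() < 2:
        raise ValueError("unpaired samples: every subject needs both conditions")

    cov_cols: list[str] = []
    base = np.ones((len(sample_order), 1))
    if covariates is not None:
        base = np.column_stack([base, covariates.loc[groups].to_numpy(dtype=float)])
        cov_cols = list(covariates.columns)

    rows = []
    for pred in predictor_levels.index:
        lv = predictor_levels.loc[pred]
        if lv.nunique() <= 1:
            raise DegenerateInputError(f"constant predictor: {pred}")
        x_pred = lv.loc[groups].to_numpy(dtype=float)
        X = np.column_stack([base, x_pred])
        names = ["intercept", *cov_cols, "predictor"]
        for module in eigengenes.index:
            y = eigengenes.loc[module, sample_order].to_numpy(dtype=float)
            fit = fit_lmm_random_intercept(X, y, groups, names=names)
            coef, se = fit.coefs[-1], fit.se[-1]
            z = coef / se if se > 0 else np.nan
            rows.append(
                {
                    "module": module,
                    "predictor": pred,
                    "coef": float(coef),
                    "se": float(se),
                    "exp_coef": float(np.exp(coef)),
                    "p": float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "re_var": fit.re_var,
                }
            )
    cols = ["module", "predictor", "coef", "se", "exp_coef", "p", "re_var"]
    out = pd.DataFrame(rows, columns=cols)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out


def module_mirna_assoc(
    eigengenes: pd.DataFrame,
    mirna_levels: pd.DataFrame,
    covariates: pd.DataFrame | None,
    samples: pd.DataFrame,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Mixed-model association of module eigengenes with miRNA levels.

    Eigengene is the response; miRNA level (constant within a subject's
    pair) plus covariates are fixed effects; a subject random intercept
    absorbs the DEX-sham pairing. BH across all (module, miRNA) pairs,
    flagged at the given FDR. ``exp_coef`` is reported as a secondary
    presentation column alongside the linear coefficient.
    """
    out = _assoc_lmm(eigengenes, mirna_levels, covariates, samples, fdr)
    return out.rename(columns={"predictor": "mirna"})


def module_trait_assoc(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None,
    samples: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model association of module eigengenes with clinical traits
    (per-subject), flagged at 5% FDR by default."""
    out = _assoc_lmm(eigengenes, traits.T, covariates, samples, fdr)
    return out.rename(columns={"predictor": "trait"})
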