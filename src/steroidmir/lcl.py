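"""Paired dexamethasone-sham differential expression and target enrichment.

Lymphoblastoid cell lines from each subject are profiled twice — once
under dexamethasone (a glucocorticoid) and once under a sham vehicle —
so every probe yields one within-subject difference per subject. The
differences are tested with an empirical-Bayes moderated paired t:
per-probe variances are shrunk toward a common prior whose weight
(prior degrees of freedom) and location are estimated from the spread
of the observed log-variances across probes, which stabilises the test
at modest pair counts. miRNA target sets are then tested for
over-representation among DEX-responsive genes by the exact
hypergeometric tail, and individual gene-miRNA couplings by a linear
mixed model with a subject random intercept absorbing the pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .stats import DegenerateInputError, bh_adjust, fit_lmm_random_intercept, hypergeom_upper

DEX, SHAM = "DEX", "sham"


class PairingError(ValueError):
    """A subject lacks exactly one DEX and one sham sample."""


@dataclass
class PairedExprSet:
    """Probe x sample log-scale expression with DEX/sham pairing.

    ``samples`` is indexed by sample id with columns ``subject_id`` and
    ``condition`` (DEX or sham); every subject must contribute exactly
    one sample per condition.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.samples.index) != set(self.values.columns):
            raise PairingError("sample metadata does not match expression columns")
        counts = self.samples.groupby("subject_id")["condition"].value_counts().unstack(fill_value=0)
        for cond in (DEX, SHAM):
            if cond not in counts.columns or (counts[cond] != 1).any():
                raise PairingError(
                    f"every subject needs exactly one {DEX} and one {SHAM} sample"
                )

    @property
    def subjects(self) -> list:
        return sorted(self.samples["subject_id"].unique())

    def sample_of(self, subject, condition: str):
        meta = self.samples
        return meta[(meta["subject_id"] == subject) & (meta["condition"] == condition)].index[0]

    def paired_differences(self) -> pd.DataFrame:
        """Probe x subject matrix of DEX - sham differences."""
        subj = self.subjects
        dex_cols = [self.sample_of(s, DEX) for s in subj]
        sham_cols = [self.sample_of(s, SHAM) for s in subj]
        d = self.values[dex_cols].to_numpy() - self.values[sham_cols].to_numpy()
        return pd.DataFrame(d, index=self.values.index, columns=subj)

    def paired_means(self) -> pd.DataFrame:
        """Probe x subject matrix of (DEX + sham)/2 pair means."""
        subj = self.subjects
        dex_cols = [self.sample_of(s, DEX) for s in subj]
        sham_cols = [self.sample_of(s, SHAM) for s in subj]
        m = (self.values[dex_cols].to_numpy() + self.values[sham_cols].to_numpy()) / 2.0
        return pd.DataFrame(m, index=self.values.index, columns=subj)


@dataclass
class EnrichResult:
    universe_n: int
    set_k: int
    hits_n: int
    overlap_k: int
    p_hyper: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior.

    Matches the mean and variance of log(s2) across probes to the
    theoretical moments of a scaled F distribution, giving the prior
    degrees of freedom d0 and prior variance s0^2. Returns
    (inf, exp(mean)) when the observed spread is no larger than the
    sampling spread (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderate_t(
    logfc: np.ndarray, s2: np.ndarray, df: int, n: int, d0: float, s0_2: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shrink per-probe variances toward the prior and form moderated t.

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df); t = logfc / sqrt(s2_post/n)
    with df + d0 total degrees of freedom (normal in the d0 -> inf limit).
    Exposed separately so the d0 -> 0 ordinary-t limit is directly testable.
    """
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post / n)
    t = np.where(s2_post == 0, 0.0, t)
    return t, s2_post, df_total


def paired_moderated_t(x: PairedExprSet) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test per probe.

    Returns a DataFrame (probe index) with logfc, t_mod, p, q plus the
    shared hyperparameters df_prior and s2_prior in ``attrs``.
    """
    diffs = x.paired_differences()
    n = diffs.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    d = diffs.to_numpy(dtype=float)
    logfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    d0, s0_2 = estimate_variance_prior(s2, df)
    t, s2_post, df_total = moderate_t(logfc, s2, df, n, d0, s0_2)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"logfc": logfc, "t_mod": t, "p": p, "q": bh_adjust(p), "s2": s2, "s2_post": s2_post},
        index=diffs.index,
    )
    out.index.name = "probe"
    out.attrs["df_prior"] = float(d0)
    out.attrs["s2_prior"] = float(s0_2)
    out.attrs["n_pairs"] = n
    return out


def target_enrichment(
    de: pd.DataFrame,
    target_sets: dict[str, set],
    mirnas: list[str] | None = None,
    probe_gene: pd.Series | None = None,
    fdr: float = 0.10,
) -> EnrichResult:
    """Hypergeometric over-representation of miRNA targets among DEX-responsive genes.

    universe = genes behind the tested probes (duplicate probes per
    gene collapse to the best q); hits = genes with q < fdr; set = the
    union of the requested miRNAs' target genes restricted to the
    universe; p = exact upper-tail P(X >= overlap).
    """
    if probe_gene is not None:
        gene_q = de["q"].groupby(probe_gene.loc[de.index]).min()
    else:
        gene_q = de["q"]
    universe = set(gene_q.index)
    if not universe:
        raise ValueError("empty probe/gene universe")
    selected = target_sets if mirnas is None else {m: target_sets[m] for m in mirnas}
    target_union = set().union(*selected.values()) if selected else set()
    target_in_universe = target_union & universe
    if selected and not target_in_universe and target_union:
        raise ValueError("no target gene maps into the probe universe")
    hits = set(gene_q.index[gene_q < fdr])
    overlap = len(hits & target_in_universe)
    p = hypergeom_upper(len(universe), len(target_in_universe), len(hits), overlap)
    return EnrichResult(
        universe_n=len(universe),
        set_k=len(target_in_universe),
        hits_n=len(hits),
        overlap_k=overlap,
        p_hyper=float(p),
    )


def mirna_gene_assoc(
    x: PairedExprSet,
    genes: list,
    mirna_levels: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Linear mixed-model association between each (miRNA, gene) pair.

    Gene expression across both conditions is the response; the
    subject's circulating miRNA level plus covariates (age, sex) are
    fixed effects and a subject random intercept absorbs the DEX-sham
    pairing. BH adjustment is applied across all pairs.
    """
    subj_of_sample = x.samples["subject_id"]
    sample_order = list(x.values.columns)
    groups = subj_of_sample.loc[sample_order].to_numpy()

    shared = [s for s in x.subjects if s in mirna_levels.columns]
    if len(shared) < len(x.subjects):
        raise ValueError("some paired subjects lack miRNA data")

    cov_cols: list[str] = []
    cov_mat = np.ones((len(sample_order), 1))
    if covariates is not None:
        per_sample = covariates.loc[groups].to_numpy(dtype=float)
        cov_mat = np.column_stack([cov_mat, per_sample])
        cov_cols = list(covariates.columns)

    rows = []
    for mirna in mirna_levels.index:
        lv = mirna_levels.loc[mirna]
        if lv.nunique() <= 1:
            raise DegenerateInputError(f"constant miRNA level: {mirna}")
        lv_sample = lv.loc[groups].to_numpy(dtype=float)
        X = np.column_stack([cov_mat, lv_sample])
        names = ["intercept", *cov_cols, "mirna"]
        for gene in genes:
            yv = x.values.loc[gene, sample_order].to_numpy(dtype=float)
            fit = fit_lmm_random_intercept(X, yv, groups, names=names)
            coef = fit.coefs[-1]
            se = fit.se[-1]
            z = coef / se if se > 0 else np.nan
            rows.append(
                {
                    "mirna": mirna,
                    "gene": gene,
                    "coef": float(coef),
                    "se": float(se),
                    "p": float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    "re_var": fit.re_var,
                }
            )
    out = pd.DataFrame(rows, columns=["mirna", "gene", "coef", "se", "p", "re_var"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
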