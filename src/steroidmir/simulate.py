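"""Synthetic cohorts, miRNA counts, paired expression sets, target sets.

The generators plant the statistical structure the pipeline stages
assume, so every stage can be exercised end-to-end with a known ground
truth. A cohort draws negative-binomial serum miRNA counts with
subject-specific library sizes; a chosen subset of miRNAs shifts the
log-odds of poor steroid response; responder status then drives the
five CASTER constituent measures in the directions seen in real
cohorts (poor responders: more oral steroid courses and ED visits,
higher bronchodilator response, lower FEV1, more reactive airways).
The paired expression generator emulates lymphoblastoid DEX-sham
arrays: block-correlated probe modules, per-probe treatment shifts, a
shared per-subject offset, and (optionally) one module whose latent
score tracks a circulating miRNA. Truth records carry everything
needed to score recovery without re-deriving the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .lcl import DEX, SHAM, PairedExprSet


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort (defaults: discovery scale)."""

    n_subjects: int = 580
    n_mirna: int = 317
    n_true_mirna: int = 20
    true_log_or: float = 0.3  # mean per-unit effect (log2 scale) on true-status log-odds
    effect_sd: float = 0.15  # heterogeneity of per-miRNA planted effects
    nb_dispersion: float = 0.3  # NB size = 1/dispersion
    bio_sigma: float = 1.5  # subject-level log-normal abundance variability (ln scale)
    lib_size_range: tuple[float, float] = (2e5, 1e6)
    batch_fraction: float = 0.0
    batch_shift: float = 0.0  # log2 fold applied to half the miRNAs in batch 2
    poor_fraction: float = 0.65  # target marginal poor-responder rate
    age_effect: float = 0.25  # log-odds of poor response per SD of age
    causal_mirna_indices: tuple[int, ...] | None = None  # fix the causal set
    causal_betas: tuple[float, ...] | None = None  # fix per-miRNA effects (sorted-index order)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_mirna > self.n_mirna:
            raise ValueError("n_true_mirna cannot exceed n_mirna")
        if self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("lib_size_range must be (low, high)")
        if not 0 <= self.batch_fraction <= 1:
            raise ValueError("batch_fraction must lie in [0, 1]")
        if self.causal_mirna_indices is not None:
            idx = tuple(self.causal_mirna_indices)
            if len(idx) != self.n_true_mirna or any(
                not 0 <= i < self.n_mirna for i in idx
            ):
                raise ValueError(
                    "causal_mirna_indices must give n_true_mirna indices < n_mirna"
                )


@dataclass
class LclConfig:
    """Conditions for a synthetic paired DEX-sham expression set."""

    n_pairs: int = 88
    n_probes: int = 2000
    n_modules: int = 10
    module_size_range: tuple[int, int] = (30, 120)
    within_module_cor: float = 0.6
    treatment_shift_sd: float = 0.4
    subject_sd: float = 0.7  # shared per-subject offset
    noise_sd: float = 1.0
    coupled_module_index: int | None = None
    coupling_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must lie strictly in (0, 1)")
        lo, hi = self.module_size_range
        if lo > hi or lo < 2:
            raise ValueError("module_size_range must be (low, high) with low >= 2")


# Table-1-scale conditional distributions of the five CASTER features
# (poor mean, good mean, poor sd, good sd) in the discovery cohort
_FEATURE_PARAMS = {
    "oral_steroid_courses": (2.15, 1.41, None, None),  # Poisson counts
    "ed_visits": (4.60, 2.75, None, None),  # Poisson counts
    "fev1_pct_pred": (91.9, 109.0, 14.1, 18.2),
    "airway_hyperresponsiveness": (0.671, 0.998, 0.336, 0.532),
    "bdr_pct": (6.57, 3.30, 8.37, 7.33),
}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (clinical table, count matrix, truth record).

    The clinical table is indexed by subject with age/sex/ethnicity,
    the five CASTER constituents, and a batch label; the count matrix
    is miRNA x subject integer counts. The truth record carries the
    causal miRNA ids, the planted per-unit log-odds, each subject's
    true responder status, and the predictor matrix scale used at
    generation time (log2 of library-size-corrected counts + 1).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_mirna
    subjects = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    mirnas = pd.Index([f"miR-{i:04d}" for i in range(m)], name="mirna")

    # abundance profile: log-normal baseline means, shared across subjects
    log_mu = rng.normal(3.0, 1.8, size=m)
    rel_abund = np.exp(log_mu)
    rel_abund /= rel_abund.sum()
    lib = rng.uniform(*config.lib_size_range, size=n)
    # subject-level biological variability: serum miRNA abundance varies
    # across children far beyond counting noise; the log-normal sigma sets
    # the spread of the log2 predictor (and hence the per-unit OR scale)
    bio = np.exp(
        config.bio_sigma * rng.normal(size=(m, n)) - config.bio_sigma**2 / 2.0
    )
    mean = np.outer(rel_abund, lib) * bio
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    # batch: multiplicative shift on a random half of miRNAs in batch 2
    batch = np.where(rng.random(n) < config.batch_fraction, "batch2", "batch1")
    shifted_mirnas = np.zeros(m, dtype=bool)
    if config.batch_shift > 0 and (batch == "batch2").any():
        shifted_mirnas = rng.random(m) < 0.5
        factor = 2.0 ** config.batch_shift
        b2 = batch == "batch2"
        counts = counts.astype(float)
        counts[np.ix_(shifted_mirnas, b2)] *= factor
        counts = np.rint(counts).astype(np.int64)
    counts = counts.astype(np.int64)

    # responder status from the planted logistic model on log2 expression
    rel_lib = lib / lib.mean()
    log_expr = np.log2(counts / rel_lib[None, :] + 1.0)
    if config.causal_mirna_indices is not None:
        causal_idx = np.asarray(sorted(config.causal_mirna_indices), dtype=int)
    else:
        causal_idx = rng.choice(m, size=config.n_true_mirna, replace=False)
        causal_idx.sort()
    age = np.clip(rng.normal(9.2, 1.9, size=n), 5.0, 15.0)
    sex = rng.random(n) < 0.45  # True = male

    if config.causal_betas is not None:
        if len(config.causal_betas) != len(causal_idx):
            raise ValueError("causal_betas length must match the causal set")
        betas = np.asarray(config.causal_betas, dtype=float)
    else:
        betas = config.true_log_or + config.effect_sd * rng.normal(
            size=config.n_true_mirna
        )
    lin = log_expr[causal_idx].T @ betas if config.n_true_mirna else np.zeros(n)
    lin = lin + config.age_effect * (age - age.mean()) / age.std()
    # intercept calibrated so the marginal poor rate matches poor_fraction
    intercept = float(logit(config.poor_fraction) - lin.mean())
    prob_poor = expit(intercept + lin)
    poor = rng.random(n) < prob_poor

    # CASTER constituents conditional on status (Table-1 directions)
    clin = {"age": age, "sex": np.where(sex, "M", "F"), "ethnicity": "hispanic"}
    for feat, (mu_p, mu_g, sd_p, sd_g) in _FEATURE_PARAMS.items():
        if sd_p is None:
            vals = rng.poisson(np.where(poor, mu_p, mu_g))
        else:
            vals = rng.normal(np.where(poor, mu_p, mu_g), np.where(poor, sd_p, sd_g))
        clin[feat] = vals
    # non-CASTER clinical covariates, weakly status-shifted (Table-1 scale)
    clin["log10_ige"] = rng.normal(np.where(poor, 2.61, 2.40), np.where(poor, 0.63, 0.67))
    clin["log10_eos"] = rng.normal(np.where(poor, 2.63, 2.52), np.where(poor, 0.44, 0.39))
    clin["batch"] = batch
    clinical = pd.DataFrame(clin, index=subjects)

    count_df = pd.DataFrame(counts, index=mirnas, columns=subjects)
    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "causal_mirnas": list(mirnas[causal_idx]),
        "causal_betas": dict(zip(mirnas[causal_idx], map(float, betas))),
        "true_log_or": config.true_log_or,
        "intercept": intercept,
        "age_effect": config.age_effect,
        "true_status": {
            s: ("poor" if p else "good") for s, p in zip(subjects, poor)
        },
        "library_sizes": dict(zip(subjects, map(float, lib))),
        "batch_shifted_mirnas": list(mirnas[shifted_mirnas]),
    }
    return clinical, count_df, truth


def true_status_series(truth: dict) -> pd.Series:
    """Planted responder status as a 'poor'/'good' Series."""
    s = pd.Series(truth["true_status"], name="responder_class")
    s.index.name = "subject_id"
    return s


def generate_lcl(
    config: LclConfig, mirna_levels: np.ndarray | pd.Series | None = None
) -> tuple[PairedExprSet, dict]:
    """Generate a paired DEX-sham expression set with planted modules.

    Each probe p of subject s under condition c is
    mean_p + u_s + sqrt(rho) * f_{module(p), s, c} + shift_p * [c = DEX]
    + sqrt(1 - rho) * noise, so probes of a module share the latent
    factor f and correlate at ``within_module_cor`` per sample. If
    ``coupled_module_index`` is set, that module's factor gains
    ``coupling_strength * standardized miRNA level`` in both
    conditions, so its eigengene tracks the circulating miRNA.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_pairs, config.n_probes
    if mirna_levels is None:
        mirna_levels = rng.normal(0.0, 1.0, size=n)
    mirna_levels = np.asarray(mirna_levels, dtype=float)
    if len(mirna_levels) != n:
        raise ValueError("mirna_levels length must equal n_pairs")

    sizes = rng.integers(
        config.module_size_range[0], config.module_size_range[1] + 1, size=config.n_modules
    )
    if sizes.sum() > p:
        raise ValueError("drawn module sizes exceed n_probes")
    assignment = np.full(p, -1)
    pos = 0
    for mi, sz in enumerate(sizes):
        assignment[pos : pos + sz] = mi
        pos += sz

    if config.coupled_module_index is not None and not (
        0 <= config.coupled_module_index < config.n_modules
    ):
        raise ValueError("coupled_module_index out of range")

    probes = pd.Index([f"G{i:04d}" for i in range(p)], name="probe")
    subjects = [f"P{i:03d}" for i in range(n)]
    z_mirna = (mirna_levels - mirna_levels.mean()) / (mirna_levels.std() or 1.0)

    rho = config.within_module_cor
    probe_mean = rng.normal(8.0, 1.0, size=p)
    shift = rng.normal(0.0, config.treatment_shift_sd, size=p)
    u = rng.normal(0.0, config.subject_sd, size=n)

    # heterogeneous module membership: per-probe loading l with mean
    # sqrt(rho), so pairwise within-module correlation averages rho while
    # hub/peripheral structure emerges (as in real co-expression data);
    # the spread vanishes as rho -> 1 so the perfect-correlation limit holds
    sq = np.sqrt(rho)
    spread = min(sq, 1.0 - sq)
    loading = sq + rng.uniform(-spread, spread, size=p)
    loading = np.clip(loading, 0.0, 1.0)

    # latent module factors per (module, subject, condition)
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n, 2))
    if config.coupled_module_index is not None and config.coupling_strength != 0.0:
        factors[config.coupled_module_index] += (
            config.coupling_strength * z_mirna[:, None]
        )

    cols, data = [], []
    meta = []
    for ci, cond in enumerate((SHAM, DEX)):
        for si, subj in enumerate(subjects):
            sample = f"{subj}_{cond}"
            base = probe_mean + u[si]
            f = np.where(
                assignment >= 0,
                factors[np.clip(assignment, 0, None), si, ci],
                0.0,
            )
            in_module = assignment >= 0
            signal_sd = np.where(in_module, loading, 0.0)
            resid_sd = np.where(in_module, np.sqrt(1.0 - loading**2), 1.0)
            x = (
                base
                + signal_sd * f
                + (shift if cond == DEX else 0.0)
                + resid_sd * config.noise_sd * rng.normal(0.0, 1.0, size=p)
            )
            cols.append(sample)
            data.append(x)
            meta.append({"sample_id": sample, "subject_id": subj, "condition": cond})

    values = pd.DataFrame(np.column_stack(data), index=probes, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    truth = {
        "seed": config.seed,
        "config": {
            **asdict(config),
            "module_size_range": list(config.module_size_range),
        },
        "module_assignment": {
            pr: int(a) for pr, a in zip(probes, assignment)
        },
        "module_sizes": [int(s) for s in sizes],
        "treatment_shift": dict(zip(probes, map(float, shift))),
        "loadings": dict(zip(probes, map(float, loading))),
        "coupled_module_index": config.coupled_module_index,
        "coupling_strength": config.coupling_strength,
        "mirna_levels": dict(zip(subjects, map(float, mirna_levels))),
    }
    return PairedExprSet(values=values, samples=samples), truth


def generate_target_sets(
    n_mirna: int,
    gene_universe_size: int,
    set_size_range: tuple[int, int],
    seed: int = 0,
    gene_ids: list | None = None,
    mirna_ids: list | None = None,
) -> dict[str, set]:
    """Reproducible miRNA -> gene-set map over a synthetic gene universe."""
    lo, hi = set_size_range
    if hi > gene_universe_size:
        raise ValueError("set size cannot exceed the gene universe")
    if lo < 0 or lo > hi:
        raise ValueError("set_size_range must be (low, high) with 0 <= low <= high")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(gene_universe_size)]
    if mirna_ids is None:
        mirna_ids = [f"miR-{i:04d}" for i in range(n_mirna)]
    out = {}
    for m in mirna_ids:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(gene_universe_size, size=k, replace=False) if k else []
        out[m] = {gene_ids[i] for i in chosen}
    return out
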