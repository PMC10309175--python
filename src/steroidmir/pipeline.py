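"""End-to-end pipeline orchestration on synthetic cohorts.

Stage order: synthesize -> CASTER -> filter/normalize/gPCA ->
associate -> replicate -> predict -> paired DE + enrichment ->
co-expression network. Every output lands in the run directory as TSV
or JSON, and a manifest records the configuration hash, the seed, the
thresholds, and per-stage headline numbers, so identical config + seed
reproduces identical outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import logistic_assoc, replicate
from .caster import compute_caster, caster_group_sizes
from .io import (
    write_clinical,
    write_counts,
    write_gmt,
    write_json,
    write_paired_expr,
)
from .lcl import mirna_gene_assoc, paired_moderated_t, target_enrichment
from .mirna import filter_low_counts, gpca_batch_test, normalize
from .network import (
    cut_modules,
    module_eigengene,
    module_mirna_assoc,
    module_trait_assoc,
    paired_correlation,
    pick_soft_power,
    topological_overlap,
)
from .predict import compare_models, evaluate_frozen, fit_models
from .simulate import (
    CohortConfig,
    LclConfig,
    generate_cohort,
    generate_lcl,
    generate_target_sets,
)


@dataclass
class PipelineConfig:
    """Stage toggles, cohort/expression conditions, and thresholds."""

    seed: int = 0
    discovery: CohortConfig = field(
        default_factory=lambda: CohortConfig(batch_fraction=0.5, batch_shift=0.0)
    )
    replication: CohortConfig = field(
        default_factory=lambda: CohortConfig(
            n_subjects=187, n_mirna=257, batch_fraction=0.0
        )
    )
    lcl: LclConfig = field(
        default_factory=lambda: LclConfig(
            coupled_module_index=0, coupling_strength=0.8
        )
    )

    # significance thresholds (the analysis defaults)
    min_count: int = 5
    min_frac: float = 0.5
    fdr_discovery: float = 0.10
    alpha_replication: float = 0.05
    fdr_de: float = 0.10
    fdr_network: float = 0.10
    fdr_traits: float = 0.05

    n_boot: int = 1000
    gpca_permutations: int = 1000
    max_assoc_genes: int = 300
    min_module_size: int = 30
    target_set_size_range: tuple[int, int] = (150, 800)
    target_de_bias: float = 0.3  # fraction of target genes drawn from shifted probes

    # stage toggles
    run_assoc: bool = True
    run_predict: bool = True
    run_lcl: bool = True
    run_network: bool = True

    def __post_init__(self) -> None:
        for name in ("min_frac", "fdr_discovery", "alpha_replication",
                     "fdr_de", "fdr_network", "fdr_traits"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derive_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "results": {},
    }
    res = manifest["results"]

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---------------------------------------------------------- synthesize
    disc_cfg = CohortConfig(**{**asdict(config.discovery),
                               "seed": _derive_seed(config.seed, 1)})
    clinical_d, counts_d, truth_d = generate_cohort(disc_cfg)
    causal_names = truth_d["causal_mirnas"]
    # same causal miRNAs planted in the replication cohort (shared id space)
    causal_idx = tuple(
        i for i in range(config.replication.n_mirna)
        if f"miR-{i:04d}" in set(causal_names)
    )
    rep_cfg = CohortConfig(**{
        **asdict(config.replication),
        "n_true_mirna": len(causal_idx),
        "causal_mirna_indices": causal_idx,
        # same planted per-miRNA effects as discovery (true replication)
        "causal_betas": tuple(
            truth_d["causal_betas"][f"miR-{i:04d}"] for i in causal_idx
        ),
        "seed": _derive_seed(config.seed, 2),
    })
    clinical_r, counts_r, truth_r = generate_cohort(rep_cfg)
    write_clinical(clinical_d, outdir / "clinical_discovery.tsv")
    write_clinical(clinical_r, outdir / "clinical_replication.tsv")
    write_counts(counts_d, outdir / "counts_discovery.tsv")
    write_counts(counts_r, outdir / "counts_replication.tsv")
    write_json(truth_d, outdir / "truth_discovery.json")
    write_json(truth_r, outdir / "truth_replication.json")
    manifest["stages"].append("synthesize")

    # --------------------------------------------------------------- CASTER
    try:
        caster_d = compute_caster(clinical_d)
        caster_r = compute_caster(clinical_r)
    except Exception as exc:  # noqa: BLE001
        fail("caster", exc)
    for name, cres in (("discovery", caster_d), ("replication", caster_r)):
        cres.to_frame().to_csv(outdir / f"caster_{name}.tsv", sep="\t")
        n_poor, n_good = caster_group_sizes(cres)
        res[f"caster_{name}"] = {
            "threshold": cres.threshold, "n_poor": n_poor, "n_good": n_good,
        }
    manifest["stages"].append("caster")

    # -------------------------------------------- filter / normalize / gPCA
    try:
        kept_d = filter_low_counts(counts_d, config.min_count, config.min_frac)
        kept_r = filter_low_counts(counts_r, config.min_count, config.min_frac)
        norm_d = normalize(kept_d)
        norm_r = normalize(kept_r)
    except Exception as exc:  # noqa: BLE001
        fail("mirna", exc)
    res["mirna_filter"] = {
        "discovery_kept": int(kept_d.shape[0]),
        "replication_kept": int(kept_r.shape[0]),
    }
    norm_d.size_factors.to_csv(outdir / "size_factors_discovery.tsv", sep="\t")
    batch = clinical_d["batch"]
    if batch.nunique() > 1:
        g = gpca_batch_test(
            norm_d, batch, n_permutations=config.gpca_permutations,
            seed=_derive_seed(config.seed, 3),
        )
        res["gpca"] = {"delta": g.delta, "p_value": g.p_value}
    manifest["stages"].append("mirna")

    # ----------------------------------------------- associate + replicate
    replicated: list[str] = []
    if config.run_assoc:
        covars_d = clinical_d[["age", "sex"]]
        covars_r = clinical_r[["age", "sex"]]
        try:
            assoc_d = logistic_assoc(norm_d, caster_d, covars_d)
            assoc_r = logistic_assoc(norm_r, caster_r, covars_r)
            replicated = replicate(
                assoc_d, assoc_r, fdr=config.fdr_discovery,
                alpha=config.alpha_replication,
            )
        except Exception as exc:  # noqa: BLE001
            fail("assoc", exc)
        assoc_d.to_csv(outdir / "assoc_discovery.tsv", sep="\t")
        assoc_r.to_csv(outdir / "assoc_replication.tsv", sep="\t")
        hits = assoc_d[assoc_d["q"] < config.fdr_discovery]
        res["assoc"] = {
            "discovery_tested": int(assoc_d["converged"].sum()),
            "discovery_hits": int(len(hits)),
            "hits_or_gt_1": int((hits["or_"] > 1).sum()),
            "replicated": replicated,
            "n_replicated": len(replicated),
        }
        manifest["stages"].append("assoc")

    # --------------------------------------------------------------- predict
    marker_mirnas = replicated
    if config.run_predict and config.run_assoc:
        if not marker_mirnas:
            # fall back to the top discovery hits so the stage stays testable
            marker_mirnas = list(
                assoc_d[assoc_d["converged"].astype(bool)]
                .sort_values("q").head(3).index
            )
            res.setdefault("assoc", {})["predict_marker_fallback"] = True
        marker_mirnas = [m for m in marker_mirnas if m in norm_r.values.index][:10]
        try:
            feats_d = _predict_features(clinical_d, norm_d, marker_mirnas)
            feats_r = _predict_features(clinical_r, norm_r, marker_mirnas)
            clinical_vars = ["age", "sex_male", "log10_ige", "log10_eos"]
            specs = {
                "M1": clinical_vars,
                "M2": list(marker_mirnas),
                "M3": clinical_vars + list(marker_mirnas),
            }
            y_d = caster_d.poor_mask.astype(int)
            y_r = caster_r.poor_mask.astype(int)
            fits = fit_models(feats_d, y_d, specs)
            evals = {
                mid: evaluate_frozen(
                    fit, feats_r, y_r, n_boot=config.n_boot,
                    seed=_derive_seed(config.seed, 4),
                )
                for mid, fit in fits.items()
            }
            lrt_13 = compare_models(fits["M1"], fits["M3"], feats_d, y_d)
            lrt_23 = compare_models(fits["M2"], fits["M3"], feats_d, y_d)
        except Exception as exc:  # noqa: BLE001
            fail("predict", exc)
        write_json({m: f.to_dict() for m, f in fits.items()}, outdir / "models.json")
        res["predict"] = {
            "markers": list(marker_mirnas),
            **{
                mid: {"auc": e.auc, "ci_low": e.ci_low, "ci_high": e.ci_high}
                for mid, e in evals.items()
            },
            "lrt_m1_vs_m3": {"stat": lrt_13[0], "p": lrt_13[1]},
            "lrt_m2_vs_m3": {"stat": lrt_23[0], "p": lrt_23[1]},
        }
        manifest["stages"].append("predict")

    # ------------------------------------------------- paired DE + network
    if config.run_lcl or config.run_network:
        lcl_mirna = marker_mirnas[0] if marker_mirnas else None
        n_pairs = config.lcl.n_pairs
        lcl_subjects = list(clinical_r.index[:n_pairs])
        if lcl_mirna is not None and lcl_mirna in norm_r.values.index:
            levels = norm_r.values.loc[lcl_mirna, lcl_subjects].to_numpy()
        else:
            levels = None
        lcl_cfg = LclConfig(**{
            **asdict(config.lcl),
            "module_size_range": tuple(config.lcl.module_size_range),
            "seed": _derive_seed(config.seed, 5),
        })
        x, truth_lcl = generate_lcl(lcl_cfg, mirna_levels=levels)
        # rename simulated subjects to the replication subjects they represent
        rename = dict(zip(sorted(x.samples["subject_id"].unique()), lcl_subjects))
        x.samples["subject_id"] = x.samples["subject_id"].map(rename)
        truth_lcl["subject_map"] = rename
        write_paired_expr(x, outdir / "lcl_expression.tsv", outdir / "lcl_samples.tsv")
        write_json(truth_lcl, outdir / "truth_lcl.json")

        # per-subject miRNA levels and covariates for the LCL subjects
        mir_ids = marker_mirnas if marker_mirnas else list(norm_r.values.index[:3])
        mir_levels = norm_r.values.loc[mir_ids, lcl_subjects]
        covars = pd.DataFrame({
            "age": clinical_r.loc[lcl_subjects, "age"].astype(float),
            "sex_male": (clinical_r.loc[lcl_subjects, "sex"] == "M").astype(float),
        })

    if config.run_lcl:
        try:
            de = paired_moderated_t(x)
            de.to_csv(outdir / "de_table.tsv", sep="\t")
            targets = _biased_target_sets(config, truth_lcl, mir_ids)
            write_gmt(targets, outdir / "target_sets.gmt")
            enr = target_enrichment(de, targets, fdr=config.fdr_de)
            de_genes = list(
                de[de["q"] < config.fdr_de].sort_values("q")
                .head(config.max_assoc_genes).index
            )
            gene_assoc = mirna_gene_assoc(x, de_genes, mir_levels, covars)
            gene_assoc.to_csv(outdir / "mirna_gene_assoc.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            fail("lcl", exc)
        res["lcl"] = {
            "n_pairs": int(de.attrs["n_pairs"]),
            "n_probes": int(de.shape[0]),
            "n_de": int((de["q"] < config.fdr_de).sum()),
            "df_prior": de.attrs["df_prior"],
            "enrichment": asdict(enr),
            "n_gene_assoc_hits": int((gene_assoc["q"] < config.fdr_de).sum()),
        }
        manifest["stages"].append("lcl")

    if config.run_network:
        try:
            cor = paired_correlation(x)
            power, sf_table = pick_soft_power(cor)
            adj = np.abs(cor.to_numpy()) ** power
            tom = topological_overlap(adj)
            # refinement on within-pair differences: free of the shared
            # subject offset that would couple every probe to every eigengene
            assignment = cut_modules(
                tom, min_module_size=config.min_module_size,
                values=x.paired_differences(), probe_ids=cor.index,
            )
            eig = module_eigengene(x.values, assignment)
            mod_mirna = module_mirna_assoc(
                eig, mir_levels, covars, x.samples, fdr=config.fdr_network
            )
            traits = pd.DataFrame({
                "age": clinical_r.loc[lcl_subjects, "age"].astype(float),
                "caster_score": caster_r.scores.reindex(lcl_subjects),
            })
            mod_trait = module_trait_assoc(
                eig, traits, None, x.samples, fdr=config.fdr_traits
            )
        except Exception as exc:  # noqa: BLE001
            fail("network", exc)
        assignment.rename_axis("probe").to_csv(outdir / "modules.tsv", sep="\t")
        eig.to_csv(outdir / "eigengenes.tsv", sep="\t")
        mod_mirna.to_csv(outdir / "module_mirna_assoc.tsv", sep="\t", index=False)
        mod_trait.to_csv(outdir / "module_trait_assoc.tsv", sep="\t", index=False)
        n_modules = int(assignment[assignment != "grey"].nunique())
        res["network"] = {
            "soft_power": int(power),
            "n_modules": n_modules,
            "n_grey": int((assignment == "grey").sum()),
            "n_module_mirna_hits": int(mod_mirna["significant"].sum()),
            "n_module_trait_hits": int(mod_trait["significant"].sum()),
        }
        manifest["stages"].append("network")

    write_json(manifest, outdir / "manifest.json")
    return manifest


def _predict_features(
    clinical: pd.DataFrame, norm, marker_mirnas: list[str]
) -> pd.DataFrame:
    feats = pd.DataFrame(index=clinical.index)
    feats["age"] = clinical["age"].astype(float)
    feats["sex_male"] = (clinical["sex"] == "M").astype(float)
    for col in ("log10_ige", "log10_eos"):
        if col in clinical.columns:
            feats[col] = clinical[col].astype(float)
    expr = norm.values
    for m in marker_mirnas:
        feats[m] = expr.loc[m].reindex(feats.index)
    return feats


def _biased_target_sets(
    config: PipelineConfig, truth_lcl: dict, mir_ids: list[str]
) -> dict[str, set]:
    """Target sets for the marker miRNAs, a fraction drawn from probes
    with the largest planted treatment shifts (so enrichment among
    DEX-responsive genes is detectable by construction)."""
    shifts = pd.Series(truth_lcl["treatment_shift"])
    probes = list(shifts.index)
    n_shifted = max(1, int(len(probes) * 0.3))
    shifted = list(shifts.abs().sort_values(ascending=False).index[:n_shifted])
    rng = np.random.default_rng(_derive_seed(config.seed, 6))
    lo, hi = config.target_set_size_range
    hi = min(hi, len(probes))
    out: dict[str, set] = {}
    for m in mir_ids:
        k = int(rng.integers(lo, hi + 1))
        k_de = int(round(k * config.target_de_bias))
        chosen = set(rng.choice(shifted, size=min(k_de, len(shifted)), replace=False))
        rest = [p for p in probes if p not in chosen]
        chosen |= set(rng.choice(rest, size=k - len(chosen), replace=False))
        out[m] = chosen
    return out
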