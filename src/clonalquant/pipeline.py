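"""End-to-end orchestration: transform -> variance decomposition ->
heritability -> BLUP -> PCA -> distances/Mantel.

The pipeline reproduces the analysis flow of a clonal common-garden
study.  Scale conventions: F-tests and BLUPs are computed on the
transformed scale (where a variance-stabilising transform is
assigned), while genetic variance, heritability and the genetic CV are
reported on the raw measurement scale so the CV is interpretable
against the raw trait mean.  Traits with low heritability or no
significant genotype effect are excluded from the multivariate and
distance stages, mirroring standard practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clonalquant.distance import mantel_test, p_distance, phenotypic_distance
from clonalquant.multivariate import pca_on_blups
from clonalquant.quantgen import (
    blup_matrix,
    bootstrap_h2_ci,
    broad_sense_h2,
    genetic_cv,
    summarize_heritability,
)
from clonalquant.tables import validate_phenotype_table
from clonalquant.transforms import DEFAULT_TRANSFORMS, apply_transforms
from clonalquant.varcomp import ems_decompose, reml_decompose, variance_percent

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    ``trait_categories`` maps every trait to one category (e.g.
    digestive / life_history / morphology); traits not mapped go to
    'uncategorized'.  ``h2_threshold`` and
    ``require_significant_genotype`` define the exclusion rule for the
    multivariate stages.  ``decomposition`` is 'ems', 'reml' or 'auto'
    (EMS when balanced, REML otherwise).
    """

    phenotype_csv: str | None = None
    snp_tsv: str | None = None
    output_dir: str = "clonalquant_out"
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    trait_categories: dict = field(default_factory=dict)
    h2_threshold: float = 0.1
    require_significant_genotype: bool = True
    alpha: float = 0.05
    bonferroni: bool = True
    decomposition: str = "auto"
    vt_definition: str = "random"
    var_percent_include_fixed: bool = True
    n_boot: int = 1000
    seed: int = 0
    per_food_distances: bool = True

    def __post_init__(self):
        if not 0.0 <= self.h2_threshold <= 1.1:
            raise ValueError("h2_threshold out of range")
        if self.decomposition not in ("ems", "reml", "auto"):
            raise ValueError("decomposition must be 'ems', 'reml' or 'auto'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        return cls(**data)


def _decompose(table, trait, how):
    if how == "ems":
        return ems_decompose(table, trait)
    if how == "reml":
        return reml_decompose(table, trait)
    try:
        return ems_decompose(table, trait)
    except ValueError:
        return reml_decompose(table, trait)


def run_pipeline(
    config: PipelineConfig,
    table: pd.DataFrame | None = None,
    snp: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write CSV outputs under ``config.output_dir``.

    Returns a report dict with the per-stage results (ANOVA summary,
    heritability table, BLUP matrix, PCA, distance matrices, Mantel
    results, run log).  Any stage failure raises with the stage name
    and offending trait in the message.
    """
    if table is None:
        if config.phenotype_csv is None:
            raise ValueError("no phenotype table given (argument or phenotype_csv)")
        table = pd.read_csv(config.phenotype_csv)
    validate_phenotype_table(table)
    if snp is None and config.snp_tsv is not None:
        snp = pd.read_csv(config.snp_tsv, sep="\t", index_col=0)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"decomposition={config.decomposition}"]
    traits = sorted(table["trait"].unique())
    n_tests = len(traits)
    alpha = config.alpha / n_tests if config.bonferroni else config.alpha
    log.append(f"traits={n_tests} alpha_per_test={alpha:.6g}")

    # stage: transforms
    try:
        transformed = apply_transforms(table, config.transforms)
    except ValueError as err:
        raise RuntimeError(f"stage=transforms: {err}") from err

    # stage: variance decomposition + F-tests (transformed scale)
    anova_rows = []
    decomps = {}
    for trait in traits:
        try:
            d = _decompose(transformed, trait, config.decomposition)
        except ValueError as err:
            raise RuntimeError(f"stage=varcomp trait={trait}: {err}") from err
        decomps[trait] = d
        pct = variance_percent(
            d, include_fixed=config.var_percent_include_fixed and d.sigma2_f_quasi is not None
        )
        row = {
            "trait": trait,
            "sigma2_g": d.sigma2_g,
            "sigma2_gf": d.sigma2_gf,
            "sigma2_e": d.sigma2_e,
            "method": d.method,
        }
        for term, v in pct.items():
            row[f"var_pct_{term}"] = v
        if d.f_tests is not None:
            for term in ("genotype", "food", "interaction"):
                row[f"F_{term}"] = d.f_tests.loc[term, "F"]
                row[f"p_{term}"] = d.f_tests.loc[term, "p"]
        anova_rows.append(row)
    anova_summary = pd.DataFrame(anova_rows).set_index("trait")
    anova_summary.to_csv(out / "anova_summary.csv")

    # stage: heritability (raw scale)
    herit_rows = []
    estimates = []
    rng = np.random.default_rng(config.seed)
    for trait in traits:
        try:
            d_raw = _decompose(table, trait, config.decomposition)
            est = broad_sense_h2(d_raw, config.vt_definition)
            est.mu = float(table.loc[table["trait"] == trait, "value"].mean())
            if est.mu > 0:
                est.cv_percent = genetic_cv(est.v_g, est.mu)
            ci_seed = int(rng.integers(0, 2**31 - 1))
            est.ci_low, est.ci_high = bootstrap_h2_ci(
                table, trait, n_boot=config.n_boot, seed=ci_seed,
                vt_definition=config.vt_definition,
            )
        except ValueError as err:
            raise RuntimeError(f"stage=heritability trait={trait}: {err}") from err
        estimates.append(est)
        herit_rows.append(
            {
                "trait": trait,
                "category": config.trait_categories.get(trait, "uncategorized"),
                "mu": est.mu,
                "v_g": est.v_g,
                "v_t": est.v_t,
                "h2": est.h2,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "cv_percent": est.cv_percent,
            }
        )
    heritability = pd.DataFrame(herit_rows).set_index("trait")
    heritability.to_csv(out / "heritability.csv")
    h2_mean, h2_min, h2_max = summarize_heritability(estimates)
    log.append(f"h2 mean={h2_mean:.4f} range=({h2_min:.4f}, {h2_max:.4f})")

    # stage: trait exclusion for the multivariate stages
    eligible = []
    for trait in traits:
        h2 = heritability.loc[trait, "h2"]
        if h2 < config.h2_threshold:
            log.append(f"excluded {trait}: h2={h2:.3f} < {config.h2_threshold}")
            continue
        if config.require_significant_genotype:
            ft = decomps[trait].f_tests
            if ft is not None and ft.loc["genotype", "p"] > alpha:
                log.append(
                    f"excluded {trait}: genotype p={ft.loc['genotype', 'p']:.4g} > {alpha:.4g}"
                )
                continue
        eligible.append(trait)
    log.append(f"eligible traits: {len(eligible)}/{n_tests}")

    report: dict = {
        "anova_summary": anova_summary,
        "heritability": heritability,
        "h2_summary": {"mean": h2_mean, "min": h2_min, "max": h2_max},
        "eligible_traits": eligible,
        "pca": None,
        "blups": None,
        "distances": {},
        "mantel": {},
    }

    if not eligible:
        log.append("no eligible traits: PCA and distance stages skipped")
        _write_log(out, log)
        report["log"] = log
        return report

    # stage: BLUPs (transformed scale) and PCA
    try:
        blups = blup_matrix(transformed, eligible, method="reml")
    except ValueError as err:
        raise RuntimeError(f"stage=blup: {err}") from err
    blups.to_csv(out / "blups.csv")
    report["blups"] = blups

    nonconstant = [t for t in eligible if blups[t].std(ddof=1) > 0]
    dropped = sorted(set(eligible) - set(nonconstant))
    if dropped:
        log.append(f"dropped constant-BLUP traits from PCA/distances: {dropped}")
    if len(nonconstant) >= 2 and blups.shape[0] >= 3:
        pca = pca_on_blups(blups[nonconstant])
        report["pca"] = pca
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pca.scores.to_csv(out / "pca_scores.csv")
        pd.DataFrame(
            {
                "eigenvalue": pca.eigenvalues,
                "contribution_percent": pca.contribution_percent,
                "cumulative_percent": pca.cumulative_percent,
            },
            index=pca.loadings.columns,
        ).to_csv(out / "pca_summary.csv")
        log.append(f"pca retained {pca.retained} components (eigenvalue > 1)")
    else:
        log.append("pca skipped: fewer than 2 usable traits or < 3 genotypes")

    # stage: phenotypic distances (overall, per category, per food level)
    categories = sorted(
        {config.trait_categories.get(t, "uncategorized") for t in nonconstant}
    )
    scopes = {"overall": nonconstant}
    for cat in categories:
        members = [
            t for t in nonconstant
            if config.trait_categories.get(t, "uncategorized") == cat
        ]
        if members:
            scopes[cat] = members

    def blups_for(subtable, label):
        mats = {}
        try:
            b = blup_matrix(subtable, nonconstant, method="reml")
        except ValueError as err:
            raise RuntimeError(f"stage=distance food={label}: {err}") from err
        for name, members in scopes.items():
            cols = [t for t in members if b[t].std(ddof=1) > 0]
            if cols and b.shape[0] >= 3:
                mats[f"{name}:{label}"] = phenotypic_distance(b, cols, name)
        return mats

    distances = blups_for(transformed, "combined")
    if config.per_food_distances:
        for food in sorted(table["food"].unique()):
            sub = transformed.loc[transformed["food"] == food]
            distances.update(blups_for(sub, f"{food:g}"))
    for key, dm in distances.items():
        dm.to_csv(out / f"distance_{key.replace(':', '_')}.csv")
    report["distances"] = distances

    # stage: genetic distance and Mantel tests
    if snp is not None:
        gdist = p_distance(snp)
        gdist.to_csv(out / "distance_genetic.csv")
        report["distances"]["genetic"] = gdist
        mantel_rows = []
        for key, dm in distances.items():
            if dm.kind != "phenotypic":
                continue
            if tuple(dm.labels) != tuple(gdist.labels):
                log.append(f"mantel skipped for {key}: label mismatch")
                continue
            try:
                res = mantel_test(dm, gdist, seed=config.seed)
            except ValueError as err:
                log.append(f"mantel skipped for {key}: {err}")
                continue
            report["mantel"][key] = res
            mantel_rows.append(
                {
                    "scope": key,
                    "r": res.r,
                    "p": res.p,
                    "n_permutations": res.n_permutations,
                    "exhaustive": res.exhaustive,
                    "tail": res.tail,
                }
            )
        if mantel_rows:
            pd.DataFrame(mantel_rows).to_csv(out / "mantel.csv", index=False)

    _write_log(out, log)
    report["log"] = log
    return report


def _write_log(out: Path, log: list[str]) -> None:
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
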