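"""End-to-end analysis pipeline and run configuration.

Stages: genotype QC (call rate, MAF, Hardy-Weinberg) → within-chromosome LD
estimation and tag-SNP pruning → per-SNP GLMs with risk-allele assignment →
GRS construction (additive and weighted × pathway/total/top-hits scopes) →
GRS-phenotype models over the configured covariate sets → median-split risk
group comparison → sex-stratified reruns → SNP-SNP interaction scan.  Every
artifact is written to the output directory with a manifest (inputs,
thresholds, seed, package versions, output hashes) sufficient to re-execute
the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancestry import compute_pcs
from .association import (
    associate_panel,
    association_table,
    prepare_phenotype,
    scan_interactions,
)
from .genotypes import GenotypeMatrix, read_genotype_csv, read_genotype_vcf
from .grs import GrsVector, build_all_definitions, compute_grs
from .grs_models import (
    compare_risk_groups,
    fit_grs_model,
    grs_results_table,
    stratify_by_sex,
)
from .panel import SnpPanel, load_default_panel, read_panel
from .qc import apply_qc_filters, ld_table, prune_ld_groups, qc_report

logger = logging.getLogger("pathgrs")

__all__ = ["RunConfig", "PipelineResult", "read_phenotypes", "run_pipeline"]

PHENOTYPE_COLUMNS = {"TG": "tg", "HDL": "hdl"}


class PipelineError(RuntimeError):
    pass


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype CSV: individual_id, age, sex (1=male), bmi, tg, hdl."""
    df = pd.read_csv(path, index_col=0)
    required = {"age", "sex", "bmi", "tg", "hdl"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"phenotype table lacks columns: {sorted(missing)}")
    if (df["tg"].dropna() <= 0).any() or (df["hdl"].dropna() <= 0).any():
        raise PipelineError("nonpositive lipid concentration in phenotype table")
    if ((df["age"].dropna() < 10) | (df["age"].dropna() > 100)).any():
        raise PipelineError("implausible age in phenotype table")
    return df


@dataclass
class RunConfig:
    genotypes: str | Path
    phenotypes: str | Path
    panel: str | Path | None = None
    aims: str | Path | None = None
    out_dir: str | Path = "pathgrs_run"
    phenotype_names: tuple[str, ...] = ("TG", "HDL")
    hwe_alpha: float = 0.05
    min_call_rate: float = 0.9
    d_prime_threshold: float = 0.8
    r2_threshold: float = 0.1
    top_hits_alpha: float = 0.10
    n_pcs: int = 2
    with_bmi: bool = True
    with_pcs: bool = True
    run_interactions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "d_prime_threshold", "r2_threshold", "top_hits_alpha"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise PipelineError(f"{name}={value} outside (0, 1]")
        for attr in ("genotypes", "phenotypes", "panel", "aims"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{attr} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "phenotype_names" in data:
            data["phenotype_names"] = tuple(data["phenotype_names"])
        return cls(**data)


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    ld: pd.DataFrame
    retained: dict[str, list[str]]  # per phenotype, post-QC post-prune
    associations: dict[str, pd.DataFrame]  # per phenotype
    definitions: dict[tuple[str, str, str], object]  # (phenotype, weighting, scope)
    vectors: dict[tuple[str, str, str], GrsVector]
    grs_results: pd.DataFrame
    risk_groups: pd.DataFrame
    stratified: pd.DataFrame
    interactions: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_genotypes(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_genotype_vcf(path, panel)
    return read_genotype_csv(path, panel=panel)


def _chromosome_pairs(panel: SnpPanel, snp_ids: list[str]) -> list[tuple[str, str]]:
    """Pairs of analysed SNPs on the same chromosome (the within-gene or
    within-chromosome scope LD screening uses)."""
    by_chrom: dict[str, list[str]] = {}
    for snp in snp_ids:
        by_chrom.setdefault(panel.get(snp).chromosome, []).append(snp)
    pairs = []
    for members in by_chrom.values():
        pairs.extend(
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        )
    return pairs


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    out_dir = Path(config.out_dir)
    panel = read_panel(config.panel) if config.panel else load_default_panel()
    genotypes = _load_genotypes(config.genotypes, panel)
    phenotypes = read_phenotypes(config.phenotypes)

    common = genotypes.codes.index.intersection(phenotypes.index)
    if len(common) < 30:
        raise PipelineError(f"only {len(common)} individuals shared by genotypes and phenotypes")
    genotypes = GenotypeMatrix(genotypes.codes.loc[common], panel=panel)
    phenotypes = phenotypes.loc[common]
    logger.info("analysing %d individuals, %d SNPs", len(common), len(genotypes.snp_ids))

    # --- QC ---------------------------------------------------------------
    qc = qc_report(genotypes, hwe_alpha=config.hwe_alpha, min_call_rate=config.min_call_rate)
    retained_qc = apply_qc_filters(qc)
    logger.info("QC retained %d/%d SNPs", len(retained_qc), len(qc))

    # --- LD ---------------------------------------------------------------
    pairs = _chromosome_pairs(panel, retained_qc)
    ld = ld_table(genotypes, pairs=pairs) if pairs else pd.DataFrame(
        columns=["snp_a", "snp_b", "d_prime", "r2", "em_converged", "em_iterations", "n"]
    )

    # --- covariates -------------------------------------------------------
    base_covs = phenotypes[["age", "sex"]]
    pcs = None
    if config.aims is not None and config.with_pcs:
        aims = read_genotype_csv(config.aims)
        aims = GenotypeMatrix(aims.codes.loc[aims.codes.index.intersection(common)])
        ancestry = compute_pcs(aims, n_components=config.n_pcs)
        pcs = ancestry.as_covariates().reindex(common)

    transforms = {
        name: prepare_phenotype(phenotypes[PHENOTYPE_COLUMNS[name]])[1]
        for name in config.phenotype_names
    }

    retained: dict[str, list[str]] = {}
    associations_raw: dict[str, dict] = {}
    associations: dict[str, pd.DataFrame] = {}
    definitions, vectors = {}, {}
    grs_rows, risk_rows, strat_rows = [], [], []
    interactions: dict[str, pd.DataFrame] = {}

    for name in config.phenotype_names:
        column = PHENOTYPE_COLUMNS[name]
        values = phenotypes[column]
        transform = transforms[name]

        # variance explained by each QC-passing SNP → tag-SNP pruning
        pre_assoc = associate_panel(
            genotypes, values, panel, name,
            covariates=base_covs, snp_ids=retained_qc,
            transform=transform, ls_means=False,
        )
        var_explained = {s: a.partial_r2 for s, a in pre_assoc.items()}
        maf = {s: float(qc.loc[s, "maf"]) for s in retained_qc}
        prune = prune_ld_groups(
            ld[ld["snp_a"].isin(retained_qc) & ld["snp_b"].isin(retained_qc)],
            var_explained,
            maf=maf,
            d_prime_threshold=config.d_prime_threshold,
            r2_threshold=config.r2_threshold,
        )
        dropped = set(prune["dropped"])
        kept = [s for s in retained_qc if s not in dropped]
        retained[name] = kept
        logger.info("%s: LD pruning dropped %d SNPs (%s)", name, len(dropped), sorted(dropped))

        assoc = {s: pre_assoc[s] for s in kept}
        associations_raw[name] = assoc
        associations[name] = association_table(assoc)

        cov_sets: list[pd.DataFrame] = [base_covs]
        if config.with_bmi:
            cov_sets.append(phenotypes[["age", "sex", "bmi"]])
        if pcs is not None:
            cov_sets.append(base_covs.join(pcs))
            if config.with_bmi:
                cov_sets.append(phenotypes[["age", "sex", "bmi"]].join(pcs))

        for weighting in ("additive", "weighted"):
            defs = build_all_definitions(
                panel, name,
                retained_snps=kept, associations=assoc,
                weighting=weighting, top_hits_alpha=config.top_hits_alpha,
            )
            for scope, definition in defs.items():
                if not definition.members:
                    continue
                key = (name, weighting, scope)
                definitions[key] = definition
                vector = compute_grs(genotypes, definition)
                vectors[key] = vector
                for covs in cov_sets:
                    result = fit_grs_model(values, vector, covariates=covs, transform=transform)
                    grs_rows.append(result)
                comparison = compare_risk_groups(values, vector, name, transform=transform)
                risk_rows.append(
                    {
                        "phenotype": name,
                        "weighting": weighting,
                        "scope": scope,
                        "median": vector.median,
                        "mean_high": comparison.mean_high,
                        "se_high": comparison.se_high,
                        "mean_low": comparison.mean_low,
                        "se_low": comparison.se_low,
                        "n_high": comparison.n_high,
                        "n_low": comparison.n_low,
                        "t_p": comparison.t_p,
                    }
                )
                by_sex = stratify_by_sex(values, vector, base_covs, transform=transform)
                for stratum, res in by_sex.items():
                    strat_rows.append(
                        {
                            "phenotype": name,
                            "weighting": weighting,
                            "scope": scope,
                            "stratum": stratum,
                            "grs_p": res.grs_p,
                            "model_r2": res.model_r2,
                            "beta": res.beta,
                            "n": res.n_used,
                        }
                    )

        if config.run_interactions:
            all_pairs = [
                (kept[i], kept[j]) for i in range(len(kept)) for j in range(i + 1, len(kept))
            ]
            interactions[name] = scan_interactions(
                genotypes, values, all_pairs, covariates=base_covs, transform=transform
            )

    result = PipelineResult(
        qc=qc,
        ld=ld,
        retained=retained,
        associations=associations,
        definitions=definitions,
        vectors=vectors,
        grs_results=grs_results_table(grs_rows),
        risk_groups=pd.DataFrame(risk_rows),
        stratified=pd.DataFrame(strat_rows),
        interactions=interactions,
    )

    if write:
        _write_bundle(result, config, out_dir)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    save(result.qc, "qc_report.tsv")
    save(result.ld, "ld_table.tsv", index=False)
    for name, table in result.associations.items():
        save(table, f"assoc_{name}.tsv")
    save(result.grs_results, "grs_results.tsv", index=False)
    save(result.risk_groups, "risk_groups.tsv", index=False)
    save(result.stratified, "stratified.tsv", index=False)
    for name, table in result.interactions.items():
        save(table, f"interactions_{name}.tsv", index=False)

    defs_dir = out_dir / "grs_definitions"
    defs_dir.mkdir(exist_ok=True)
    scores = {}
    for (phenotype, weighting, scope), definition in result.definitions.items():
        stem = f"{phenotype}_{weighting}_{scope}".lower()
        path = defs_dir / f"{stem}.json"
        payload = definition.to_dict()
        payload["median"] = result.vectors[(phenotype, weighting, scope)].median
        path.write_text(json.dumps(payload, indent=2))
        written.append(path)
        scores[stem] = result.vectors[(phenotype, weighting, scope)].scores
    scores_df = pd.DataFrame(scores)
    scores_df.index.name = "individual_id"
    save(scores_df, "grs_scores.csv")

    manifest = {
        "package": "pathgrs",
        "version": __version__,
        "inputs": {
            "genotypes": str(config.genotypes),
            "phenotypes": str(config.phenotypes),
            "panel": str(config.panel) if config.panel else "packaged:up-amigos-lipid-grs",
            "aims": str(config.aims) if config.aims else None,
        },
        "thresholds": {
            "hwe_alpha": config.hwe_alpha,
            "min_call_rate": config.min_call_rate,
            "d_prime_threshold": config.d_prime_threshold,
            "r2_threshold": config.r2_threshold,
            "top_hits_alpha": config.top_hits_alpha,
        },
        "seed": config.seed,
        "retained_snps": result.retained,
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in written},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result.manifest = manifest
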