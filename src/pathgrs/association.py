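"""Per-SNP general linear models for lipid phenotypes.

Each SNP is fitted twice on the complete cases: an additive-dosage OLS fit
(effect per counted-allele copy — the β used for weighted scores and partial
R²) and a genotype-as-category fit from which least-squares (covariate-
adjusted) class means and Tukey–Kramer pairwise comparisons are derived.
Phenotypes failing a Shapiro–Wilk normality check are analysed on the
natural-log scale and class means are back-transformed (geometric means).

The risk allele for a SNP is the allele whose carriage points in the adverse
direction: higher TG, lower HDL-C.  Under additive coding this is the sign
of β; it is determined per phenotype and may differ between the two lipids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix
from .panel import SnpPanel

__all__ = [
    "AssociationError",
    "prepare_phenotype",
    "SnpAssociation",
    "fit_snp_model",
    "determine_risk_allele",
    "associate_panel",
    "association_table",
    "scan_interactions",
]

ADVERSE_DIRECTION = {"TG": +1, "HDL": -1}  # sign of the adverse phenotype shift


class AssociationError(ValueError):
    pass


def prepare_phenotype(
    values: pd.Series, alpha: float = 0.05, force: str | None = None
) -> tuple[pd.Series, str]:
    """Normality-gated transform: returns (values-for-analysis, transform).

    ``transform`` is ``"log"`` (natural log, applied when Shapiro–Wilk
    rejects normality at *alpha*) or ``"identity"``.  Pass ``force`` to pin
    the choice.  Log transform of nonpositive values is an error.
    """
    clean = values.dropna()
    if force is None:
        _, p = stats.shapiro(clean.to_numpy())
        transform = "log" if p < alpha else "identity"
    else:
        if force not in ("log", "identity"):
            raise AssociationError(f"unknown transform {force!r}")
        transform = force
    if transform == "log":
        if (clean <= 0).any():
            raise AssociationError("log transform requires strictly positive values")
        return np.log(values), transform
    return values.astype(float), transform


def back_transform(mean: float, se: float, transform: str) -> tuple[float, float]:
    """Report a fitted mean on the interpretation scale (delta-method SE)."""
    if transform == "log":
        return float(np.exp(mean)), float(np.exp(mean) * se)
    return float(mean), float(se)


@dataclass
class SnpAssociation:
    snp_id: str
    phenotype: str
    transform: str
    beta: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float
    partial_r2: float
    n_used: int
    ls_means: pd.DataFrame | None = field(default=None, repr=False)
    pairwise_p: dict[tuple[float, float], float] = field(default_factory=dict, repr=False)
    risk_allele: str | None = None
    risk_ambiguous: bool = False
    covariates: tuple[str, ...] = ()


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, X)
    return model.fit()


def fit_snp_model(
    phenotype: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame | None = None,
    phenotype_name: str = "TG",
    transform: str = "identity",
    snp_id: str | None = None,
    ls_means: bool = True,
) -> SnpAssociation:
    """Additive OLS fit of a (transformed) phenotype on one SNP's dosage.

    ``phenotype`` must already be on the analysis scale (see
    :func:`prepare_phenotype`); ``transform`` records how to back-transform.
    Partial R² is the Type-III sum of squares of the SNP term over the
    corrected total SS, i.e. (SSE_reduced − SSE_full) / SST.
    """
    snp_id = snp_id or str(dosage.name)
    frame = pd.DataFrame({"y": phenotype, "g": dosage})
    if covariates is not None and len(covariates.columns):
        frame = frame.join(covariates.astype(float), how="inner")
    frame = frame.dropna()
    n = len(frame)
    if n < 10:
        raise AssociationError(f"{snp_id}: only {n} complete cases")
    g = frame["g"].to_numpy()
    if np.unique(g).size < 2:
        raise AssociationError(f"{snp_id}: monomorphic in complete cases")
    y = frame["y"].to_numpy()
    cov_cols = [c for c in frame.columns if c not in ("y", "g")]
    covs = frame[cov_cols].to_numpy() if cov_cols else np.empty((n, 0))

    X_full = np.column_stack([np.ones(n), g, covs])
    fit = _ols(y, X_full)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise AssociationError(f"{snp_id}: singular design matrix")
    X_red = np.column_stack([np.ones(n), covs])
    fit_red = _ols(y, X_red)
    sst = float(((y - y.mean()) ** 2).sum())
    partial_r2 = float((fit_red.ssr - fit.ssr) / sst) if sst > 0 else 0.0

    ci = fit.conf_int(alpha=0.05)
    assoc = SnpAssociation(
        snp_id=snp_id,
        phenotype=phenotype_name,
        transform=transform,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        partial_r2=partial_r2,
        n_used=n,
        covariates=tuple(cov_cols),
    )
    if ls_means:
        assoc.ls_means, assoc.pairwise_p = _ls_means(y, g, covs, transform)
    return assoc


def _ls_means(
    y: np.ndarray, g: np.ndarray, covs: np.ndarray, transform: str
) -> tuple[pd.DataFrame, dict]:
    """Adjusted genotype-class means from a categorical parallel fit.

    Classes are the observed dosage values; LS means evaluate the fit at the
    covariate means.  Pairwise class comparisons use the Tukey–Kramer
    studentized-range adjustment within this one model.
    """
    classes = np.unique(g)
    k = classes.size
    indicators = np.column_stack([(g == c).astype(float) for c in classes[1:]])
    X = np.column_stack([np.ones_like(y), indicators, covs])
    fit = _ols(y, X)
    params = fit.params
    cov_params = fit.cov_params()
    cov_means = covs.mean(axis=0) if covs.size else np.empty(0)

    rows = []
    vectors = {}
    for idx, c in enumerate(classes):
        x = np.zeros(X.shape[1])
        x[0] = 1.0
        if idx > 0:
            x[idx] = 1.0
        x[k:] = cov_means
        vectors[c] = x
        mean = float(x @ params)
        se = float(np.sqrt(x @ cov_params @ x))
        bt_mean, bt_se = back_transform(mean, se, transform)
        rows.append(
            {
                "dosage": float(c),
                "n": int((g == c).sum()),
                "ls_mean": mean,
                "se": se,
                "ls_mean_bt": bt_mean,
                "se_bt": bt_se,
            }
        )
    table = pd.DataFrame(rows).set_index("dosage")

    pairwise = {}
    df_resid = fit.df_resid
    for i in range(k):
        for j in range(i + 1, k):
            c = vectors[classes[i]] - vectors[classes[j]]
            diff = float(c @ params)
            se_diff = float(np.sqrt(c @ cov_params @ c))
            if se_diff == 0:
                pairwise[(float(classes[i]), float(classes[j]))] = 1.0
                continue
            q = abs(diff) / (se_diff / np.sqrt(2))
            p = float(stats.studentized_range.sf(q, k, df_resid))
            pairwise[(float(classes[i]), float(classes[j]))] = min(max(p, 0.0), 1.0)
    return table, pairwise


def determine_risk_allele(assoc: SnpAssociation, record) -> tuple[str, bool]:
    """Phenotype-specific risk allele for a fitted SNP.

    For TG the risk allele tracks the higher adjusted mean (β > 0 under
    additive coding means the counted allele is the risk allele); for HDL-C
    the direction reverses — the risk allele is the one lowering HDL-C.
    A β of exactly zero is ambiguous: the minor allele is returned, flagged.
    """
    direction = ADVERSE_DIRECTION[assoc.phenotype]
    if assoc.beta == 0.0:
        minor = record.counted_allele
        if record.maf_cohort is not None and record.maf_cohort > 0.5:
            minor = record.other_allele
        return minor, True
    counted_is_risk = (assoc.beta > 0) == (direction > 0)
    return (record.counted_allele if counted_is_risk else record.other_allele), False


def associate_panel(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    panel: SnpPanel,
    phenotype_name: str,
    covariates: pd.DataFrame | None = None,
    snp_ids: list[str] | None = None,
    transform: str | None = None,
    ls_means: bool = True,
) -> dict[str, SnpAssociation]:
    """Fit every requested SNP and attach its phenotype-specific risk allele."""
    values, used_transform = prepare_phenotype(phenotype, force=transform)
    out = {}
    for snp in snp_ids if snp_ids is not None else genotypes.snp_ids:
        assoc = fit_snp_model(
            values,
            genotypes.dosages(snp),
            covariates=covariates,
            phenotype_name=phenotype_name,
            transform=used_transform,
            snp_id=snp,
            ls_means=ls_means,
        )
        assoc.risk_allele, assoc.risk_ambiguous = determine_risk_allele(assoc, panel.get(snp))
        out[snp] = assoc
    return out


def association_table(associations: dict[str, SnpAssociation]) -> pd.DataFrame:
    """Flatten per-SNP associations to one row per SNP."""
    rows = []
    for snp, a in associations.items():
        rows.append(
            {
                "snp_id": snp,
                "phenotype": a.phenotype,
                "transform": a.transform,
                "beta": a.beta,
                "se": a.se,
                "p_value": a.p_value,
                "ci_low": a.ci_low,
                "ci_high": a.ci_high,
                "partial_r2": a.partial_r2,
                "risk_allele": a.risk_allele,
                "risk_ambiguous": a.risk_ambiguous,
                "n_used": a.n_used,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def scan_interactions(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    pairs: list[tuple[str, str]],
    covariates: pd.DataFrame | None = None,
    transform: str | None = None,
    collinear_r2: float = 0.99,
) -> pd.DataFrame:
    """Pairwise SNP×SNP interaction scan.

    Fits phenotype ~ g1 + g2 + g1·g2 + covariates per pair and reports the
    Wald p of the product term.  Pairs whose dosages are (near-)collinear
    are flagged and skipped.
    """
    values, _ = prepare_phenotype(phenotype, force=transform)
    rows = []
    for a, b in pairs:
        frame = pd.DataFrame(
            {"y": values, "g1": genotypes.dosages(a), "g2": genotypes.dosages(b)}
        )
        if covariates is not None and len(covariates.columns):
            frame = frame.join(covariates.astype(float), how="inner")
        frame = frame.dropna()
        n = len(frame)
        row = {"snp_a": a, "snp_b": b, "n": n, "p_interaction": np.nan, "flag": ""}
        if n < 10:
            row["flag"] = "insufficient_n"
            rows.append(row)
            continue
        g1, g2 = frame["g1"].to_numpy(), frame["g2"].to_numpy()
        if g1.std() == 0 or g2.std() == 0:
            row["flag"] = "monomorphic"
            rows.append(row)
            continue
        if np.corrcoef(g1, g2)[0, 1] ** 2 >= collinear_r2:
            row["flag"] = "collinear"
            rows.append(row)
            continue
        covs = frame[[c for c in frame.columns if c not in ("y", "g1", "g2")]].to_numpy()
        X = np.column_stack([np.ones(n), g1, g2, g1 * g2, covs])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            row["flag"] = "singular"
            rows.append(row)
            continue
        fit = _ols(frame["y"].to_numpy(), X)
        row["p_interaction"] = float(fit.pvalues[3])
        row["beta_interaction"] = float(fit.params[3])
        rows.append(row)
    return pd.DataFrame(rows)
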