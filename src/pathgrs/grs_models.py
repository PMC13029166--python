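"""GRS-phenotype association models and risk-group comparisons.

Each model is an OLS of the (transformed) phenotype on the score plus a
covariate set (age+sex; optionally BMI; optionally ancestry PCs).  The
report follows the field's variance-decomposition convention: overall model
F-test p and R², the score term's Wald p, its partial R² (Type-III SS over
corrected total SS, identical to the nested-model ΔR²), and β with a 95%
CI.  "Percent variability explained by the GRS" is 100×partial R² and is
suppressed (NC, not calculated) when the score term is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import back_transform, prepare_phenotype
from .grs import GrsVector

__all__ = [
    "GrsModelError",
    "GrsAssociation",
    "fit_grs_model",
    "grs_results_table",
    "RiskGroupComparison",
    "compare_risk_groups",
    "stratify_by_sex",
    "classify_tg_category",
    "TG_CATEGORIES",
]

TG_CATEGORIES = (
    "Optimal",
    "Early metabolic risk",
    "Borderline metabolic risk",
    "Clinical hypertriglyceridemia",
)


class GrsModelError(ValueError):
    pass


@dataclass
class GrsAssociation:
    phenotype: str
    scope: str
    weighting: str
    covariates: tuple[str, ...]
    transform: str
    model_p: float
    model_r2: float
    grs_p: float
    grs_partial_r2: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int

    @property
    def pct_model(self) -> float:
        return 100.0 * self.model_r2

    @property
    def pct_grs(self) -> float | None:
        """Percent variability explained by the score; None (NC) when the
        score term is not significant at 0.05."""
        return 100.0 * self.grs_partial_r2 if self.grs_p < 0.05 else None


def fit_grs_model(
    phenotype: pd.Series,
    vector: GrsVector,
    covariates: pd.DataFrame | None = None,
    transform: str | None = None,
    alpha: float = 0.05,
) -> GrsAssociation:
    """OLS of the (transformed) phenotype on a risk score plus covariates."""
    values, used_transform = prepare_phenotype(phenotype, force=transform)
    frame = pd.DataFrame({"y": values, "score": vector.scores})
    if covariates is not None and len(covariates.columns):
        frame = frame.join(covariates.astype(float), how="inner")
    frame = frame.dropna()
    n = len(frame)
    if n < 10:
        raise GrsModelError(f"only {n} complete cases")
    score = frame["score"].to_numpy()
    if np.unique(score).size < 2:
        raise GrsModelError("constant score")
    y = frame["y"].to_numpy()
    cov_cols = [c for c in frame.columns if c not in ("y", "score")]
    covs = frame[cov_cols].to_numpy() if cov_cols else np.empty((n, 0))

    X_full = np.column_stack([np.ones(n), score, covs])
    fit = sm.OLS(y, X_full).fit()
    X_red = np.column_stack([np.ones(n), covs])
    fit_red = sm.OLS(y, X_red).fit()
    sst = float(((y - y.mean()) ** 2).sum())
    partial_r2 = float((fit_red.ssr - fit.ssr) / sst) if sst > 0 else 0.0
    ci = fit.conf_int(alpha=alpha)
    return GrsAssociation(
        phenotype=vector.definition.phenotype,
        scope=vector.definition.scope,
        weighting=vector.definition.weighting,
        covariates=tuple(cov_cols),
        transform=used_transform,
        model_p=float(fit.f_pvalue),
        model_r2=float(fit.rsquared),
        grs_p=float(fit.pvalues[1]),
        grs_partial_r2=partial_r2,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n_used=n,
    )


def grs_results_table(results: list[GrsAssociation]) -> pd.DataFrame:
    """One row per (scope × phenotype × weighting × covariate set), in the
    layout of the study-style results table; NC marks suppressed percents."""
    rows = []
    for r in results:
        pct = r.pct_grs
        rows.append(
            {
                "scope": r.scope,
                "phenotype": r.phenotype,
                "weighting": r.weighting,
                "covariates": "+".join(r.covariates),
                "model_p": r.model_p,
                "pct_model": r.pct_model,
                "grs_p": r.grs_p,
                "pct_grs": "NC" if pct is None else round(pct, 2),
                "beta": r.beta,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": r.n_used,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RiskGroupComparison:
    phenotype: str
    transform: str
    mean_high: float
    se_high: float
    mean_low: float
    se_low: float
    n_high: int
    n_low: int
    t_stat: float
    t_p: float


def compare_risk_groups(
    phenotype: pd.Series,
    vector: GrsVector,
    phenotype_name: str = "TG",
    transform: str | None = None,
) -> RiskGroupComparison:
    """Two-sample t-test of phenotype between high and low genetic risk.

    The test runs on the analysis (possibly log) scale; reported group means
    ± SE are back-transformed for log phenotypes (geometric means).
    """
    if vector.risk_group is None:
        raise GrsModelError("risk groups not assigned; call assign_risk_groups first")
    values, used_transform = prepare_phenotype(phenotype, force=transform)
    frame = pd.DataFrame({"y": values, "group": vector.risk_group}).dropna()
    high = frame.loc[frame["group"] == "high", "y"].to_numpy()
    low = frame.loc[frame["group"] == "low", "y"].to_numpy()
    if len(high) < 2 or len(low) < 2:
        raise GrsModelError("each risk group needs at least 2 individuals")
    t_stat, t_p = stats.ttest_ind(high, low)
    mh, sh = back_transform(high.mean(), high.std(ddof=1) / np.sqrt(len(high)), used_transform)
    ml, sl = back_transform(low.mean(), low.std(ddof=1) / np.sqrt(len(low)), used_transform)
    return RiskGroupComparison(
        phenotype=phenotype_name,
        transform=used_transform,
        mean_high=mh,
        se_high=sh,
        mean_low=ml,
        se_low=sl,
        n_high=len(high),
        n_low=len(low),
        t_stat=float(t_stat),
        t_p=float(t_p),
    )


def stratify_by_sex(
    phenotype: pd.Series,
    vector: GrsVector,
    covariates: pd.DataFrame,
    sex_column: str = "sex",
    transform: str | None = None,
    min_n: int = 30,
) -> dict[str, GrsAssociation]:
    """Rerun the GRS model within each sex stratum, dropping sex as a
    covariate; strata below *min_n* are skipped with a warning entry."""
    import warnings

    if sex_column not in covariates.columns:
        raise GrsModelError(f"covariates lack a {sex_column!r} column")
    out: dict[str, GrsAssociation] = {}
    other = covariates.drop(columns=[sex_column])
    for label, value in (("male", 1), ("female", 0)):
        mask = covariates[sex_column] == value
        ids = covariates.index[mask]
        n = int(mask.sum())
        if n < min_n:
            warnings.warn(f"{label} stratum has n={n} < {min_n}; skipped", stacklevel=2)
            continue
        stratum_vector = GrsVector(
            scores=vector.scores.loc[vector.scores.index.intersection(ids)],
            definition=vector.definition,
            n_missing_members=vector.n_missing_members.loc[
                vector.n_missing_members.index.intersection(ids)
            ],
        )
        out[label] = fit_grs_model(
            phenotype.loc[phenotype.index.intersection(ids)],
            stratum_vector,
            covariates=other.loc[ids] if len(other.columns) else None,
            transform=transform,
        )
    return out


def classify_tg_category(tg: float) -> str:
    """Guideline TG category: <90 Optimal; 90–<130 Early metabolic risk;
    130–<150 Borderline metabolic risk; ≥150 Clinical hypertriglyceridemia."""
    if not np.isfinite(tg) or tg <= 0:
        raise GrsModelError(f"TG must be positive, got {tg}")
    if tg < 90:
        return TG_CATEGORIES[0]
    if tg < 130:
        return TG_CATEGORIES[1]
    if tg < 150:
        return TG_CATEGORIES[2]
    return TG_CATEGORIES[3]
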