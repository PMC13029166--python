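"""Genetic risk score construction.

A score is defined by its member SNPs, each carrying a phenotype-specific
risk allele and a weight.  Additive scores count risk alleles (weights all
1; an m-member score lies in [0, 2m]); weighted scores multiply each risk-
allele count by the SNP's per-allele effect estimated in-sample, expressed
per risk-allele copy — positive toward higher TG, negative toward lower
HDL-C, so raw weighted HDL scores are typically negative sums.

Scopes: one per pathway (RCT, CLU, LPF), their union (TOTAL), and a
"top hits" score restricted to SNPs individually associated with the
phenotype below a p threshold.  High/low genetic risk is a median split:
high = score strictly above the sample median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .association import SnpAssociation
from .genotypes import GenotypeMatrix
from .panel import PATHWAYS, SnpPanel

__all__ = [
    "GrsError",
    "GrsMember",
    "GrsDefinition",
    "GrsVector",
    "orient_dosages",
    "build_additive_grs",
    "build_weighted_grs",
    "assign_risk_groups",
    "compute_grs",
    "build_pathway_definition",
    "build_all_definitions",
    "build_top_hits_definition",
    "remove_key_snp",
]

SCOPES = ("RCT", "CLU", "LPF", "TOTAL", "TOP_HITS")


class GrsError(ValueError):
    pass


@dataclass(frozen=True)
class GrsMember:
    snp_id: str
    risk_allele: str
    weight: float = 1.0


@dataclass(frozen=True)
class GrsDefinition:
    phenotype: str
    scope: str
    members: tuple[GrsMember, ...]
    weighting: str = "additive"  # additive | weighted

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise GrsError(f"unknown scope {self.scope!r}")
        if self.weighting not in ("additive", "weighted"):
            raise GrsError(f"unknown weighting {self.weighting!r}")
        ids = [m.snp_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise GrsError("duplicate member snp_ids")
        if self.weighting == "additive" and any(m.weight != 1.0 for m in self.members):
            raise GrsError("additive definitions require unit weights")

    @property
    def snp_ids(self) -> list[str]:
        return [m.snp_id for m in self.members]

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "scope": self.scope,
            "weighting": self.weighting,
            "members": [
                {"snp_id": m.snp_id, "risk_allele": m.risk_allele, "weight": m.weight}
                for m in self.members
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "GrsDefinition":
        return cls(
            phenotype=data["phenotype"],
            scope=data["scope"],
            weighting=data.get("weighting", "additive"),
            members=tuple(
                GrsMember(m["snp_id"], m["risk_allele"], float(m.get("weight", 1.0)))
                for m in data["members"]
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GrsDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GrsVector:
    scores: pd.Series
    definition: GrsDefinition
    n_missing_members: pd.Series
    risk_group: pd.Series | None = None
    median: float | None = None


def orient_dosages(genotypes: GenotypeMatrix, definition: GrsDefinition) -> pd.DataFrame:
    """Per-member risk-allele counts: dosage if the counted allele is the
    risk allele, else 2 − dosage; missing propagates."""
    if genotypes.panel is None:
        raise GrsError("genotype matrix has no attached panel")
    cols = {}
    for member in definition.members:
        if member.snp_id not in genotypes.codes.columns:
            raise GrsError(f"member SNP {member.snp_id!r} absent from genotype matrix")
        record = genotypes.panel.get(member.snp_id)
        if member.risk_allele not in (record.allele_a, record.allele_b):
            raise GrsError(
                f"{member.snp_id}: risk allele {member.risk_allele!r} is not one of "
                f"{record.allele_a!r}/{record.allele_b!r}"
            )
        dosage = genotypes.codes[member.snp_id]
        cols[member.snp_id] = dosage if member.risk_allele == record.counted_allele else 2.0 - dosage
    return pd.DataFrame(cols, index=genotypes.codes.index)


def _sum_scores(counts: pd.DataFrame, weights: pd.Series) -> tuple[pd.Series, pd.Series]:
    n_missing = counts.isna().sum(axis=1)
    complete = counts.dropna()
    scores = complete.mul(weights, axis=1).sum(axis=1)
    return scores, n_missing


def build_additive_grs(counts: pd.DataFrame, definition: GrsDefinition) -> GrsVector:
    """Sum of risk-allele counts; individuals missing any member excluded."""
    if definition.weighting != "additive":
        raise GrsError("definition is not additive")
    if not definition.members:
        raise GrsError("empty member list")
    weights = pd.Series(1.0, index=definition.snp_ids)
    scores, n_missing = _sum_scores(counts[definition.snp_ids], weights)
    return GrsVector(scores=scores, definition=definition, n_missing_members=n_missing)


def build_weighted_grs(counts: pd.DataFrame, definition: GrsDefinition) -> GrsVector:
    """β-weighted sum of risk-allele counts (weights live in the definition)."""
    if definition.weighting != "weighted":
        raise GrsError("definition is not weighted")
    if not definition.members:
        raise GrsError("empty member list")
    for m in definition.members:
        if m.weight is None or np.isnan(m.weight):
            raise GrsError(f"member {m.snp_id} has no weight")
    weights = pd.Series({m.snp_id: m.weight for m in definition.members})
    scores, n_missing = _sum_scores(counts[definition.snp_ids], weights)
    return GrsVector(scores=scores, definition=definition, n_missing_members=n_missing)


def assign_risk_groups(vector: GrsVector) -> GrsVector:
    """Median split on the analysed sample: high = score > median."""
    scores = vector.scores
    if scores.nunique() < 2:
        raise GrsError("degenerate score distribution: all scores identical")
    median = float(scores.median())
    vector.median = median
    vector.risk_group = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="risk_group"
    )
    return vector


def compute_grs(genotypes: GenotypeMatrix, definition: GrsDefinition) -> GrsVector:
    """Orient, sum, and median-split in one step."""
    counts = orient_dosages(genotypes, definition)
    builder = build_additive_grs if definition.weighting == "additive" else build_weighted_grs
    return assign_risk_groups(builder(counts, definition))


def _risk_weight(assoc: SnpAssociation, record, risk_allele: str) -> float:
    """Express the fitted per-counted-allele β per risk-allele copy."""
    return assoc.beta if risk_allele == record.counted_allele else -assoc.beta


def _members_from(
    panel: SnpPanel,
    snp_ids: list[str],
    phenotype: str,
    associations: dict[str, SnpAssociation] | None,
    weighting: str,
) -> tuple[GrsMember, ...]:
    members = []
    for snp in snp_ids:
        record = panel.get(snp)
        if associations is not None and snp in associations:
            assoc = associations[snp]
            risk = assoc.risk_allele or record.counted_allele
            weight = _risk_weight(assoc, record, risk) if weighting == "weighted" else 1.0
        else:
            if weighting == "weighted":
                raise GrsError(f"{snp}: weighted score requires a fitted association")
            risk, weight = record.counted_allele, 1.0
        members.append(GrsMember(snp_id=snp, risk_allele=risk, weight=weight))
    return tuple(members)


def build_pathway_definition(
    panel: SnpPanel,
    phenotype: str,
    scope: str,
    retained_snps: list[str] | None = None,
    associations: dict[str, SnpAssociation] | None = None,
    weighting: str = "additive",
) -> GrsDefinition:
    """Definition for one pathway or the TOTAL union.

    Starts from the panel's eligible members for *phenotype* (Hardy-Weinberg-
    flagged and other-phenotype-restricted variants excluded), intersects
    with *retained_snps* (the post-QC, post-LD-prune set) when given, and
    takes risk alleles and weights from *associations* when given.
    """
    if scope not in ("RCT", "CLU", "LPF", "TOTAL"):
        raise GrsError(f"scope {scope!r} is not a pathway scope")
    candidates = panel.score_candidates(phenotype)
    if scope != "TOTAL":
        candidates = [r for r in candidates if r.pathway == scope]
    ids = [r.snp_id for r in candidates]
    if retained_snps is not None:
        keep = set(retained_snps)
        ids = [s for s in ids if s in keep]
    return GrsDefinition(
        phenotype=phenotype,
        scope=scope,
        weighting=weighting,
        members=_members_from(panel, ids, phenotype, associations, weighting),
    )


def build_all_definitions(
    panel: SnpPanel,
    phenotype: str,
    retained_snps: list[str] | None = None,
    associations: dict[str, SnpAssociation] | None = None,
    weighting: str = "additive",
    top_hits_alpha: float = 0.10,
) -> dict[str, GrsDefinition]:
    """All five scopes for one phenotype and weighting scheme."""
    out = {
        scope: build_pathway_definition(
            panel, phenotype, scope, retained_snps, associations, weighting
        )
        for scope in PATHWAYS + ("TOTAL",)
    }
    if associations is not None:
        top = build_top_hits_definition(
            panel, associations, phenotype, alpha=top_hits_alpha, weighting=weighting,
            retained_snps=retained_snps,
        )
        if top.members:
            out["TOP_HITS"] = top
    return out


def build_top_hits_definition(
    panel: SnpPanel,
    associations: dict[str, SnpAssociation],
    phenotype: str,
    alpha: float = 0.10,
    weighting: str = "additive",
    retained_snps: list[str] | None = None,
) -> GrsDefinition:
    """Score restricted to SNPs individually associated at p < *alpha*.

    The default 0.10 is the "approaching significance" rule; pass 0.05 for
    the strict set (always a subset of the loose one).
    """
    eligible = {r.snp_id for r in panel.score_candidates(phenotype)}
    if retained_snps is not None:
        eligible &= set(retained_snps)
    ids = [
        s
        for s, a in associations.items()
        if s in eligible and a.p_value < alpha
    ]
    if not ids:
        warnings.warn(
            f"no SNP associated with {phenotype} at p < {alpha}; top-hits score is empty",
            stacklevel=2,
        )
    return GrsDefinition(
        phenotype=phenotype,
        scope="TOP_HITS",
        weighting=weighting,
        members=_members_from(panel, ids, phenotype, associations, weighting),
    )


def remove_key_snp(definition: GrsDefinition, snp_id: str) -> GrsDefinition:
    """Sensitivity analysis: the definition without one member."""
    if snp_id not in definition.snp_ids:
        raise GrsError(f"{snp_id!r} is not a member of this definition")
    return replace(
        definition, members=tuple(m for m in definition.members if m.snp_id != snp_id)
    )
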