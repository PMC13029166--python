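"""SNP panel: the annotated variant set with pathway membership and alleles.

The packaged panel describes 19 genotyped variants from three lipoprotein
metabolism pathways — reverse cholesterol transport (RCT), cellular lipid
uptake (CLU), and lipoprotein formation (LPF) — with the counted (risk)
allele, reference allele frequencies, and per-phenotype membership notes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

PATHWAYS = ("RCT", "CLU", "LPF")
PHENOTYPES = ("TG", "HDL")

HWE_FAIL_FLAG = "reported_hwe_fail"


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class SnpRecord:
    """One panel variant.

    ``counted_allele`` is the allele the 0/1/2 dosage counts; it must be one
    of ``allele_a``/``allele_b``.  ``phenotype_restriction`` limits the SNP to
    one phenotype's risk score (used for the ABCA1 pair, which is in strong
    D' but negligible r2, so each member serves one lipid trait).
    """

    snp_id: str
    gene: str
    chromosome: str
    pathway: str
    allele_a: str
    allele_b: str
    counted_allele: str
    maf_global: float | None = None
    maf_mxl: float | None = None
    maf_cohort: float | None = None
    phenotype_restriction: str | None = None
    aliases: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise PanelError(f"{self.snp_id}: unknown pathway {self.pathway!r}")
        if self.counted_allele not in (self.allele_a, self.allele_b):
            raise PanelError(
                f"{self.snp_id}: counted allele {self.counted_allele!r} is not "
                f"one of {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.phenotype_restriction is not None and self.phenotype_restriction not in PHENOTYPES:
            raise PanelError(
                f"{self.snp_id}: phenotype_restriction must be one of {PHENOTYPES}"
            )
        for name in ("maf_global", "maf_mxl", "maf_cohort"):
            value = getattr(self, name)
            if value is not None and not 0.0 < value < 1.0:
                raise PanelError(f"{self.snp_id}: {name}={value} outside (0, 1)")

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.counted_allele == self.allele_a else self.allele_a


@dataclass
class SnpPanel:
    """An ordered collection of :class:`SnpRecord` with unique ids."""

    records: list[SnpRecord]
    name: str = "panel"
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate snp_ids in panel: {dupes}")
        self._by_id = {r.snp_id: r for r in self.records}
        for record in self.records:
            for alias in record.aliases:
                self._by_id.setdefault(alias, record)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> SnpRecord:
        try:
            return self._by_id[snp_id]
        except KeyError:
            raise PanelError(f"SNP {snp_id!r} not on panel {self.name!r}") from None

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, snp_ids) -> "SnpPanel":
        return SnpPanel(
            [self.get(s) for s in snp_ids], name=self.name, pathway_names=self.pathway_names
        )

    def pathway_members(self, pathway: str) -> list[SnpRecord]:
        if pathway not in PATHWAYS:
            raise PanelError(f"unknown pathway {pathway!r}")
        return [r for r in self.records if r.pathway == pathway]

    def score_candidates(self, phenotype: str) -> list[SnpRecord]:
        """Panel members eligible for *phenotype*'s risk score.

        Excludes variants flagged as Hardy-Weinberg failures in the source
        genotyping report and variants restricted to the other phenotype.
        """
        if phenotype not in PHENOTYPES:
            raise PanelError(f"unknown phenotype {phenotype!r}")
        out = []
        for r in self.records:
            if HWE_FAIL_FLAG in r.flags:
                continue
            if r.phenotype_restriction is not None and r.phenotype_restriction != phenotype:
                continue
            out.append(r)
        return out

    def to_dict(self) -> dict:
        recs = []
        for r in self.records:
            d = {
                "snp_id": r.snp_id,
                "gene": r.gene,
                "chromosome": r.chromosome,
                "pathway": r.pathway,
                "allele_a": r.allele_a,
                "allele_b": r.allele_b,
                "counted_allele": r.counted_allele,
            }
            for opt in ("maf_global", "maf_mxl", "maf_cohort", "phenotype_restriction"):
                if getattr(r, opt) is not None:
                    d[opt] = getattr(r, opt)
            if r.aliases:
                d["aliases"] = list(r.aliases)
            if r.flags:
                d["flags"] = list(r.flags)
            recs.append(d)
        return {"panel_name": self.name, "pathways": self.pathway_names, "snps": recs}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _panel_from_dict(data: dict) -> SnpPanel:
    try:
        raw = data["snps"]
    except KeyError:
        raise PanelError("panel definition lacks a 'snps' list") from None
    records = []
    for entry in raw:
        entry = dict(entry)
        entry["aliases"] = tuple(entry.get("aliases", ()))
        entry["flags"] = tuple(entry.get("flags", ()))
        entry["chromosome"] = str(entry.get("chromosome", ""))
        records.append(SnpRecord(**entry))
    return SnpPanel(
        records,
        name=data.get("panel_name", "panel"),
        pathway_names=dict(data.get("pathways", {})),
    )


def read_panel(path: str | Path) -> SnpPanel:
    """Read a panel from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _panel_from_dict(data)


def load_default_panel() -> SnpPanel:
    """Load the packaged UP-AMIGOS lipid-metabolism SNP panel."""
    ref = resources.files("pathgrs.data").joinpath("panel_up_amigos.yaml")
    return _panel_from_dict(yaml.safe_load(ref.read_text()))
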