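"""Genotype container and file IO.

Genotypes are allele-count codes: 0/1/2 copies of each SNP's counted allele,
NaN for missing.  The canonical interchange format is a CSV with individuals
as rows (first column ``individual_id``) and SNP ids as columns; a minimal
biallelic VCF reader (GT field only) is provided with allele harmonisation
against the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = ["GenotypeMatrix", "GenotypeError", "read_genotype_csv", "read_genotype_vcf"]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs dosage codes with optional attached panel.

    ``codes`` is a float DataFrame indexed by individual id with SNP-id
    columns; entries are 0.0/1.0/2.0 or NaN.
    """

    codes: pd.DataFrame
    panel: SnpPanel | None = None
    admixture: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        values = self.codes.to_numpy(dtype=float, copy=False)
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = np.unique(observed[~np.isin(observed, (0.0, 1.0, 2.0))])
            raise GenotypeError(f"genotype codes outside {{0,1,2,NA}}: {bad.tolist()}")
        if self.codes.columns.duplicated().any():
            raise GenotypeError("duplicate SNP columns")
        if self.codes.index.duplicated().any():
            raise GenotypeError("duplicate individual ids")
        self.codes = self.codes.rename_axis("individual_id")
        if self.panel is not None:
            unknown = [s for s in self.codes.columns if s not in self.panel]
            if unknown:
                raise GenotypeError(f"SNPs absent from attached panel: {unknown}")

    @property
    def individual_ids(self) -> list:
        return list(self.codes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    def dosages(self, snp_id: str) -> pd.Series:
        if snp_id not in self.codes.columns:
            raise GenotypeError(f"SNP {snp_id!r} not in genotype matrix")
        return self.codes[snp_id]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        missing = [s for s in snp_ids if s not in self.codes.columns]
        if missing:
            raise GenotypeError(f"SNPs not in genotype matrix: {missing}")
        return GenotypeMatrix(self.codes[list(snp_ids)], panel=self.panel, admixture=self.admixture)

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n0, n1, n2) non-missing genotype class counts for one SNP."""
        g = self.dosages(snp_id).dropna().to_numpy()
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    def to_csv(self, path: str | Path) -> None:
        # integer look (0/1/2) with NA cells for missing
        self.codes.to_csv(path, na_rep="NA", float_format="%.0f")


def read_genotype_csv(path: str | Path, panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Read the canonical genotype CSV (rows=individuals, values 0/1/2/NA)."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    try:
        codes = df.astype(float)
    except ValueError as exc:
        raise GenotypeError(f"malformed genotype CSV {path}: {exc}") from exc
    return GenotypeMatrix(codes, panel=panel)


def read_genotype_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read biallelic records from a VCF, harmonising alleles against *panel*.

    Only the GT field is used.  For each panel SNP found in the file the
    returned dosage counts copies of the panel's counted allele: if REF/ALT
    are swapped relative to the panel the ALT count is complemented (2 - alt)
    with a logged notice; records whose alleles do not match the panel at all
    raise an error listing the offending SNPs.
    """
    from cyvcf2 import VCF

    rows: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []
    mismatches: list[str] = []
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    for variant in vcf:
        snp_id = variant.ID
        if snp_id is None or snp_id not in panel:
            continue
        if len(variant.ALT) != 1:
            raise GenotypeError(f"{snp_id}: only biallelic records are supported")
        record = panel.get(snp_id)
        ref, alt = variant.REF, variant.ALT[0]
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        lut = np.array([0.0, 1.0, np.nan, 2.0])
        alt_counts = lut[np.asarray(variant.gt_types, dtype=int)]
        if {ref, alt} != {record.allele_a, record.allele_b}:
            mismatches.append(f"{snp_id} ({ref}/{alt} vs panel {record.allele_a}/{record.allele_b})")
            continue
        if alt == record.counted_allele:
            dosage = alt_counts
        else:
            warnings.warn(
                f"{snp_id}: VCF REF/ALT swapped relative to panel counted allele; "
                "complementing dosage",
                stacklevel=2,
            )
            dosage = 2.0 - alt_counts
        rows[record.snp_id] = dosage
    if mismatches:
        raise GenotypeError("allele mismatch between VCF and panel: " + "; ".join(mismatches))
    if not rows:
        raise GenotypeError(f"no panel SNPs found in VCF {path}")
    codes = pd.DataFrame(rows, index=sample_ids)
    return GenotypeMatrix(codes, panel=panel)
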