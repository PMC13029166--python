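"""Per-SNP quality control and pairwise linkage disequilibrium.

QC covers minor-allele frequency, call rate, and a 1-df Pearson chi-square
test of Hardy-Weinberg proportions.  LD on unphased dosage data uses the
composite estimator for r² (squared Pearson correlation of 0/1/2 codes) and
an EM estimate of the four two-locus haplotype frequencies for D′ — the
double heterozygote is the only ambiguous cell and its cis/trans split is
re-estimated each iteration.  Tag-SNP pruning collapses connected components
of the high-LD graph to the member explaining the most phenotype variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "QcError",
    "compute_maf",
    "test_hwe",
    "qc_report",
    "apply_qc_filters",
    "LdEstimate",
    "estimate_ld",
    "ld_table",
    "prune_ld_groups",
]


class QcError(ValueError):
    pass


def compute_maf(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP counted-allele frequency and folded MAF.

    Computed from non-missing codes only: p̂ = (2·n2 + n1) / (2·n_nonmissing)
    for the counted allele, MAF = min(p̂, 1−p̂).  All-missing SNPs are
    excluded from the table and listed in the ``excluded`` attribute.
    """
    rows, excluded = {}, []
    for snp in genotypes.snp_ids:
        n0, n1, n2 = genotypes.genotype_counts(snp)
        n = n0 + n1 + n2
        if n == 0:
            excluded.append(snp)
            continue
        p = (2 * n2 + n1) / (2 * n)
        rows[snp] = {
            "counted_freq": p,
            "maf": min(p, 1 - p),
            "n_nonmissing": n,
            "monomorphic": n1 == 0 and (n0 == 0 or n2 == 0),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "snp_id"
    table.attrs["excluded"] = excluded
    return table


def test_hwe(n0: int, n1: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg genotype proportions.

    Expected counts use the sample allele frequency; 1 degree of freedom,
    no continuity correction.  Returns ``(chi2, p)``.  Monomorphic samples
    are not testable.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise QcError("no genotypes to test")
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        raise QcError("monomorphic SNP: HWE not testable")
    q = 1 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_report(
    genotypes: GenotypeMatrix,
    hwe_alpha: float = 0.05,
    min_call_rate: float = 0.9,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Per-SNP QC table: maf, call_rate, hwe_chi2, hwe_p, pass, reasons."""
    freq = compute_maf(genotypes)
    rows = {}
    for snp in genotypes.snp_ids:
        n0, n1, n2 = genotypes.genotype_counts(snp)
        n = n0 + n1 + n2
        call_rate = n / genotypes.n_individuals
        reasons = []
        if snp in freq.attrs["excluded"]:
            rows[snp] = {
                "maf": np.nan,
                "call_rate": 0.0,
                "hwe_chi2": np.nan,
                "hwe_p": np.nan,
                "pass": False,
                "reasons": "all_missing",
            }
            continue
        maf = freq.loc[snp, "maf"]
        if freq.loc[snp, "monomorphic"]:
            hwe_chi2 = hwe_p = np.nan
            reasons.append("monomorphic")
        else:
            hwe_chi2, hwe_p = test_hwe(n0, n1, n2)
            if hwe_p < hwe_alpha:
                reasons.append("hwe_fail")
        if call_rate < min_call_rate:
            reasons.append("low_call_rate")
        if maf < min_maf:
            reasons.append("low_maf")
        rows[snp] = {
            "maf": maf,
            "call_rate": call_rate,
            "hwe_chi2": hwe_chi2,
            "hwe_p": hwe_p,
            "pass": not reasons,
            "reasons": ";".join(reasons),
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "snp_id"
    return report


def apply_qc_filters(report: pd.DataFrame) -> list[str]:
    """Retained SNP ids from a :func:`qc_report` table."""
    retained = list(report.index[report["pass"]])
    if not retained:
        raise QcError("QC removed every SNP; nothing to analyse")
    return retained


@dataclass(frozen=True)
class LdEstimate:
    snp_a: str
    snp_b: str
    d: float
    d_prime: float
    r2: float
    hap_freqs: tuple[float, float, float, float]  # AB, Ab, aB, ab (1 = counted)
    em_converged: bool
    em_iterations: int
    n: int


def _em_haplotypes(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, bool, int]:
    """EM haplotype frequencies (pAB, pAb, paB, pab) from the 3×3 genotype
    count table; counts[i, j] is the number of individuals with dosage i at
    the first SNP and j at the second."""
    n = counts.sum()
    pa = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    p = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        f_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
        n_dh = counts[1, 1]
        nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + n_dh * f_cis
        nAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0] + n_dh * (1 - f_cis)
        naB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2] + n_dh * (1 - f_cis)
        nab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0] + n_dh * f_cis
        new = np.array([nAB, nAb, naB, nab]) / (2 * n)
        if np.abs(new - p).max() < tol:
            p = new
            converged = True
            break
        p = new
    return p, converged, it


def estimate_ld(
    genotypes: GenotypeMatrix,
    snp_a: str,
    snp_b: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
    min_n: int = 20,
) -> LdEstimate:
    """Pairwise LD from unphased dosages.

    r² is the composite estimate — the squared Pearson correlation of the
    two dosage vectors.  D′ is |D|/D_max from EM-estimated two-locus
    haplotype frequencies; non-convergence is reported, not raised.
    """
    pair = pd.concat([genotypes.dosages(snp_a), genotypes.dosages(snp_b)], axis=1).dropna()
    n = len(pair)
    if n < min_n:
        raise QcError(f"{snp_a}/{snp_b}: only {n} complete pairs (need >= {min_n})")
    a = pair.iloc[:, 0].to_numpy()
    b = pair.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise QcError(f"{snp_a}/{snp_b}: monomorphic SNP in pair")
    counts = np.zeros((3, 3), dtype=int)
    for i in range(3):
        for j in range(3):
            counts[i, j] = int(((a == i) & (b == j)).sum())
    p, converged, iterations = _em_haplotypes(counts, tol=tol, max_iter=max_iter)
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    d = p[0] - pA * pB
    if d >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r = np.corrcoef(a, b)[0, 1]
    return LdEstimate(
        snp_a=snp_a,
        snp_b=snp_b,
        d=float(d),
        d_prime=float(min(d_prime, 1.0)),
        r2=float(r * r),
        hap_freqs=tuple(float(x) for x in p),
        em_converged=converged,
        em_iterations=iterations,
        n=n,
    )


def ld_table(
    genotypes: GenotypeMatrix,
    snp_ids: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """LD estimates for explicit pairs, or all pairs among *snp_ids*."""
    if pairs is None:
        snps = snp_ids if snp_ids is not None else genotypes.snp_ids
        pairs = [(snps[i], snps[j]) for i in range(len(snps)) for j in range(i + 1, len(snps))]
    rows = []
    for a, b in pairs:
        est = estimate_ld(genotypes, a, b, **kwargs)
        rows.append(
            {
                "snp_a": a,
                "snp_b": b,
                "d_prime": est.d_prime,
                "r2": est.r2,
                "em_converged": est.em_converged,
                "em_iterations": est.em_iterations,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def prune_ld_groups(
    ld: pd.DataFrame,
    variance_explained: dict[str, float],
    maf: dict[str, float] | None = None,
    d_prime_threshold: float = 0.8,
    r2_threshold: float = 0.1,
    snp_ids: list[str] | None = None,
) -> dict:
    """Collapse high-LD groups to one tag SNP each.

    A pair is "high LD" when D′ ≥ ``d_prime_threshold`` and r² ≥
    ``r2_threshold`` (the r² floor keeps pairs in strong D′ but negligible
    allelic correlation — e.g. a rare variant on a common haplotype — from
    being collapsed).  Within each connected component the tag is the member
    with the greatest phenotype variance explained; ties break to the larger
    MAF, then to the lexicographically smaller snp_id.

    ``snp_ids`` optionally names the full SNP universe (SNPs absent from the
    LD table are retained untouched); by default only SNPs appearing in the
    table are considered.  Returns {"retained": [...], "dropped": {snp: tag},
    "groups": [[...]]}.
    """
    snps = sorted(set(ld["snp_a"]) | set(ld["snp_b"]) | set(snp_ids or ()))
    parent = {s: s for s in snps}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for _, row in ld.iterrows():
        if row["d_prime"] >= d_prime_threshold and row["r2"] >= r2_threshold:
            ra, rb = find(row["snp_a"]), find(row["snp_b"])
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, list[str]] = {}
    for s in snps:
        groups.setdefault(find(s), []).append(s)

    maf = maf or {}
    retained, dropped, group_list = [], {}, []
    for members in groups.values():
        if len(members) == 1:
            retained.append(members[0])
            continue
        group_list.append(sorted(members))
        missing = [m for m in members if m not in variance_explained]
        if missing:
            raise QcError(f"no variance-explained value for LD-group members: {missing}")
        tag = sorted(
            members,
            key=lambda s: (-variance_explained[s], -maf.get(s, 0.0), s),
        )[0]
        retained.append(tag)
        for m in members:
            if m != tag:
                dropped[m] = tag
    return {"retained": sorted(retained), "dropped": dropped, "groups": group_list}
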