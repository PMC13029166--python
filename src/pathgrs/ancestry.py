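"""Ancestry principal components from AIMs genotypes.

Ancestry-informative markers (AIMs) have large allele-frequency differences
between ancestral populations; the leading principal components of their
standardized dosage matrix track individual admixture proportions and serve
as covariates against population-stratification confounding.

Dosages are centred by twice the sample allele frequency and scaled by the
binomial SD sqrt(2p(1-p)) before decomposition; missing genotypes are
mean-imputed (zero after centring).  The sign of each component is fixed by
making its largest-magnitude AIM loading positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["AncestryError", "AncestryScores", "compute_pcs"]


class AncestryError(ValueError):
    pass


@dataclass
class AncestryScores:
    scores: pd.DataFrame  # individuals × PC1..PCk
    variance_explained: np.ndarray  # per-PC fraction of total variance
    loadings: pd.DataFrame  # AIMs × PCs

    def as_covariates(self) -> pd.DataFrame:
        return self.scores


def compute_pcs(aims: GenotypeMatrix, n_components: int = 2) -> AncestryScores:
    """Leading principal components of the standardized AIMs matrix.

    Monomorphic AIMs are dropped with a warning (they carry no ancestry
    signal and have zero scale); at least two polymorphic AIMs are required.
    """
    codes = aims.codes.to_numpy(dtype=float)
    n, m = codes.shape
    if m < 2:
        raise AncestryError("need at least 2 AIMs")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN AIM columns
        p_hat = np.nanmean(codes, axis=0) / 2.0  # per-AIM counted-allele frequency
    polymorphic = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    if not polymorphic.all():
        dropped = [c for c, keep in zip(aims.codes.columns, polymorphic) if not keep]
        warnings.warn(f"dropping {len(dropped)} monomorphic AIMs: {dropped[:5]}...", stacklevel=2)
    if polymorphic.sum() < 2:
        raise AncestryError("fewer than 2 polymorphic AIMs after filtering")
    codes = codes[:, polymorphic]
    cols = [c for c, keep in zip(aims.codes.columns, polymorphic) if keep]
    p_hat = p_hat[polymorphic]

    centred = codes - 2.0 * p_hat
    centred = np.where(np.isnan(centred), 0.0, centred)  # mean imputation
    standardized = centred / np.sqrt(2.0 * p_hat * (1.0 - p_hat))

    n_components = min(n_components, min(standardized.shape))
    u, s, vt = np.linalg.svd(standardized, full_matrices=False)
    eigvals = s**2
    var_frac = eigvals / eigvals.sum()

    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    # sign convention: largest-|loading| AIM positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    pc_names = [f"PC{k + 1}" for k in range(n_components)]
    return AncestryScores(
        scores=pd.DataFrame(scores, index=aims.codes.index, columns=pc_names),
        variance_explained=var_frac[:n_components],
        loadings=pd.DataFrame(loadings, index=cols, columns=pc_names),
    )
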