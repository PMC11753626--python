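"""Within-population diversity statistics and the modified Rogers distance.

Works on populations x loci B-allele frequency matrices. Missing cells
are imputed by the observed mean frequency of their locus before any
distance computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = ["impute_missing", "diversity_stats", "mrd_matrix"]


def impute_missing(freqs: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell by the mean observed frequency of its locus.

    Observed cells are untouched and locus means are preserved. A locus
    with no observed value at all is filled with the maximum-entropy
    neutral value 0.5 and logged.
    """
    arr = freqs.to_numpy(dtype=float, copy=True)
    observed = ~np.isnan(arr)
    counts = observed.sum(axis=0)
    col_means = np.where(counts > 0, np.nansum(arr, axis=0) / np.maximum(counts, 1), np.nan)
    all_missing = counts == 0
    if all_missing.any():
        logger.warning(
            "%d loci have no observed values; filled with 0.5: %s",
            int(all_missing.sum()),
            list(freqs.columns[all_missing][:10]),
        )
        col_means[all_missing] = 0.5
    nan_mask = np.isnan(arr)
    arr[nan_mask] = np.broadcast_to(col_means, arr.shape)[nan_mask]
    return pd.DataFrame(arr, index=freqs.index, columns=freqs.columns)


def diversity_stats(
    freqs: pd.DataFrame, mono_tol: float = 0.0, ignore_missing: bool = False
) -> pd.DataFrame:
    """Per-population expected heterozygosity Hs and monomorphic-locus count.

    ``Hs`` is the mean over loci of ``2 p (1 - p)`` (in [0, 0.5] for
    biallelic loci); ``NbMono`` counts loci with ``p <= mono_tol`` or
    ``p >= 1 - mono_tol``. The default ``mono_tol = 0`` counts exact
    fixation only, matching the upstream monomorphism snapping to 0/1.
    With ``ignore_missing`` missing cells are dropped per population
    instead of requiring a complete (imputed) matrix.
    """
    if freqs.shape[1] == 0:
        raise ValueError("diversity_stats needs at least one locus")
    if not 0 <= mono_tol < 0.5:
        raise ValueError("mono_tol must lie in [0, 0.5)")
    arr = freqs.to_numpy(dtype=float)
    if np.isnan(arr).any() and not ignore_missing:
        raise ValueError("matrix has missing values; impute first or set ignore_missing")
    het = 2.0 * arr * (1.0 - arr)
    mono = (arr <= mono_tol) | (arr >= 1.0 - mono_tol)
    if ignore_missing:
        hs = np.nanmean(het, axis=1)
        nbmono = np.nansum(np.where(np.isnan(arr), 0, mono), axis=1).astype(int)
    else:
        hs = het.mean(axis=1)
        nbmono = mono.sum(axis=1).astype(int)
    return pd.DataFrame({"Hs": hs, "NbMono": nbmono}, index=freqs.index)


def mrd_matrix(freqs: pd.DataFrame) -> pd.DataFrame:
    """Modified Rogers distance matrix between populations.

    For biallelic loci with B-allele frequencies ``p``,

        d(x, y) = sqrt( (1 / (2L)) * sum_l sum_{a in {A,B}} (p_xla - p_yla)^2 )
                = sqrt( (1 / L)   * sum_l (p_xl - p_yl)^2 ),

    the Euclidean distance on frequency vectors scaled so that
    ``0 <= d <= 1`` with 1 attained only when every locus is oppositely
    fixed. Symmetric with a zero diagonal; requires a complete matrix.
    """
    arr = freqs.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values present; run impute_missing first")
    L = arr.shape[1]
    if L < 1:
        raise ValueError("mrd_matrix needs at least one locus")
    d = squareform(pdist(arr, metric="euclidean") / np.sqrt(L))
    return pd.DataFrame(d, index=freqs.index, columns=freqs.index)
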