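"""Delimited-text readers and writers for the pipeline's tables.

One dialect throughout: tab-separated, populations in rows, loci in
columns, a header row of locus IDs, the first column holding population
IDs, missing values encoded as ``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA = "NA"
_SEP = "\t"

REFERENCE_COLUMNS = ["mean_A", "sd_A", "mean_B", "sd_B"]


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "population") -> None:
    """Write a populations x loci matrix (frequencies or FIR) as TSV."""
    df.to_csv(path, sep=_SEP, na_rep=_NA, index_label=index_label, float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a populations x loci matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep=_SEP, index_col=0, na_values=[_NA], keep_default_na=False)
    return df.astype(float)


def write_distance_matrix(d: pd.DataFrame, path: str | Path) -> None:
    """Square distance matrix with population IDs as header and first column."""
    d.to_csv(path, sep=_SEP, index_label="population", float_format="%.10g")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    d = pd.read_csv(path, sep=_SEP, index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    return d.astype(float)


def write_phylip_distance(d: pd.DataFrame, path: str | Path) -> None:
    """PHYLIP square-matrix format, for interoperability with tree tools.

    Labels are written in relaxed PHYLIP style (whitespace-delimited,
    not padded to 10 characters).
    """
    with open(path, "w") as fh:
        fh.write(f"{len(d)}\n")
        for pop, row in d.iterrows():
            vals = " ".join(f"{v:.10g}" for v in row.to_numpy())
            fh.write(f"{pop} {vals}\n")


def write_inbred_reference(ref: pd.DataFrame, path: str | Path) -> None:
    """Five-column table: locus, mean_A, sd_A, mean_B, sd_B."""
    ref[REFERENCE_COLUMNS].to_csv(path, sep=_SEP, index_label="locus", float_format="%.10g")


def read_inbred_reference(path: str | Path) -> pd.DataFrame:
    """Read an inbred homozygote FIR reference table.

    Enforces the orientation convention mean_A < mean_B (the B allele is
    the allele with the higher FIR); rows violating it are flipped with a
    logged warning.
    """
    ref = pd.read_csv(path, sep=_SEP, index_col=0).astype(float)
    missing = [c for c in REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise ValueError(f"inbred reference table lacks columns {missing}")
    flipped = ref["mean_A"] >= ref["mean_B"]
    if flipped.any():
        logger.warning(
            "flipping A/B orientation for %d loci with mean_A >= mean_B", int(flipped.sum())
        )
        a_cols, b_cols = ["mean_A", "sd_A"], ["mean_B", "sd_B"]
        orig = ref.loc[flipped, a_cols + b_cols].to_numpy()
        ref.loc[flipped, b_cols + a_cols] = orig
    return ref


def write_pool_set(pool_set, path: str | Path) -> None:
    """Controlled-pool FIR table; each row ID is the pool's known frequency."""
    fir = pool_set.fir.copy()
    fir.index = [f"{f:.10g}" for f in pool_set.known_freqs.iloc[:, 0]]
    fir.to_csv(path, sep=_SEP, na_rep=_NA, index_label="known_freq", float_format="%.10g")


def read_pool_set(path: str | Path):
    """Load a controlled-pool set written by :func:`write_pool_set`."""
    from .synthetic import ControlledPoolSet

    fir = pd.read_csv(path, sep=_SEP, index_col=0, na_values=[_NA], keep_default_na=False)
    fir = fir.astype(float)
    known = pd.DataFrame(
        np.repeat(fir.index.astype(float).to_numpy()[:, None], fir.shape[1], axis=1),
        index=fir.index,
        columns=fir.columns,
    )
    return ControlledPoolSet(known_freqs=known, fir=fir, n_snps=fir.shape[1])


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("group").to_csv(path, sep=_SEP, index_label="population")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep=_SEP, index_col=0)
    return df.iloc[:, 0].astype(str)


def write_proportions(props: pd.DataFrame, path: str | Path) -> None:
    """Ancestry coefficients written as percentages with one decimal."""
    (props * 100.0).to_csv(path, sep=_SEP, index_label="population", float_format="%.1f")


def read_proportions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_SEP, index_col=0).astype(float) / 100.0
    return df


def validate_frequency_matrix(df: pd.DataFrame, name: str = "frequency matrix") -> None:
    """Check the FrequencyMatrix invariants: values in [0,1] where present,
    unique population and locus IDs."""
    if df.index.has_duplicates:
        raise ValueError(f"{name}: duplicate population IDs")
    if df.columns.has_duplicates:
        raise ValueError(f"{name}: duplicate locus IDs")
    vals = df.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and (observed.min() < 0 or observed.max() > 1):
        raise ValueError(f"{name}: values outside [0, 1]")
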