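"""Supervised ancestry-proportion assignment to reference genetic groups.

Each query population's B-allele frequency vector ``f`` is expressed as
a mixture of the K group mean frequency vectors (rows of ``G``) by
solving the convex quadratic program

    min_a  || f - G^T a ||^2  +  ridge_lambda * || a ||^2
    s.t.   sum_k a_k = 1,   a_k >= 0,

independently per population. The coefficients are read as percentages
of belonging to each ancestral group. Non-negativity can be dropped
(``nonneg=False``) to mimic a sum-to-one-only penalized regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentConfig",
    "group_mean_frequencies",
    "solve_proportions",
    "assign_panel",
]

_SIMPLEX_TOL = 1e-8


@dataclass
class AssignmentConfig:
    """Knobs of the assignment: optional ridge penalty (default off) and
    the coefficient fraction above which a landrace counts as "mainly
    assigned" to its top group."""

    ridge_lambda: float = 0.0
    main_assignment_threshold: float = 0.5
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")


def group_mean_frequencies(freqs: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Mean allele-frequency matrix of each genetic group.

    Unweighted mean of member-population frequencies, per group and
    locus. Every reference population must carry a group label.
    """
    labels = pd.Series(labels)
    unlabeled = [p for p in freqs.index if p not in labels.index]
    if unlabeled:
        raise ValueError(f"populations without a group label: {unlabeled[:10]}")
    groups = labels.loc[freqs.index]
    g = freqs.groupby(groups).mean()
    g.index.name = "group"
    # keep first-appearance order of groups rather than lexicographic
    order = groups.drop_duplicates().tolist()
    return g.loc[order]


def _solve_qp(Q: np.ndarray, c: np.ndarray) -> np.ndarray:
    """min 1/2 a'Qa - c'a on the probability simplex (SLSQP, exact gradients)."""
    K = Q.shape[0]
    a0 = np.full(K, 1.0 / K)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - c @ a,
        a0,
        jac=lambda a: Q @ a - c,
        method="SLSQP",
        bounds=[(0.0, None)] * K,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0, "jac": lambda a: np.ones(K)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    a = np.clip(res.x, 0.0, None)
    return a / a.sum()


def _solve_sum_to_one(Q: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Equality-constrained least squares (sum-to-one only) via KKT."""
    K = Q.shape[0]
    kkt = np.zeros((K + 1, K + 1))
    kkt[:K, :K] = Q
    kkt[:K, K] = 1.0
    kkt[K, :K] = 1.0
    rhs = np.append(c, 1.0)
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return sol[:K]


def solve_proportions(
    f: np.ndarray, G: pd.DataFrame | np.ndarray, cfg: AssignmentConfig | None = None
) -> np.ndarray:
    """Ancestry coefficients of one frequency vector against group means.

    Unique when the group rows are affinely independent or
    ``ridge_lambda > 0``; with duplicated group rows and no ridge the
    solver's deterministic iteration fixes a representative (logged).
    """
    cfg = cfg or AssignmentConfig()
    Gm = np.asarray(G, dtype=float)
    f = np.asarray(f, dtype=float)
    K, L = Gm.shape
    if f.shape != (L,):
        raise ValueError(f"frequency vector has length {f.shape}, expected {L}")
    if np.isnan(f).any():
        raise ValueError("frequency vector has missing values; impute first")
    if K > L:
        raise ValueError("need at least as many loci as groups (K <= L)")
    # reduced K-dimensional quadratic, scaled by 1/L for conditioning
    Q = (Gm @ Gm.T + cfg.ridge_lambda * np.eye(K)) / L
    c = Gm @ f / L
    if cfg.ridge_lambda == 0:
        dup = np.linalg.matrix_rank(Gm @ Gm.T) < K
        if dup:
            logger.warning("group mean rows are rank-deficient; solution may be non-unique")
    a = _solve_qp(Q, c) if cfg.nonneg else _solve_sum_to_one(Q, c)
    if cfg.nonneg:
        assert abs(a.sum() - 1.0) <= _SIMPLEX_TOL and (a >= 0).all()
    return a


def assign_panel(
    freqs: pd.DataFrame, G: pd.DataFrame, cfg: AssignmentConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ancestry proportions for every population of a frequency matrix.

    Returns the populations x groups coefficient matrix and a per-
    population summary (main group = largest coefficient, its
    percentage, and whether it exceeds the main-assignment threshold).
    Coefficient ties are broken by group order (logged).
    """
    cfg = cfg or AssignmentConfig()
    missing = [l for l in G.columns if l not in freqs.columns]
    if missing or freqs.shape[1] != G.shape[1]:
        raise ValueError(
            f"loci mismatch between query matrix and group means (e.g. {missing[:5]})"
        )
    fr = freqs[G.columns]
    rows = [solve_proportions(fr.loc[p].to_numpy(), G, cfg) for p in fr.index]
    props = pd.DataFrame(rows, index=fr.index, columns=G.index)

    arr = props.to_numpy()
    top = arr.argmax(axis=1)  # argmax takes the first maximum: group-order tie-break
    ties = (arr == arr[np.arange(len(arr)), top][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.warning("main-group ties for %s; broke by group order", list(props.index[ties]))
    summary = pd.DataFrame(
        {
            "main_group": props.columns.to_numpy()[top],
            "percent": arr[np.arange(len(arr)), top] * 100.0,
            "mainly_assigned": arr[np.arange(len(arr)), top] > cfg.main_assignment_threshold,
        },
        index=props.index,
    )
    return props, summary
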