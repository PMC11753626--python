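"""Synthetic bulk-genotyping study generator.

Emulates the design of a landrace diversity study genotyped on a SNP
array from pooled DNA: K ancestral genetic groups with distinct
allele-frequency profiles, reference populations drifted around their
group means (Balding–Nichols-style Beta drift), query landraces formed
as simplex mixtures of group means, DNA bulks of ``n`` diploid plants
sampled binomially per locus, two-channel fluorescent-intensity-ratio
(FIR) signals linked to the true B-allele frequency through a logistic
curve plus Gaussian noise, controlled calibration pools of known
frequency, and missing genotype calls injected completely at random.

All loci are independent (no linkage disequilibrium) and the FIR is the
entry point: raw two-channel X/Y intensities are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulatedLandrace",
    "ControlledPoolSet",
    "fir_link",
    "simulate_reference_panel",
    "simulate_admixed_landraces",
    "simulate_fir",
    "simulate_controlled_pools",
    "simulate_inbred_reference",
    "inject_missing",
]

#: Defaults mirroring the study conditions: 15-plant bulks, FIR noise of
#: 0.03 on the [0,1] ratio scale, 7 reference groups, 2% missing calls.
DEFAULT_N_INDIVIDUALS = 15
DEFAULT_NOISE_SD = 0.03
DEFAULT_BETA0 = -3.0
DEFAULT_BETA1 = 6.0
DEFAULT_K = 7
DEFAULT_DRIFT = 50.0
DEFAULT_MISSING_RATE = 0.02

_FREQ_EPS = 1e-9  # keeps Beta parameters strictly positive


@dataclass
class SimulatedLandrace:
    """One simulated landrace: its ground-truth admixture and frequencies.

    ``bulk_freqs`` are the frequencies realised in a finite bulk of
    ``n_individuals`` diploid plants, hence exact multiples of
    ``1/(2*n_individuals)``.
    """

    landrace_id: str
    true_proportions: np.ndarray
    true_freqs: np.ndarray
    bulk_freqs: np.ndarray
    n_individuals: int = DEFAULT_N_INDIVIDUALS

    def __post_init__(self) -> None:
        self.true_proportions = np.asarray(self.true_proportions, dtype=float)
        self.true_freqs = np.asarray(self.true_freqs, dtype=float)
        self.bulk_freqs = np.asarray(self.bulk_freqs, dtype=float)
        if abs(self.true_proportions.sum() - 1.0) > 1e-9 or (self.true_proportions < 0).any():
            raise ValueError(f"{self.landrace_id}: true_proportions not on the simplex")


@dataclass
class ControlledPoolSet:
    """Pools of known allele frequency used to calibrate the FIR link.

    ``known_freqs`` and ``fir`` are pools x loci frames sharing labels;
    the known frequencies carry no noise by construction.
    """

    known_freqs: pd.DataFrame
    fir: pd.DataFrame
    pool_ids: list[str] = field(default_factory=list)
    n_snps: int = 1000

    def __post_init__(self) -> None:
        if not self.pool_ids:
            self.pool_ids = list(self.known_freqs.index)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (known frequency, FIR) pairs, NaN-free."""
        f = self.known_freqs.to_numpy(dtype=float).ravel()
        x = self.fir.to_numpy(dtype=float).ravel()
        keep = ~(np.isnan(f) | np.isnan(x))
        return f[keep], x[keep]


def fir_link(freqs: np.ndarray, beta0: float = DEFAULT_BETA0, beta1: float = DEFAULT_BETA1) -> np.ndarray:
    """Noise-free logistic link from B-allele frequency to FIR.

    ``fir = expit(beta0 + beta1 * f)``: a monotone map into (0, 1) whose
    inverse is linear on the logit-FIR scale, which is what the
    calibration step fits.
    """
    return expit(beta0 + beta1 * np.asarray(freqs, dtype=float))


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")


def simulate_reference_panel(
    K: int = DEFAULT_K,
    L: int = 1000,
    n_populations_per_group: int = 5,
    drift: float = DEFAULT_DRIFT,
    seed: int = 0,
    beta_shape: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate K reference genetic groups and their member populations.

    Group mean frequencies are drawn i.i.d. from a symmetric
    ``Beta(beta_shape, beta_shape)`` per group and locus; each member
    population's frequency at a locus drifts around its group mean ``p``
    as ``Beta(p*c, (1-p)*c)`` with concentration ``c = drift``
    (Balding–Nichols form, ``c`` on a 1/Fst-like scale: larger drift
    means tighter groups).

    Returns
    -------
    (group_means, population_freqs, labels)
        ``group_means`` is K x L, ``population_freqs`` is
        (K * n_populations_per_group) x L, ``labels`` maps population
        IDs to group IDs.
    """
    if K < 1 or L < 1 or n_populations_per_group < 1:
        raise ValueError("K, L and n_populations_per_group must all be >= 1")
    _check_positive(drift=drift, beta_shape=beta_shape)
    rng = np.random.default_rng(seed)
    group_ids = [f"G{g + 1}" for g in range(K)]
    loci_ids = [f"snp{l + 1}" for l in range(L)]
    means = rng.beta(beta_shape, beta_shape, size=(K, L))
    means = np.clip(means, _FREQ_EPS, 1 - _FREQ_EPS)
    group_means = pd.DataFrame(means, index=group_ids, columns=loci_ids)

    pop_ids, rows, labels = [], [], []
    for g, gid in enumerate(group_ids):
        a = means[g] * drift
        b = (1 - means[g]) * drift
        for m in range(n_populations_per_group):
            pop_ids.append(f"{gid}_pop{m + 1}")
            labels.append(gid)
            rows.append(rng.beta(a, b))
    freqs = pd.DataFrame(np.clip(rows, 0.0, 1.0), index=pop_ids, columns=loci_ids)
    return group_means, freqs, pd.Series(labels, index=pop_ids, name="group")


def simulate_admixed_landraces(
    group_means: pd.DataFrame,
    proportions: np.ndarray,
    n_individuals: int = DEFAULT_N_INDIVIDUALS,
    seed: int = 0,
    ids: list[str] | None = None,
) -> list[SimulatedLandrace]:
    """Create landraces as mixtures of group mean frequencies plus bulk sampling.

    ``true_freqs = proportions @ group_means`` per landrace; the bulk
    frequency at each locus is ``X / (2n)`` with
    ``X ~ Binomial(2n, true_freq)`` drawn independently per locus —
    equal-mass pooling of ``n`` diploid plants, ignoring unequal DNA
    contribution between plants.
    """
    props = np.atleast_2d(np.asarray(proportions, dtype=float))
    K = group_means.shape[0]
    if props.shape[1] != K:
        raise ValueError(f"proportions have length {props.shape[1]}, expected K={K}")
    if (props < 0).any() or np.abs(props.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("each proportions vector must be non-negative and sum to 1")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if ids is None:
        ids = [f"LR{i + 1}" for i in range(props.shape[0])]
    rng = np.random.default_rng(seed)
    G = group_means.to_numpy(dtype=float)
    out = []
    for lid, a in zip(ids, props):
        true = a @ G
        draws = rng.binomial(2 * n_individuals, true)
        out.append(
            SimulatedLandrace(
                landrace_id=lid,
                true_proportions=a,
                true_freqs=true,
                bulk_freqs=draws / (2.0 * n_individuals),
                n_individuals=n_individuals,
            )
        )
    return out


def simulate_fir(
    freqs: pd.DataFrame | np.ndarray,
    beta0: float = DEFAULT_BETA0,
    beta1: float = DEFAULT_BETA1,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> pd.DataFrame | np.ndarray:
    """Generate FIR signals from true frequencies through the logistic link.

    Gaussian noise of standard deviation ``noise_sd`` is added on the
    FIR scale and the result clamped to [0, 1]. Missing frequencies
    propagate to missing FIR. Deterministic under a fixed seed.
    """
    if beta1 == 0:
        raise ValueError("beta1 must be nonzero (the FIR link would not be invertible)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    arr = np.asarray(freqs, dtype=float)
    clean = fir_link(arr, beta0, beta1)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    fir = np.clip(noisy, 0.0, 1.0)
    fir[np.isnan(arr)] = np.nan
    if isinstance(freqs, pd.DataFrame):
        return pd.DataFrame(fir, index=freqs.index, columns=freqs.columns)
    return fir


def simulate_controlled_pools(
    frequency_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
    n_snps: int = 1000,
    beta0: float = DEFAULT_BETA0,
    beta1: float = DEFAULT_BETA1,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ControlledPoolSet, ControlledPoolSet]:
    """Two controlled-pool sets (calibration, validation) of known frequency.

    Each set holds one pool per grid frequency and ``n_snps`` loci per
    pool; FIR is generated through :func:`simulate_fir`. The two sets
    use disjoint seeds (``seed`` and ``seed + 1``) so that validation is
    genuinely held out.
    """
    grid = np.asarray(frequency_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("frequency_grid must not be empty")
    if (grid < 0).any() or (grid > 1).any():
        raise ValueError("grid frequencies must lie in [0, 1]")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")

    def one(s: int, tag: str) -> ControlledPoolSet:
        pool_ids = [f"{tag}_pool{i + 1}" for i in range(grid.size)]
        loci = [f"ctl{j + 1}" for j in range(n_snps)]
        known = pd.DataFrame(
            np.repeat(grid[:, None], n_snps, axis=1), index=pool_ids, columns=loci
        )
        fir = simulate_fir(known, beta0, beta1, noise_sd, seed=s)
        return ControlledPoolSet(known_freqs=known, fir=fir, pool_ids=pool_ids, n_snps=n_snps)

    return one(seed, "cal"), one(seed + 1, "val")


def simulate_inbred_reference(
    loci_ids: list[str],
    beta0: float = DEFAULT_BETA0,
    beta1: float = DEFAULT_BETA1,
    cluster_sd: float = DEFAULT_NOISE_SD,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus FIR cluster summaries of homozygous inbred lines.

    Homozygote-A lines sit at the link value for frequency 0 and
    homozygote-B lines at the value for frequency 1; ``cluster_sd`` is
    the within-cluster FIR spread and ``jitter_sd`` an optional
    per-locus wobble of the cluster means.
    """
    rng = np.random.default_rng(seed)
    L = len(loci_ids)
    mean_a = np.full(L, float(fir_link(0.0, beta0, beta1)))
    mean_b = np.full(L, float(fir_link(1.0, beta0, beta1)))
    if jitter_sd > 0:
        mean_a = np.clip(mean_a + rng.normal(0, jitter_sd, L), 0, 1)
        mean_b = np.clip(mean_b + rng.normal(0, jitter_sd, L), 0, 1)
    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "sd_A": np.full(L, cluster_sd),
            "mean_B": mean_b,
            "sd_B": np.full(L, cluster_sd),
        },
        index=pd.Index(loci_ids, name="locus"),
    )


def inject_missing(
    df: pd.DataFrame, rate: float = DEFAULT_MISSING_RATE, seed: int = 0
) -> pd.DataFrame:
    """Blank cells completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(df.shape) < rate
    arr = df.to_numpy(dtype=float, copy=True)
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=df.index, columns=df.columns)
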