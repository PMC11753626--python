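"""Two-step B-allele frequency estimation in DNA bulks from FIR data.

Step 1 classifies each bulk x SNP cell as monomorphic or polymorphic by
comparing its fluorescent intensity ratio (FIR) against the homozygote
FIR clusters of inbred lines. Step 2 converts FIR to frequency through
one global ("unique") logistic calibration fitted on controlled pools of
known allele frequency.

The calibration model is the inverse of the logistic link relating
frequency to FIR: ``logit(fir) = beta0 + beta1 * f`` is fitted by
ordinary least squares on the pool pairs, and frequencies are estimated
as ``f_hat = clamp((logit(fir) - beta0) / beta1, 0, 1)``. Estimates near
fixation are conservative: a cell is only snapped to 0 or 1 when its FIR
falls inside the matching homozygote cluster AND its estimated frequency
is beyond the fixation threshold (default 5%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logit

from .synthetic import ControlledPoolSet

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "classify_polymorphism",
    "estimate_frequencies",
    "calibration_report",
    "MONO_A",
    "MONO_B",
    "POLYMORPHIC",
    "MISSING",
]

MONO_A = "mono_A"
MONO_B = "mono_B"
POLYMORPHIC = "polymorphic"
MISSING = "missing"

_EPS = 1e-6  # clamp before logit
DEFAULT_FIXATION_THRESHOLD = 0.05
DEFAULT_CLUSTER_Z = 3.0


@dataclass
class CalibrationModel:
    """Global logistic FIR-to-frequency calibration.

    ``beta0``/``beta1`` parameterize ``logit(fir) = beta0 + beta1 * f``;
    ``beta1 > 0`` after orientation (B is the high-FIR allele).
    ``fixation_threshold`` is the frequency below which (resp. above
    ``1 - threshold``) a cell may be declared monomorphic.
    """

    beta0: float
    beta1: float
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD
    calibration_mae: float | None = None
    validation_mae: float | None = None
    #: True when the raw FIR orientation was reversed during fitting
    #: (A was the high-FIR allele); predict() then works on 1 - FIR.
    flip: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fixation_threshold < 0.5:
            raise ValueError("fixation_threshold must lie in (0, 0.5)")
        if self.beta1 <= 0:
            raise ValueError("beta1 must be positive after orientation")

    def predict(self, fir: np.ndarray | pd.DataFrame | float) -> np.ndarray | pd.DataFrame | float:
        """Estimated B-allele frequency for FIR values; NaN propagates."""
        arr = np.asarray(fir, dtype=float)
        x = 1.0 - arr if self.flip else arr
        f = (logit(np.clip(x, _EPS, 1 - _EPS)) - self.beta0) / self.beta1
        f = np.clip(f, 0.0, 1.0)
        f = np.where(np.isnan(arr), np.nan, f)
        if isinstance(fir, pd.DataFrame):
            return pd.DataFrame(f, index=fir.index, columns=fir.columns)
        if np.isscalar(fir) or getattr(fir, "ndim", 1) == 0:
            return float(f)
        return f

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


def _mae(model: CalibrationModel, pools: ControlledPoolSet) -> float:
    f, x = pools.pairs()
    return float(np.mean(np.abs(model.predict(x) - f)))


def fit_calibration(
    pools: ControlledPoolSet,
    validation: ControlledPoolSet | None = None,
    fixation_threshold: float = DEFAULT_FIXATION_THRESHOLD,
) -> CalibrationModel:
    """Fit the unique logistic calibration on controlled-pool pairs.

    Least squares of ``logit(fir)`` (FIR clamped to [eps, 1-eps]) on the
    known frequencies. Requires at least two distinct known frequencies
    strictly inside (0, 1); a single pool frequency leaves the slope
    unidentifiable. Held-out accuracy on ``validation`` is stored as a
    mean absolute error in the diagnostics.
    """
    f, x = pools.pairs()
    interior = np.unique(f[(f > 0) & (f < 1)])
    if interior.size < 2:
        raise ValueError(
            "calibration needs >= 2 distinct known frequencies in (0, 1); "
            f"got {interior.size}"
        )
    keep = (f > 0) & (f < 1)
    y = logit(np.clip(x[keep], _EPS, 1 - _EPS))
    slope, intercept = np.polyfit(f[keep], y, 1)
    flip = bool(slope < 0)
    if flip:
        # reversed allele orientation: refit on flipped FIR
        logger.warning("negative calibration slope; flipping FIR orientation (B = high FIR)")
        y = logit(np.clip(1 - x[keep], _EPS, 1 - _EPS))
        slope, intercept = np.polyfit(f[keep], y, 1)
    model = CalibrationModel(
        beta0=float(intercept), beta1=float(slope),
        fixation_threshold=fixation_threshold, flip=flip,
    )
    model.calibration_mae = _mae(model, pools)
    if validation is not None:
        model.validation_mae = _mae(model, validation)
    return model


def classify_polymorphism(
    fir_value: float,
    reference_row: pd.Series,
    model: CalibrationModel,
    z: float = DEFAULT_CLUSTER_Z,
) -> tuple[str, float]:
    """Classify one bulk x SNP cell and return (call, frequency).

    mono_A requires the FIR to sit inside the homozygote-A inbred
    cluster (``mean_A +/- z * sd_A``) AND the calibrated frequency to be
    below the fixation threshold; symmetrically for mono_B. Monomorphic
    calls snap the frequency to exactly 0 or 1; everything else is
    polymorphic with the model's estimate. Missing FIR propagates a
    missing call.
    """
    if fir_value is None or np.isnan(fir_value):
        return MISSING, np.nan
    f_hat = float(model.predict(float(fir_value)))
    t = model.fixation_threshold
    in_a = abs(fir_value - reference_row["mean_A"]) <= z * reference_row["sd_A"]
    in_b = abs(fir_value - reference_row["mean_B"]) <= z * reference_row["sd_B"]
    if in_a and f_hat < t:
        return MONO_A, 0.0
    if in_b and f_hat > 1 - t:
        return MONO_B, 1.0
    return POLYMORPHIC, f_hat


def estimate_frequencies(
    fir: pd.DataFrame,
    reference: pd.DataFrame,
    model: CalibrationModel,
    z: float = DEFAULT_CLUSTER_Z,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the two-step estimator to a populations x loci FIR matrix.

    Returns the estimated frequency matrix (NaN where FIR was missing)
    and the matching matrix of polymorphism calls. Shape and labels are
    conserved; loci must match the inbred reference.
    """
    missing_loci = [l for l in fir.columns if l not in reference.index]
    if missing_loci:
        raise ValueError(f"loci absent from inbred reference: {missing_loci[:10]}")
    ref = reference.loc[fir.columns]
    x = fir.to_numpy(dtype=float)
    f_hat = np.asarray(model.predict(x), dtype=float)

    mean_a = ref["mean_A"].to_numpy()[None, :]
    sd_a = ref["sd_A"].to_numpy()[None, :]
    mean_b = ref["mean_B"].to_numpy()[None, :]
    sd_b = ref["sd_B"].to_numpy()[None, :]
    t = model.fixation_threshold
    with np.errstate(invalid="ignore"):
        is_a = (np.abs(x - mean_a) <= z * sd_a) & (f_hat < t)
        is_b = (np.abs(x - mean_b) <= z * sd_b) & (f_hat > 1 - t)
    is_na = np.isnan(x)

    freqs = np.where(is_a, 0.0, np.where(is_b, 1.0, f_hat))
    freqs = np.where(is_na, np.nan, freqs)
    calls = np.full(x.shape, POLYMORPHIC, dtype=object)
    calls[is_a] = MONO_A
    calls[is_b] = MONO_B
    calls[is_na] = MISSING
    return (
        pd.DataFrame(freqs, index=fir.index, columns=fir.columns),
        pd.DataFrame(calls, index=fir.index, columns=fir.columns),
    )


def calibration_report(model: CalibrationModel) -> dict:
    """Flat diagnostics record of a fitted calibration."""
    if model.calibration_mae is None:
        raise ValueError("model has no fit diagnostics (unfitted?)")
    return {
        "beta0": model.beta0,
        "beta1": model.beta1,
        "fixation_threshold": model.fixation_threshold,
        "calibration_mae": model.calibration_mae,
        "validation_mae": model.validation_mae,
    }
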