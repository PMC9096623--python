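"""Effect-size scale conversions and artifact corrections.

Pooling can run on four scales: raw Pearson r, Fisher z, small-sample
bias-corrected r, or r corrected for direct range restriction (Thorndike
Case II).  Every transformed effect carries its scale tag so that pooling
refuses to mix scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

Scale = Literal["fisher_z", "raw_r", "bias_corrected_r", "range_corrected_r"]


@dataclass(frozen=True)
class RangeRestrictionParams:
    """Direct range-restriction ratio u = reference SD / observed SD.

    For IQ scores the reference population SD is 15, so u = 15 / sd_observed.
    u == 1 makes the correction the identity.
    """

    u: float

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")

    @classmethod
    def from_iq_sd(cls, sd_observed: float, reference_sd: float = 15.0) -> "RangeRestrictionParams":
        return cls(u=reference_sd / sd_observed)


@dataclass(frozen=True)
class TransformedEffect:
    value: float
    variance: float
    scale: Scale
    n: int
    source: object = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.scale != "fisher_z" and abs(self.value) > 1:
            raise ValueError("r-scale effects must lie in [-1, 1]")


def fisher_z(r):
    """arctanh transform of a correlation; domain error outside (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def back_transform(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def z_variance(n):
    """Sampling variance 1/(n-3) of a Fisher-z transformed correlation."""
    n = np.asarray(n)
    if np.any(n < 4):
        raise ValueError("z_variance requires n >= 4")
    out = 1.0 / (np.asarray(n, dtype=float) - 3.0)
    return float(out) if out.ndim == 0 else out


def bias_correct_r(r, n):
    """Approximately unbiased estimate of rho from an observed r.

    Uses the Olkin–Pratt style first-order expansion
    ``r * (1 + (1 - r^2) / (2 (n - 3)))``, clipped into (-1, 1).  The exact
    correction is a pluggable strategy; this default is accurate to O(n^-2).
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("bias_correct_r requires |r| < 1")
    if np.any(n < 4):
        raise ValueError("bias_correct_r requires n >= 4")
    out = np.clip(r * (1.0 + (1.0 - r ** 2) / (2.0 * (n - 3.0))), -0.999999, 0.999999)
    return float(out) if out.ndim == 0 else out


def case2_correct(r, params: RangeRestrictionParams):
    """Thorndike Case II correction for direct range restriction.

    r_c = r u / sqrt(1 + r^2 (u^2 - 1)).  Sign-preserving, strictly
    increasing in r, identity at u == 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("case2_correct requires |r| < 1")
    u = params.u
    out = r * u / np.sqrt(1.0 + r ** 2 * (u ** 2 - 1.0))
    return float(out) if out.ndim == 0 else out


def case2_derivative(r, params: RangeRestrictionParams):
    """d(case2)/dr = u / (1 + r^2 (u^2 - 1))^(3/2)."""
    r = np.asarray(r, dtype=float)
    u = params.u
    out = u / (1.0 + r ** 2 * (u ** 2 - 1.0)) ** 1.5
    return float(out) if out.ndim == 0 else out


def corrected_se(r, se_r, params: RangeRestrictionParams):
    """Delta-method standard error of the Case II corrected correlation."""
    se_r = np.asarray(se_r, dtype=float)
    if np.any(se_r <= 0):
        raise ValueError("se_r must be positive")
    out = np.abs(case2_derivative(r, params)) * se_r
    return float(out) if out.ndim == 0 else out


def transform_record(rec, scale: Scale = "fisher_z",
                     rr_params: Optional[RangeRestrictionParams] = None) -> TransformedEffect:
    """Put one effect record on a pooling scale with its sampling variance.

    Raw-r scales use the large-sample variance (1 - r^2)^2 / (n - 1); the
    range-corrected scale additionally applies the delta-method SE and
    requires range-restriction parameters.
    """
    r, n = rec.r, rec.n
    if scale == "fisher_z":
        return TransformedEffect(fisher_z(r), z_variance(n), "fisher_z", n, rec)
    var_r = (1.0 - r ** 2) ** 2 / (n - 1.0)
    if scale == "raw_r":
        return TransformedEffect(r, var_r, "raw_r", n, rec)
    if scale == "bias_corrected_r":
        rc = bias_correct_r(r, n)
        return TransformedEffect(rc, var_r, "bias_corrected_r", n, rec)
    if scale == "range_corrected_r":
        if rr_params is None:
            raise ValueError("range_corrected_r requires RangeRestrictionParams")
        rc = case2_correct(r, rr_params)
        se = corrected_se(r, math.sqrt(var_r), rr_params)
        return TransformedEffect(float(rc), float(se ** 2), "range_corrected_r", n, rec)
    raise ValueError(f"unknown scale: {scale!r}")
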