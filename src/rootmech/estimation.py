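"""Parameter estimation from sampled stress-strain curves.

Implements the measurement pipeline used to fit the one-parameter
constitutive model to a tensile-test curve:

1. locate the peak (sigma_p, eps_p) — first sample attaining the maximum
   stress, so post-peak necking tails never shift the peak strain;
2. estimate the linear elastic modulus E0 as the secant modulus at a
   fraction q of peak stress (default q = 0.4), using the first crossing
   of q*sigma_p with linear interpolation between bracketing samples;
3. take the peak secant modulus Ep = sigma_p/eps_p and form E = E0/Ep;
4. evaluate the critical point x_e = y^{-1}(q) under the fitted model and
   the residual statistics of the normalised data against it.

The secant estimator is *not* unbiased for the generating E even on exact
model data: on a noiseless model curve it converges to q/x_q(E_true),
which is strictly below E_true.  :func:`plug_in_modulus_ratio` computes
that limit so the inherent bias can be separated from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .constitutive import (
    DomainError,
    E_LOWER,
    RootMaterialParams,
    critical_point,
    stress_ratio,
)

__all__ = [
    "DegenerateCurveError",
    "SamplingError",
    "StressStrainCurve",
    "FitResult",
    "peak_point",
    "secant_modulus_at_fraction",
    "peak_secant_modulus",
    "normalize_curve",
    "residual_statistics",
    "fit_curve",
    "plug_in_modulus_ratio",
]


class DegenerateCurveError(ValueError):
    """Curve carries no usable signal (e.g. all-zero stress)."""


class SamplingError(ValueError):
    """Sampling too sparse to bracket a required stress level."""


@dataclass
class StressStrainCurve:
    """Sampled stress-strain series from one tensile test.

    Parameters
    ----------
    strain : array-like
        Dimensionless strains, strictly increasing, first value >= 0.
    stress : array-like
        Stresses in MPa, same length, all >= 0.
    meta : object, optional
        Specimen metadata (species, diameter, gauge length); opaque here.
    """

    strain: np.ndarray
    stress: np.ndarray
    meta: Optional[Any] = field(default=None)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.ndim != 1 or self.stress.ndim != 1:
            raise ValueError("strain and stress must be 1-D series")
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must have equal length")
        if len(self.strain) < 3:
            raise ValueError("curve needs at least 3 samples")
        if self.strain[0] < 0:
            raise ValueError("first strain must be >= 0")
        if np.any(np.diff(self.strain) <= 0):
            bad = int(np.argmax(np.diff(self.strain) <= 0)) + 1
            raise ValueError(f"strains must be strictly increasing (row {bad})")
        if np.any(self.stress < 0):
            raise ValueError("stresses must be non-negative")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters and diagnostics for one curve.

    ``params`` is None when the fit is invalid (estimated E <= 1, i.e. the
    curve is convex or super-linear and violates the model assumption); the
    raw moduli and E remain available for diagnosis.  ``x_e`` is the
    model-based critical point y^{-1}(q); ``x_e_data`` is the data-based
    alternative, the strain ratio at the first crossing of q*sigma_p.
    """

    params: Optional[RootMaterialParams]
    E: float
    x_e: float
    mean_abs_residual: float
    residual_variance: float
    n_points_used: int
    sigma_p: float
    eps_p: float
    E0: float
    Ep: float
    q: float
    x_e_data: float
    valid: bool


def peak_point(curve: StressStrainCurve) -> tuple[float, float]:
    """Peak strain and stress (eps_p, sigma_p).

    sigma_p is the maximum stress; eps_p the strain at the *first* index
    attaining it, so a necking tail (strain continuing past peak stress)
    does not shift the peak strain.
    """
    ip = int(np.argmax(curve.stress))  # argmax returns the first maximum
    sigma_p = float(curve.stress[ip])
    eps_p = float(curve.strain[ip])
    if sigma_p <= 0.0:
        raise DegenerateCurveError("all stresses are zero; no peak exists")
    if eps_p <= 0.0:
        raise DegenerateCurveError("peak stress at zero strain; degenerate curve")
    return eps_p, sigma_p


def _first_crossing_strain(curve: StressStrainCurve, target: float) -> float:
    """Strain at the first pre-peak crossing of ``target`` stress.

    Linear interpolation between the bracketing samples makes the result
    grid-independent; taking the *first* crossing guards against
    noise-induced multiple crossings.
    """
    ip = int(np.argmax(curve.stress))
    s = curve.stress[: ip + 1]
    e = curve.strain[: ip + 1]
    above = np.nonzero(s >= target)[0]
    if len(above) == 0:
        raise SamplingError("no pre-peak sample reaches the target stress")
    j = int(above[0])
    if j == 0:
        raise SamplingError(
            "first sample already at or above the target stress; sample the "
            "low-strain region more densely"
        )
    # s[j-1] < target <= s[j] by construction of the first crossing
    frac = (target - s[j - 1]) / (s[j] - s[j - 1])
    return float(e[j - 1] + frac * (e[j] - e[j - 1]))


def secant_modulus_at_fraction(curve: StressStrainCurve, q: float = 0.4) -> float:
    """Linear elastic modulus E0: secant modulus at stress fraction ``q``.

    E0 = (q*sigma_p) / eps_q, where eps_q is the strain at the first
    pre-peak crossing of q*sigma_p (linearly interpolated).
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"stress fraction q must lie in (0, 1) (got {q!r})")
    _, sigma_p = peak_point(curve)
    eps_q = _first_crossing_strain(curve, q * sigma_p)
    if eps_q <= 0.0:
        raise DegenerateCurveError("target stress reached at zero strain")
    return q * sigma_p / eps_q


def peak_secant_modulus(curve: StressStrainCurve) -> float:
    """Peak secant modulus Ep = sigma_p/eps_p (MPa)."""
    eps_p, sigma_p = peak_point(curve)
    return sigma_p / eps_p


def normalize_curve(curve: StressStrainCurve) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless pre-peak series (x, y) = (eps/eps_p, sigma/sigma_p).

    Truncated to x <= 1 inclusive: samples beyond the peak strain (necking
    tails) are dropped, and the last retained point is exactly (1, 1).
    """
    eps_p, sigma_p = peak_point(curve)
    ip = int(np.argmax(curve.stress))
    x = curve.strain[: ip + 1] / eps_p
    y = curve.stress[: ip + 1] / sigma_p
    return x, y


def residual_statistics(
    x: np.ndarray, y: np.ndarray, E: float, *, ddof: int = 1
) -> tuple[float, float]:
    """Residual mean and variance of a normalised curve against the model.

    Residuals r_i = y_i - y_model(x_i, E) on the dimensionless stress
    scale.  Returns (mean of |r_i|, sample variance of r_i).  The variance
    denominator is n - ddof; ddof = 1 (unbiased) by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points for the residual variance")
    r = y - stress_ratio(x, E)
    return float(np.mean(np.abs(r))), float(np.var(r, ddof=ddof))


def fit_curve(curve: StressStrainCurve, q: float = 0.4) -> FitResult:
    """Full fit of one curve: moduli, dimensionless modulus, critical point
    and residual statistics.

    When the estimated E = E0/Ep does not exceed 1 the fit is flagged
    invalid (``valid=False``): the curve is convex or super-linear and the
    concave-down model cannot represent it.  Moduli and E are still
    reported; model-dependent fields are NaN.
    """
    eps_p, sigma_p = peak_point(curve)
    Ep = sigma_p / eps_p
    E0 = secant_modulus_at_fraction(curve, q)
    E = E0 / Ep
    eps_q = q * sigma_p / E0
    x_e_data = eps_q / eps_p
    x, y = normalize_curve(curve)

    if E < E_LOWER:
        return FitResult(
            params=None, E=E, x_e=float("nan"),
            mean_abs_residual=float("nan"), residual_variance=float("nan"),
            n_points_used=len(x), sigma_p=sigma_p, eps_p=eps_p,
            E0=E0, Ep=Ep, q=q, x_e_data=x_e_data, valid=False,
        )

    x_e = critical_point(E, q)
    mean_abs, var = residual_statistics(x, y, E)
    params = RootMaterialParams(sigma_p=sigma_p, eps_p=eps_p, E0=E0, Ep=Ep)
    return FitResult(
        params=params, E=E, x_e=x_e,
        mean_abs_residual=mean_abs, residual_variance=var,
        n_points_used=len(x), sigma_p=sigma_p, eps_p=eps_p,
        E0=E0, Ep=Ep, q=q, x_e_data=x_e_data, valid=True,
    )


def plug_in_modulus_ratio(E_true: float, q: float = 0.4) -> float:
    """Dimensionless modulus the secant estimator converges to on exact
    model data with shape parameter ``E_true``.

    Equals q / x_q where x_q = y^{-1}(q, E_true).  Since y(x) <= E*x with
    equality only at the origin, this is strictly below E_true for every
    E_true > 1, and tends to E_true as q -> 0 (the secant tends to the
    tangent at the origin).  The gap is the self-consistency bias of the
    estimation pipeline.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"stress fraction q must lie in (0, 1) (got {q!r})")
    return q / critical_point(E_true, q)
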