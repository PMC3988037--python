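"""Dimensionless constitutive model for single-root tension.

The pre-peak tensile response of a single root is reduced to a one-parameter
family of concave-down curves.  With strain and stress normalised by their
values at the peak (x = eps/eps_p, y = sigma/sigma_p), the model is

    y(x) = E*x - (E - 1) * x**(E/(E - 1)),        0 <= x <= 1,  E > 1,

where E = E0/Ep is the dimensionless elastic modulus: the ratio of the
linear elastic modulus E0 (secant slope in the near-linear regime) to the
peak secant modulus Ep = sigma_p/eps_p.  The curve is pinned by four
boundary conditions: it passes through the origin, has initial slope E,
reaches (1, 1) at the peak, and has zero slope there.  For every E > 1 the
second derivative is negative on (0, 1], so the curve is concave down and
stiffness decreases monotonically from E0 to zero.

All functions operate on the dimensionless scale except
:func:`dimensional_stress`, which maps back to MPa for a given specimen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "ModelAssumptionError",
    "ModelParams",
    "RootMaterialParams",
    "DimensionlessPoint",
    "E_LOWER",
    "dimensionless_modulus",
    "nonlinear_exponent",
    "stress_ratio",
    "tangent_modulus",
    "curvature",
    "inverse_stress_ratio",
    "critical_point",
    "dimensional_stress",
]

#: Smallest admissible dimensionless modulus.  The model requires E > 1
#: strictly; values this close to 1 are rejected rather than switched to the
#: linear-elastic limit y = x.
E_LOWER = 1.0 + 1e-9

_X_ATOL = 1e-12  # slack for boundary comparisons on the strain ratio


class DomainError(ValueError):
    """An argument lies outside the model's domain."""


class ModelAssumptionError(ValueError):
    """Specimen moduli violate the concavity assumption (requires E0 > Ep)."""


def _check_E(E: float) -> float:
    E = float(E)
    if not np.isfinite(E) or E < E_LOWER:
        raise DomainError(
            f"dimensionless modulus must exceed 1 (got E={E!r}); "
            "the model is only defined for concave-down curves"
        )
    return E


def _check_x(x, *, lo: float = 0.0):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < lo - _X_ATOL) or np.any(arr > 1.0 + _X_ATOL):
        raise DomainError(
            f"strain ratio must lie in [{lo}, 1] (post-peak response is not "
            f"modelled); got values in [{arr.min()!r}, {arr.max()!r}]"
        )
    return np.clip(arr, lo, 1.0)


@dataclass(frozen=True)
class ModelParams:
    """Shape parameter of one dimensionless curve.

    Parameters
    ----------
    E : float
        Dimensionless elastic modulus E0/Ep; must be strictly greater
        than 1.
    """

    E: float

    def __post_init__(self) -> None:
        _check_E(self.E)

    @property
    def exponent(self) -> float:
        """Exponent of the nonlinear term, E/(E - 1)."""
        return nonlinear_exponent(self.E)


@dataclass(frozen=True)
class RootMaterialParams:
    """Dimensional tensile parameters of one root specimen.

    Parameters
    ----------
    sigma_p : float
        Peak (breaking) stress, MPa.
    eps_p : float
        Strain at peak stress, dimensionless (mm/mm).
    E0 : float
        Linear elastic modulus, MPa (secant in the near-linear regime).
    Ep : float
        Peak secant modulus sigma_p/eps_p, MPa.  Must equal that ratio to
        within 1e-9 relative; use :meth:`from_peak` to have it derived.
    """

    sigma_p: float
    eps_p: float
    E0: float
    Ep: float

    def __post_init__(self) -> None:
        if not (self.sigma_p > 0 and self.eps_p > 0):
            raise DomainError("peak stress and peak strain must be positive")
        if not (self.E0 > self.Ep > 0):
            raise ModelAssumptionError(
                f"require E0 > Ep > 0 (got E0={self.E0}, Ep={self.Ep}); "
                "a non-concave specimen cannot be represented"
            )
        ratio = self.sigma_p / self.eps_p
        if not math.isclose(self.Ep, ratio, rel_tol=1e-9):
            raise DomainError(
                f"Ep={self.Ep} inconsistent with sigma_p/eps_p={ratio}"
            )

    @classmethod
    def from_peak(cls, sigma_p: float, eps_p: float, E0: float) -> "RootMaterialParams":
        """Build parameters with Ep derived as sigma_p/eps_p."""
        return cls(sigma_p=sigma_p, eps_p=eps_p, E0=E0, Ep=sigma_p / eps_p)

    @property
    def E(self) -> float:
        """Dimensionless modulus E0/Ep."""
        return dimensionless_modulus(self.E0, self.Ep)


@dataclass(frozen=True)
class DimensionlessPoint:
    """One point (x, y) = (eps/eps_p, sigma/sigma_p) on a normalised curve."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise DomainError("dimensionless coordinates must be non-negative")


def dimensionless_modulus(E0: float, Ep: float) -> float:
    """Dimensionless elastic modulus E = E0/Ep.

    Raises
    ------
    DomainError
        If either modulus is non-positive.
    ModelAssumptionError
        If E0 <= Ep: the resulting curve would not be concave down, so the
        specimen violates the model assumption.
    """
    if not (E0 > 0 and Ep > 0):
        raise DomainError(f"moduli must be positive (got E0={E0}, Ep={Ep})")
    if E0 <= Ep:
        raise ModelAssumptionError(
            f"E0={E0} <= Ep={Ep}: dimensionless modulus would be <= 1 and "
            "the stress-strain curve cannot be concave down"
        )
    return E0 / Ep


def nonlinear_exponent(E: float) -> float:
    """Exponent n = E/(E - 1) of the nonlinear deformation term.

    Strictly decreasing in E, always > 1 (n -> 1 as E -> inf, n -> inf as
    E -> 1+).
    """
    E = _check_E(E)
    return E / (E - 1.0)


def stress_ratio(x, E: float):
    """Stress ratio y(x) = E*x - (E - 1)*x**(E/(E-1)) on [0, 1].

    The first term is the linear portion of deformation, the second the
    nonlinear portion.  Accepts scalars or arrays for ``x``.
    """
    E = _check_E(E)
    xa = _check_x(x)
    n = E / (E - 1.0)
    y = E * xa - (E - 1.0) * xa**n
    return float(y) if np.isscalar(x) or np.ndim(x) == 0 else y


def tangent_modulus(x, E: float):
    """Slope dy/dx = E*(1 - x**(1/(E-1))).

    Equals E at x = 0 (boundary condition 2) and 0 at x = 1 (boundary
    condition 4); non-negative on [0, 1].
    """
    E = _check_E(E)
    xa = _check_x(x)
    d = E * (1.0 - xa ** (1.0 / (E - 1.0)))
    return float(d) if np.isscalar(x) or np.ndim(x) == 0 else d


def curvature(x, E: float):
    """Second derivative d2y/dx2 = -(E/(E-1)) * x**((2-E)/(E-1)).

    Strictly negative on (0, 1] for every E > 1 (the curve is concave
    down).  x = 0 is excluded from the domain: for E > 2 the curvature
    diverges there, so no finite value is returned at the origin.
    """
    E = _check_E(E)
    xa = _check_x(x, lo=math.ulp(0.0))
    if np.any(np.asarray(x, dtype=float) <= 0.0):
        raise DomainError(
            "curvature is not defined at x=0 (it diverges for E > 2)"
        )
    c = -(E / (E - 1.0)) * xa ** ((2.0 - E) / (E - 1.0))
    return float(c) if np.isscalar(x) or np.ndim(x) == 0 else c


def inverse_stress_ratio(
    y: float, E: float, *, atol: float = 1e-10, max_iter: int = 200
) -> float:
    """Unique x in [0, 1] with stress_ratio(x, E) = y.

    Solved by bisection, which is guaranteed by the strict monotonicity of
    y on [0, 1] and remains robust for E arbitrarily close to 1 (where
    derivative-based iterations degrade).

    Parameters
    ----------
    y : float
        Target stress ratio in [0, 1].
    atol : float
        Absolute tolerance on x (default 1e-10).
    """
    E = _check_E(E)
    y = float(y)
    if not -_X_ATOL <= y <= 1.0 + _X_ATOL:
        raise DomainError(f"stress ratio must lie in [0, 1] (got {y!r})")
    if y <= 0.0:
        return 0.0
    if y >= 1.0:
        return 1.0
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if stress_ratio(mid, E) < y:
            lo = mid
        else:
            hi = mid
        if hi - lo <= atol:
            break
    return 0.5 * (lo + hi)


def critical_point(E: float, q: float = 0.4) -> float:
    """Strain ratio x_e at which the stress reaches fraction ``q`` of peak.

    The critical point separates the linear-dominated early stage from the
    regime where nonlinear deformation is significant; by convention it is
    taken at q = 0.4 (40 % of the tensile stress limit).  Monotone
    increasing in q and decreasing in E.
    """
    if not 0.0 <= q <= 1.0:
        raise DomainError(f"stress fraction q must lie in [0, 1] (got {q!r})")
    return inverse_stress_ratio(q, E)


def dimensional_stress(eps, params: RootMaterialParams):
    """Model stress (MPa) at strain ``eps`` for one specimen.

    sigma(eps) = sigma_p * y(eps/eps_p, E0/Ep); defined on [0, eps_p] only
    (the model ends at the peak by construction).
    """
    e = np.asarray(eps, dtype=float)
    if np.any(e < -_X_ATOL) or np.any(e > params.eps_p * (1.0 + _X_ATOL)):
        raise DomainError(
            f"strain must lie in [0, eps_p={params.eps_p}]; post-peak "
            "behaviour is not modelled"
        )
    y = stress_ratio(np.clip(e / params.eps_p, 0.0, 1.0), params.E)
    sigma = params.sigma_p * np.asarray(y)
    return float(sigma) if np.isscalar(eps) or np.ndim(eps) == 0 else sigma
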