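"""Helfrich curvature elasticity on the sampled surface.

Energy functional (total-curvature convention, spontaneous curvature c0
defaulting to zero for a symmetric bilayer):

    F = int_S [ (k_c/2)(2H + c0)^2 + k_d K + lambda ] dA + dp V

whose stationarity condition for an axisymmetric vesicle is the shape
equation evaluated pointwise by :func:`el_residual`:

    dp - 2 lambda H + k_c (2H + c0)(2H^2 - c0 H - 2K) + 2 k_c lap(H) = 0.

The inverse problem — given a shape and bending constants, find the
bending-induced pressure dp and the surface tension lambda that best
satisfy the shape equation — is linear in (dp, lambda) and solved by
area-weighted least squares.  On a sphere the two columns are collinear
(Laplace law: only dp - 2 lambda/R is identifiable); the solver reports
the condition number and flags that degeneracy instead of failing
silently.

Units: k_c, k_d in erg; curvatures in 1/um from the geometry module;
lambda in N/m and dp in Pa (converted internally to SI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import CurvatureField, EllipsoidShape, curvature_field, ellipsoid_volume

__all__ = [
    "BendingParams",
    "BendingSolution",
    "ObservedBending",
    "helfrich_energy",
    "el_residual",
    "solve_inverse_bending",
    "bending_from_stretching",
    "fit_bending_constants",
]

_ERG = 1e-7  # J
_DEGENERACY_COND = 1e8


@dataclass(frozen=True)
class BendingParams:
    """Bending modulus k_c and Gaussian (saddle) modulus k_d, in erg;
    spontaneous curvature c0 in 1/um (default 0: planar resting bilayer)."""

    k_c: float
    k_d: float = 0.0
    c0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_c < 0:
            raise ValueError("k_c must be non-negative")


@dataclass(frozen=True)
class BendingSolution:
    """Inverse-solve result: dp (Pa), lam (N/m), area-weighted RMS of the
    shape-equation residual (Pa) and the condition number of the
    least-squares system.  ``degenerate`` marks the sphere collinearity."""

    dp: float
    lam: float
    residual_rms: float
    condition_number: float
    degenerate: bool = False


@dataclass(frozen=True)
class ObservedBending:
    """Per-shape observation used when fitting bending constants: the
    bending-induced pressure and, optionally, the total free energy."""

    dp: float  # Pa
    energy: float | None = None  # erg
    lam: float | None = None  # N/m
    volume: float | None = None  # um^3


def _si_fields(field: CurvatureField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(H, K, lap H) in 1/m, 1/m^2, 1/m^3."""
    return field.H * 1e6, field.K * 1e12, field.lap_H * 1e18


def helfrich_energy(
    field: CurvatureField,
    params: BendingParams,
    lam: float = 0.0,
    dp: float = 0.0,
    volume: float | None = None,
) -> float:
    """Total free energy in erg.

    lam in N/m, dp in Pa, volume in um^3 (taken from the field's shape
    when omitted).  A sphere with c0 = lam = dp = 0 gives the classic
    scale-invariant 8 pi k_c + 4 pi k_d.
    """
    if volume is None:
        volume = ellipsoid_volume(field.shape)
    f_c = 0.5 * params.k_c * (2.0 * field.H + params.c0) ** 2 + params.k_d * field.K
    lam_erg_um2 = lam * 1e-5  # N/m = J/m^2 -> erg/um^2
    dp_erg_um3 = dp * 1e-11  # Pa = J/m^3 -> erg/um^3
    return field.integrate(f_c + lam_erg_um2) + dp_erg_um3 * volume


def el_residual(
    field: CurvatureField, params: BendingParams, lam: float, dp: float
) -> np.ndarray:
    """Pointwise left side of the shape equation, in Pa.

    Zero everywhere for a sphere obeying the Laplace law dp = 2 lam / R.
    """
    H, K, lapH = _si_fields(field)
    kc = params.k_c * _ERG
    c0 = params.c0 * 1e6
    return (
        dp
        - 2.0 * lam * H
        + kc * (2.0 * H + c0) * (2.0 * H**2 - c0 * H - 2.0 * K)
        + 2.0 * kc * lapH
    )


def _design(field: CurvatureField, params: BendingParams, weighting: str):
    H, K, lapH = _si_fields(field)
    kc = params.k_c * _ERG
    c0 = params.c0 * 1e6
    b = kc * (2.0 * H + c0) * (2.0 * H**2 - c0 * H - 2.0 * K) + 2.0 * kc * lapH
    if weighting == "area":
        w = np.sqrt(field.dA / field.dA.sum())
    elif weighting == "uniform":
        w = np.full(H.size, 1.0 / np.sqrt(H.size))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return H, b, w


def solve_inverse_bending(
    field: CurvatureField,
    params: BendingParams,
    lam_fixed: float | None = None,
    weighting: str = "area",
) -> BendingSolution:
    """Fit (dp, lam) so the shape equation holds in the least-squares sense.

    Minimizes sum dA * residual^2 (or uniform-in-theta with
    ``weighting="uniform"``).  ``lam_fixed`` pins the tension and fits dp
    alone — the well-posed mode on a sphere, where otherwise only the
    combination dp - 2 lam / R is identifiable and the solution is
    flagged degenerate.
    """
    H, b, w = _design(field, params, weighting)
    if lam_fixed is None:
        A = np.column_stack([np.ones_like(H), -2.0 * H]) * w[:, None]
        rhs = -b * w
        coef, _, _, sv = np.linalg.lstsq(A, rhs, rcond=None)
        dp, lam = float(coef[0]), float(coef[1])
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    else:
        lam = float(lam_fixed)
        A = (np.ones_like(H) * w)[:, None]
        rhs = -(b - 2.0 * lam * H) * w
        coef, _, _, sv = np.linalg.lstsq(A, rhs, rcond=None)
        dp = float(coef[0])
        cond = 1.0
    res = el_residual(field, params, lam, dp)
    rms = float(np.sqrt(field.integrate(res**2) / field.area))
    return BendingSolution(
        dp=dp,
        lam=lam,
        residual_rms=rms,
        condition_number=cond,
        degenerate=bool(cond > _DEGENERACY_COND),
    )


def bending_from_stretching(g: float, h: float, nu: float) -> float:
    """Homogeneous-plate estimate k_c = g h^2 / (12 (1 - nu^2)), in erg.

    g is the stretch rigidity in N/m, h the sheet thickness in nm, nu the
    Poisson ratio (0 <= nu <= 0.5).
    """
    if not h > 0:
        raise ValueError("thickness must be positive")
    if not 0.0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    kc_J = g * (h * 1e-9) ** 2 / (12.0 * (1.0 - nu**2))
    return kc_J / _ERG


def fit_bending_constants(
    shapes: list[EllipsoidShape],
    params0: BendingParams,
    observations: list[ObservedBending],
    n_samples: int = 200,
    ftol: float = 1e-10,
) -> BendingParams:
    """Recover (k_c, k_d) from per-shape bending observations.

    For each shape the inverse solve predicts dp(k_c) (linear in k_c; the
    Gaussian modulus never enters the shape equation for fixed topology —
    Gauss–Bonnet removes it).  k_d is therefore only identifiable when
    total energies are observed, through the 4 pi k_d term; without
    energies it is reported unchanged from ``params0``.  Deterministic
    Nelder–Mead from ``params0`` (e.g. the homogeneous-sheet relation)
    with the stated objective tolerance.
    """
    if len(shapes) < 2:
        raise ValueError("need at least two distinct shapes")
    if len(observations) != len(shapes):
        raise ValueError("one observation per shape required")
    fields = [curvature_field(s, n_samples) for s in shapes]
    # unit responses: dp and lam scale linearly with k_c
    unit = [solve_inverse_bending(f, BendingParams(k_c=1.0, c0=params0.c0)) for f in fields]
    have_energy = all(o.energy is not None for o in observations)

    dp_scale = max(abs(o.dp) for o in observations) or 1.0
    en_scale = (
        max(abs(o.energy) for o in observations) if have_energy else 1.0
    ) or 1.0

    def objective(x: np.ndarray) -> float:
        k_c, k_d = x
        if k_c <= 0:
            return 1e12 * (1.0 - k_c)
        total = 0.0
        for f, u, obs in zip(fields, unit, observations):
            total += ((k_c * u.dp - obs.dp) / dp_scale) ** 2
            if have_energy:
                lam = obs.lam if obs.lam is not None else k_c * u.lam
                dp = k_c * u.dp
                F = helfrich_energy(
                    f, BendingParams(k_c, k_d, params0.c0), lam, dp, obs.volume
                )
                total += ((F - obs.energy) / en_scale) ** 2
        return total

    res = minimize(
        objective,
        x0=np.array([params0.k_c, params0.k_d]),
        method="Nelder-Mead",
        options={"fatol": ftol, "xatol": 1e-12, "maxiter": 4000},
    )
    if not res.success:
        raise RuntimeError(
            f"bending-constant fit did not converge: {res.message}; "
            f"final objective {res.fun:.3e}"
        )
    k_c, k_d = float(res.x[0]), float(res.x[1])
    if not have_energy:
        k_d = params0.k_d  # unidentifiable from the shape equation alone
    return BendingParams(k_c=k_c, k_d=k_d, c0=params0.c0)
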