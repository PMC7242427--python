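"""Differential geometry of axisymmetric spheroids.

The cell is modelled as a spheroid of revolution with equatorial
semi-axis ``a`` (along x and y) and polar semi-axis ``c`` (along z), both
in micrometres; the resting erythrocyte-like shape is oblate (a > c).
All surface fields are closed-form functions of the polar angle
``theta`` (the surface is parameterized as ``r = a sin(theta)``,
``z = c cos(theta)``), so every surface integral reduces to a 1-D
Gauss–Legendre quadrature with spectral accuracy.

Sign convention: outward normal; the mean curvature H and Gaussian
curvature K are positive on a sphere (H = 1/R, K = 1/R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipsoidShape",
    "CurvatureField",
    "ellipsoid_volume",
    "ellipsoid_area",
    "curvature_field",
]

#: relative |1 - c/a| below which the sphere limit is used (avoids 0/0 in
#: the eccentricity formula)
_SPHERE_SWITCH = 1e-8


@dataclass(frozen=True)
class EllipsoidShape:
    """Axisymmetric spheroid, semi-axes in um.

    ``a`` is the equatorial semi-axis (x and y), ``c`` the polar one (z).
    Oblate intent (a >= c) is warned on violation, not enforced: swelling
    may legitimately drive the shape prolate.
    """

    a: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0):
            raise ValueError(f"semi-axes must be positive, got a={self.a}, c={self.c}")
        if self.c > self.a * (1 + 1e-12):
            warnings.warn(
                f"shape is prolate (c={self.c} > a={self.a}); oblate geometry intended",
                stacklevel=2,
            )

    @property
    def aspect(self) -> float:
        return self.c / self.a


@dataclass(frozen=True)
class CurvatureField:
    """Curvature data sampled along the polar angle of an axisymmetric surface.

    Per sample: position (r, z) in um, outward unit normal (n_r, n_z),
    mean curvature H (1/um), Gaussian curvature K (1/um^2), surface
    Laplacian of H (1/um^3) and area weight dA (um^2).  The dA weights
    are full quadrature weights: ``field.dA.sum()`` is the surface area.
    """

    shape: EllipsoidShape
    theta: np.ndarray
    position: np.ndarray  # (n, 2): r, z
    normal: np.ndarray  # (n, 2): n_r, n_z
    H: np.ndarray
    K: np.ndarray
    lap_H: np.ndarray
    dA: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.dA <= 0):
            raise ValueError("all area weights must be positive")

    @property
    def area(self) -> float:
        return float(self.dA.sum())

    def integrate(self, values: np.ndarray | float) -> float:
        """Surface integral of a per-sample field."""
        return float(np.sum(values * self.dA))


def ellipsoid_volume(shape: EllipsoidShape) -> float:
    """Volume (4/3) pi a^2 c, in um^3."""
    return 4.0 / 3.0 * np.pi * shape.a**2 * shape.c


def ellipsoid_area(shape: EllipsoidShape) -> float:
    """Closed-form surface area of the spheroid, in um^2.

    Oblate branch: 2 pi a^2 [1 + ((1-e^2)/e) artanh(e)], e^2 = 1 - c^2/a^2.
    Near a = c a series in e^2 keeps the formula continuous through the
    sphere; for c > a the prolate closed form (arcsin) is used.
    """
    a, c = shape.a, shape.c
    x = 1.0 - (c / a) ** 2  # signed e^2; negative means prolate
    if abs(1.0 - c / a) < _SPHERE_SWITCH:
        # sphere limit with leading corrections: artanh(e)/e = 1 + e^2/3 + e^4/5
        return 2.0 * np.pi * a**2 * (2.0 - 2.0 * x / 3.0 - 2.0 * x**2 / 15.0)
    if x > 0:
        e = np.sqrt(x)
        return 2.0 * np.pi * a**2 * (1.0 + (1.0 - x) / e * np.arctanh(e))
    # prolate eccentricity e'^2 = 1 - a^2/c^2
    e = np.sqrt(1.0 - (a / c) ** 2)
    return 2.0 * np.pi * a**2 * (1.0 + c / (a * e) * np.arcsin(e))


def _delta2(a: float, c: float, theta: np.ndarray) -> np.ndarray:
    """Squared metric factor  Delta^2 = a^2 cos^2 + c^2 sin^2."""
    return a**2 * np.cos(theta) ** 2 + c**2 * np.sin(theta) ** 2


def principal_curvatures(
    shape: EllipsoidShape, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Meridional and azimuthal principal curvatures (1/um).

    kappa_m = a c / Delta^3 and kappa_phi = c / (a Delta); at the equator
    of an oblate shape these are a/c^2 and 1/a.
    """
    a, c = shape.a, shape.c
    d = np.sqrt(_delta2(a, c, theta))
    return a * c / d**3, c / (a * d)


def _lap_H(shape: EllipsoidShape, theta: np.ndarray) -> np.ndarray:
    """Surface Laplacian (Laplace–Beltrami) of H, closed form.

    For an axisymmetric scalar f(theta):
        lap f = (1/(r Delta)) d/dtheta [ (r/Delta) df/dtheta ],
    r = a sin(theta), Delta = metric factor.  With u = Delta^2,
    H(u) = c (a^2 + u) / (2 a u^{3/2}) the chain rule gives everything
    analytically; poles are regular (the field is even in theta there).
    """
    a, c = shape.a, shape.c
    u = _delta2(a, c, theta)
    up = (c**2 - a**2) * np.sin(2.0 * theta)
    upp = 2.0 * (c**2 - a**2) * np.cos(2.0 * theta)

    H_u = -c * (3.0 * a**2 + u) / (4.0 * a * u**2.5)
    H_uu = 3.0 * c * (5.0 * a**2 + u) / (8.0 * a * u**3.5)

    Hp = H_u * up
    Hpp = H_uu * up**2 + H_u * upp

    r = a * np.sin(theta)
    rp = a * np.cos(theta)
    d = np.sqrt(u)
    # g = (r/Delta) H';  lap H = g' / (r Delta)
    gp = (rp * Hp + r * Hpp) / d - r * Hp * up / (2.0 * u**1.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = gp / (r * d)
    # pole limit (r -> 0): even symmetry makes lap H finite; our Gauss
    # nodes never sit exactly on a pole, but guard anyway
    out = np.where(np.isfinite(out), out, 0.0)
    return out


def curvature_field(shape: EllipsoidShape, n_samples: int = 200) -> CurvatureField:
    """Sample curvatures and quadrature weights on Gauss–Legendre nodes.

    Nodes are Gauss–Legendre points in theta on [0, pi]; the area weight
    of node i is 2 pi r_i Delta_i w_i, so sums over the field are surface
    integrals of spectral accuracy for smooth integrands.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    a, c = shape.a, shape.c
    nodes, weights = np.polynomial.legendre.leggauss(n_samples)
    theta = 0.5 * np.pi * (nodes + 1.0)
    w = 0.5 * np.pi * weights

    d = np.sqrt(_delta2(a, c, theta))
    r = a * np.sin(theta)
    z = c * np.cos(theta)
    km, kp = principal_curvatures(shape, theta)
    H = 0.5 * (km + kp)
    K = km * kp
    dA = 2.0 * np.pi * r * d * w

    # outward normal of (x^2+y^2)/a^2 + z^2/c^2 = 1, in the (r, z) plane
    nr = np.sin(theta) / a
    nz = np.cos(theta) / c
    norm = np.hypot(nr, nz)

    return CurvatureField(
        shape=shape,
        theta=theta,
        position=np.column_stack([r, z]),
        normal=np.column_stack([nr / norm, nz / norm]),
        H=H,
        K=K,
        lap_H=_lap_H(shape, theta),
        dA=dA,
    )
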