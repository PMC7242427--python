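"""Constitutive physics of the stretched closed membrane.

Three ingredients couple swelling to mechanics:

* a diagonal second-rank rigidity tensor (g'_xx = g'_yy = g0, g'_zz = gzz)
  whose components decay at large strain — a phenomenological model of
  membrane disruption during irreversible (pathological) swelling,
* the inward pressure generated by membrane stretch,
      dP_stretch = (2 g0 dr + gzz dz) / S,
* van 't Hoff osmotic pressure from the transmembrane solute imbalance.

Unit convention: rigidities are stored in N/m (constructors convert from
the customary dyn/nm), deformations and areas stay in um / um^2 like the
geometry module, pressures come out in Pa.  Disruption coefficients are
in um^-n1 and act on the deformation magnitude in um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .units import convert

__all__ = [
    "GAS_CONSTANT",
    "RigidityTensorParams",
    "imm_rigidity",
    "DeformationState",
    "MediumState",
    "rigidity_components",
    "osmotic_pressure",
    "stretching_pressure",
]

#: k_B * N_A, J/(mol K)
GAS_CONSTANT = constants.k * constants.N_A


@dataclass(frozen=True)
class RigidityTensorParams:
    """Stretch-rigidity tensor with large-strain disruption.

    g00, gzz0 : zero-strain rigidities, N/m (equatorial and polar).
    beta0, betaz : disruption coefficients, um^-n1.
    n1 : disruption exponent (integer >= 1).  For even n1 the rigidity is
    an even function of strain; for odd n1 the magnitude of the strain is
    used inside the disruption ratio so rigidity stays positive and
    symmetric under a sign flip.
    """

    g00: float
    gzz0: float
    beta0: float
    betaz: float
    n1: int = 4

    def __post_init__(self) -> None:
        if not (self.g00 > 0 and self.gzz0 > 0):
            raise ValueError("zero-strain rigidities must be positive")
        if self.beta0 < 0 or self.betaz < 0:
            raise ValueError("disruption coefficients must be non-negative")
        if int(self.n1) < 1 or self.n1 != int(self.n1):
            raise ValueError("n1 must be an integer >= 1")

    @classmethod
    def from_quantities(
        cls,
        g00: str | float,
        gzz0: str | float,
        beta0: str | float,
        betaz: str | float,
        n1: int = 4,
    ) -> "RigidityTensorParams":
        """Build from quantity strings, e.g. ``g00="0.0101 dyn/nm"``."""
        n1 = int(n1)
        return cls(
            g00=convert(g00, "rigidity"),
            gzz0=convert(gzz0, "rigidity"),
            beta0=convert(beta0, "disruption", n1=n1),
            betaz=convert(betaz, "disruption", n1=n1),
            n1=n1,
        )


def imm_rigidity() -> RigidityTensorParams:
    """The published stretch-rigidity preset for the inner mitochondrial
    membrane (murine heart), reused here for the erythrocyte-like model:
    n1=4, gzz0=0.008 dyn/nm, g00=0.0101 dyn/nm, betaz=1.6e4 um^-4,
    beta0=1.8e4 um^-4."""
    return RigidityTensorParams.from_quantities(
        g00="0.0101 dyn/nm",
        gzz0="0.008 dyn/nm",
        beta0="1.8e4 um^-4",
        betaz="1.6e4 um^-4",
        n1=4,
    )


@dataclass(frozen=True)
class DeformationState:
    """Axis deformations relative to the resting shape, in um.

    dr = a(t) - a(0) (equatorial), dz = c(t) - c(0) (polar).  Negative
    values (shrinkage) are allowed.
    """

    dr: float
    dz: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dr) and np.isfinite(self.dz)):
            raise ValueError("deformations must be finite")


@dataclass(frozen=True)
class MediumState:
    """Solute concentrations on both sides of the membrane plus temperature.

    Concentrations are per-species, in mM (numerically equal to mol/m^3);
    temperature in K.  Species lists inside/outside must match.
    """

    species: tuple[str, ...]
    c_in: np.ndarray  # mM
    c_out: np.ndarray  # mM
    T: float = 310.0

    def __post_init__(self) -> None:
        c_in = np.asarray(self.c_in, dtype=float)
        c_out = np.asarray(self.c_out, dtype=float)
        object.__setattr__(self, "c_in", c_in)
        object.__setattr__(self, "c_out", c_out)
        if len(self.species) != c_in.size or len(self.species) != c_out.size:
            raise ValueError("species list and concentration arrays must match")
        if np.any(c_in < 0) or np.any(c_out < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.T > 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_dict(
        cls, table: dict[str, tuple[float, float]], T: float = 310.0
    ) -> "MediumState":
        """``{"Na": (50, 1), "Cl": (50, 1)}`` -> sorted-species state (mM)."""
        names = tuple(sorted(table))
        c_in = np.array([table[s][0] for s in names], dtype=float)
        c_out = np.array([table[s][1] for s in names], dtype=float)
        return cls(species=names, c_in=c_in, c_out=c_out, T=T)

    def swap(self) -> "MediumState":
        """Mirror state with inside/outside concentrations exchanged."""
        return MediumState(self.species, self.c_out.copy(), self.c_in.copy(), self.T)


def rigidity_components(
    params: RigidityTensorParams, defo: DeformationState
) -> tuple[float, float]:
    """Rigidity tensor components (g0, gzz) at the given deformation, N/m.

    g0 = g00 (1 - b/(1+b)) = g00 / (1 + beta0 |dr|^n1), likewise gzz; both
    strictly positive and approaching zero asymptotically at large strain.
    """
    b_r = params.beta0 * abs(defo.dr) ** params.n1
    b_z = params.betaz * abs(defo.dz) ** params.n1
    return params.g00 / (1.0 + b_r), params.gzz0 / (1.0 + b_z)


def osmotic_pressure(medium: MediumState) -> float:
    """van 't Hoff osmotic pressure k_B N_A T sum_i (C_i_in - C_i_out), Pa.

    Positive when the interior is hypertonic (net inward water drive).
    mM is numerically mol/m^3, so no concentration conversion is needed.
    """
    return GAS_CONSTANT * medium.T * float(np.sum(medium.c_in - medium.c_out))


def stretching_pressure(
    params: RigidityTensorParams, defo: DeformationState, area: float
) -> float:
    """Inward pressure from membrane stretch, (2 g0 dr + gzz dz)/S, in Pa.

    *area* is the current membrane area in um^2; deformations in um.
    The conversion is explicit: g [N/m] * d [um -> m] / S [um^2 -> m^2].
    """
    if not area > 0:
        raise ValueError("area must be positive")
    g0, gzz = rigidity_components(params, defo)
    numerator = (2.0 * g0 * defo.dr + gzz * defo.dz) * 1e-6  # N
    return numerator / (area * 1e-12)  # Pa
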