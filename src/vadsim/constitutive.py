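"""Finite-strain constitutive models for childbirth soft-tissue mechanics.

Four material laws cover the tissues of the pelvic floor and the fetal head:

* the Martins transversely isotropic hyperelastic model for the pelvic floor
  muscles (exponential isotropic matrix, exponential passive fiber term, an
  optional active fiber term gated by an activation level ``theta``, and a
  quadratic volumetric penalty),
* a Neo-Hookean model for the external anal sphincter,
* small-strain linear elasticity for the perineal body / bulbospongiosus and
  for the fetal head,
* plus a central-difference stress oracle used to verify every analytic
  stress push-forward against its strain-energy function.

Units are MPa for stresses/energy densities throughout (so MPa * mm^2 = N
downstream).  Deformation is described by the deformation gradient ``F``;
isochoric invariants (``Ibar1``, ``lambdabar_f``) have the volume change
removed via ``J = det F``.

Cauchy ("true") stress is the stress measure everywhere: principal-stress
outputs of the delivery model are eigenvalues of these tensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidDeformationError,
    ModeError,
    NormalizationError,
    OracleDomainError,
)

__all__ = [
    "DeformationState",
    "MartinsParams",
    "NeoHookeanParams",
    "LinearElasticParams",
    "compute_invariants",
    "martins_energy",
    "martins_energy_parts",
    "neo_hookean_energy",
    "martins_cauchy_stress",
    "neo_hookean_stress",
    "linear_elastic_stress",
    "numerical_stress_oracle",
    "uniaxial_isochoric_F",
    "martins_uniaxial_stress",
    "martins_uniaxial_parts",
    "neo_hookean_uniaxial_stress",
]

_EYE = np.eye(3)

#: Tag accepted by the stress routines to request the incompressible
#: uniaxial convenience mode (pressure determined by traction-free
#: lateral faces).
TRACTION_FREE_LATERAL = "from-traction-free-lateral"


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient, reference fiber direction and derived invariants.

    Attributes
    ----------
    F : (3, 3) ndarray
        Deformation gradient, ``det F > 0``.
    N : (3,) ndarray
        Unit fiber direction in the reference configuration.
    J : float
        Volume ratio ``det F``.
    Ibar1 : float
        First invariant of the isochoric right Cauchy-Green tensor,
        ``J**(-2/3) * tr(F^T F)``.
    lambdabar_f : float
        Isochoric fiber stretch ``J**(-1/3) * |F N|``.
    """

    F: np.ndarray
    N: np.ndarray
    J: float
    Ibar1: float
    lambdabar_f: float


def compute_invariants(F, N) -> DeformationState:
    """Build a :class:`DeformationState` from ``F`` and a unit fiber direction.

    Raises
    ------
    InvalidDeformationError
        If ``F`` is not 3x3 or ``det F <= 0``.
    NormalizationError
        If ``|N|`` deviates from 1 by more than 1e-8.
    """
    F = np.asarray(F, dtype=float)
    N = np.asarray(N, dtype=float)
    if F.shape != (3, 3):
        raise InvalidDeformationError(f"F must be 3x3, got shape {F.shape}")
    J = float(np.linalg.det(F))
    if not J > 0.0:
        raise InvalidDeformationError(f"det F = {J} must be positive")
    if N.shape != (3,):
        raise NormalizationError(f"N must be a 3-vector, got shape {N.shape}")
    norm = float(np.linalg.norm(N))
    if abs(norm - 1.0) > 1e-8:
        raise NormalizationError(f"|N| = {norm} is not 1 within 1e-8")
    Ibar1 = float(J ** (-2.0 / 3.0) * np.trace(F.T @ F))
    lambdabar = float(J ** (-1.0 / 3.0) * np.linalg.norm(F @ N))
    return DeformationState(F=F, N=N, J=J, Ibar1=Ibar1, lambdabar_f=lambdabar)


@dataclass(frozen=True)
class MartinsParams:
    """Constants of the Martins transversely isotropic model.

    Defaults are the pelvic-floor values of the published material table.
    ``c``/``b`` govern the isotropic matrix, ``A``/``a`` the passive fiber
    response, ``T0M`` (MPa) the maximum active tension scaled by the
    activation level ``theta`` in [0, 1], and ``D`` (1/MPa) the volumetric
    penalty: ``U_J = (1/D) (J - 1)**2``.

    ``c`` and ``A`` may be zero so that the matrix or fiber contribution can
    be switched off in isolation (pure-fiber or matrix-only materials are
    used by the relaxation drivers and tests).

    The source gives no value for ``D`` (incompressibility was enforced by a
    mixed formulation there); the default ``D = 0.1`` gives a volumetric
    stiffness ``1/D = 10`` MPa, more than 200x the matrix shear modulus
    ``2cb``, i.e. near-incompressible.  ``T0M`` likewise has no published
    value because ``theta = 0`` (passive muscle) throughout; the default is
    a placeholder that only matters when activation is switched on.
    """

    c: float = 0.0185
    b: float = 1.1730
    A: float = 0.0280
    a: float = 0.6215
    T0M: float = 0.682
    theta: float = 0.0
    D: float = 0.1

    def __post_init__(self):
        if self.c < 0 or self.A < 0:
            raise ValueError("c and A must be non-negative")
        if self.b <= 0 or self.a <= 0 or self.D <= 0:
            raise ValueError("b, a and D must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.T0M < 0:
            raise ValueError("T0M must be non-negative")


@dataclass(frozen=True)
class NeoHookeanParams:
    """Neo-Hookean constants: ``U = c10 (Ibar1 - 3) + (1/D)(J-1)^2``."""

    c10: float = 0.1
    D: float = 0.1

    def __post_init__(self):
        if self.c10 <= 0:
            raise ValueError("c10 must be positive")
        if self.D <= 0:
            raise ValueError("D must be positive")


@dataclass(frozen=True)
class LinearElasticParams:
    """Young's modulus with its unit of record, and Poisson's ratio."""

    E: float
    nu: float
    unit: str = "MPa"

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (-1, 0.5)")
        if self.unit not in ("MPa", "kPa"):
            raise ValueError("unit must be 'MPa' or 'kPa'")

    @property
    def E_MPa(self) -> float:
        return self.E * (1e-3 if self.unit == "kPa" else 1.0)


# ---------------------------------------------------------------------------
# strain-energy densities
# ---------------------------------------------------------------------------

def martins_energy_parts(state: DeformationState, p: MartinsParams) -> dict:
    """Return the four energy contributions of the Martins model (MPa).

    ``U_m``: isotropic matrix, ``c (exp(b (Ibar1 - 3)) - 1)``.
    ``U_fPE``: passive fiber, ``A (exp(a (lambdabar_f - 1)^2) - 1)``.
    ``U_fSE``: active fiber, closed form of the activation integral,
    ``theta T0M ((lf - 1) - 4/3 (lf - 1)^3)``.
    ``U_J``: volumetric penalty ``(1/D) (J - 1)^2``.
    """
    x = state.lambdabar_f - 1.0
    U_m = p.c * math.expm1(p.b * (state.Ibar1 - 3.0))
    U_fPE = p.A * math.expm1(p.a * x * x)
    U_fSE = p.theta * p.T0M * (x - (4.0 / 3.0) * x ** 3)
    U_J = (1.0 / p.D) * (state.J - 1.0) ** 2
    return {"U_m": U_m, "U_fPE": U_fPE, "U_fSE": U_fSE, "U_J": U_J}


def martins_energy(state: DeformationState, p: MartinsParams) -> float:
    """Total Martins strain-energy density (MPa)."""
    return sum(martins_energy_parts(state, p).values())


def neo_hookean_energy(state: DeformationState, p: NeoHookeanParams) -> float:
    """Neo-Hookean strain-energy density with volumetric penalty (MPa)."""
    return p.c10 * (state.Ibar1 - 3.0) + (1.0 / p.D) * (state.J - 1.0) ** 2


# ---------------------------------------------------------------------------
# analytic Cauchy stresses
# ---------------------------------------------------------------------------

def _martins_dU(state: DeformationState, p: MartinsParams):
    """(dU/dIbar1, dU/dlambdabar_f, dU/dJ) of the Martins energy."""
    x = state.lambdabar_f - 1.0
    dU_dI1 = p.c * p.b * math.exp(p.b * (state.Ibar1 - 3.0))
    dU_dlf = 2.0 * p.A * p.a * x * math.exp(p.a * x * x)
    dU_dlf += p.theta * p.T0M * (1.0 - 4.0 * x * x)
    dU_dJ = (2.0 / p.D) * (state.J - 1.0)
    return dU_dI1, dU_dlf, dU_dJ


def _isochoric_cauchy(state, dU_dI1, dU_dlf):
    """Push-forward of the isochoric energy derivatives to Cauchy stress.

    sigma_iso = (2 dU/dIbar1 / J) dev(Bbar)
              + (dU/dlf * lf / J) (m x m - I/3)
    with Bbar the isochoric left Cauchy-Green tensor and m the unit spatial
    fiber direction.  Both terms are deviatoric by construction.
    """
    J = state.J
    Bbar = J ** (-2.0 / 3.0) * (state.F @ state.F.T)
    sigma = (2.0 * dU_dI1 / J) * (Bbar - (state.Ibar1 / 3.0) * _EYE)
    if dU_dlf != 0.0:
        v = state.F @ state.N
        m = v / np.linalg.norm(v)
        sigma = sigma + (dU_dlf * state.lambdabar_f / J) * (
            np.outer(m, m) - _EYE / 3.0
        )
    return sigma


def _check_uniaxial_fiber_aligned(state: DeformationState, tol=1e-9):
    """Validate F = diag(lam, lam^-1/2, lam^-1/2) with fiber along axis 1."""
    F = state.F
    lam = F[0, 0]
    expected = np.diag([lam, lam ** -0.5, lam ** -0.5])
    if not np.allclose(F, expected, rtol=0.0, atol=tol * max(1.0, lam)):
        raise ModeError(
            "traction-free-lateral mode requires an incompressible uniaxial "
            "F = diag(lam, lam^-1/2, lam^-1/2)"
        )
    if abs(abs(state.N[0]) - 1.0) > 1e-8:
        raise ModeError("traction-free-lateral mode requires the fiber along axis 1")


def _cauchy_stress(state, p, dU_dI1, dU_dlf, dU_dJ, pressure):
    if pressure is None:
        return _isochoric_cauchy(state, dU_dI1, dU_dlf) + dU_dJ * _EYE
    if isinstance(pressure, str):
        if pressure != TRACTION_FREE_LATERAL:
            raise ModeError(f"unknown pressure mode {pressure!r}")
        _check_uniaxial_fiber_aligned(state)
        sigma = _isochoric_cauchy(state, dU_dI1, dU_dlf)
        sigma = sigma - sigma[1, 1] * _EYE
        # lateral faces are traction free by construction; zero them exactly
        sigma[1, 1] = 0.0
        sigma[2, 2] = 0.0
        return sigma
    return _isochoric_cauchy(state, dU_dI1, dU_dlf) - float(pressure) * _EYE


def martins_cauchy_stress(state: DeformationState, p: MartinsParams, pressure=None):
    """Cauchy stress tensor (MPa) of the Martins model.

    Parameters
    ----------
    pressure
        ``None`` uses the volumetric penalty as the pressure term
        (compressible evaluation).  The string
        ``"from-traction-free-lateral"`` selects the incompressible uniaxial
        convenience mode: ``F`` must be ``diag(lam, lam^-1/2, lam^-1/2)``
        with the fiber along axis 1, the hydrostatic pressure is determined
        by the traction-free lateral condition, and the returned tensor has
        exactly zero lateral components.  A float subtracts that hydrostatic
        pressure explicitly.
    """
    dU_dI1, dU_dlf, dU_dJ = _martins_dU(state, p)
    return _cauchy_stress(state, p, dU_dI1, dU_dlf, dU_dJ, pressure)


def neo_hookean_stress(state: DeformationState, p: NeoHookeanParams, pressure=None):
    """Cauchy stress tensor (MPa) of the Neo-Hookean model.

    Same pressure conventions as :func:`martins_cauchy_stress`.
    """
    dU_dJ = (2.0 / p.D) * (state.J - 1.0)
    return _cauchy_stress(state, p, p.c10, 0.0, dU_dJ, pressure)


def linear_elastic_stress(engineering_strain: float, p: LinearElasticParams) -> float:
    """Uniaxial small-strain law ``sigma = E * eps`` (same unit family as E).

    The ring model applies this with ``eps = lambda - 1``; the linear law is
    kept even at large stretch, mirroring the constitutive simplicity chosen
    for the perineal body and bulbospongiosus.
    """
    if engineering_strain <= -1.0:
        raise ValueError("engineering strain must exceed -1")
    return p.E * engineering_strain


# ---------------------------------------------------------------------------
# verification oracle
# ---------------------------------------------------------------------------

def numerical_stress_oracle(energy_fn, state: DeformationState, step: float = 1e-6):
    """Cauchy stress by central-difference differentiation of an energy.

    Differentiates ``energy_fn(DeformationState)`` component-wise in ``F`` to
    obtain the first Piola-Kirchhoff stress ``P = dU/dF`` (truncation error
    O(step^2)), then pushes forward: ``sigma = P F^T / J``, symmetrized.

    Intended as the independent check on every analytic stress in this
    module; it is deliberately slow and simple.
    """
    if not 1e-8 <= step <= 1e-4:
        raise ValueError("step must lie in [1e-8, 1e-4]")
    F = state.F
    P = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            Fp = F.copy()
            Fm = F.copy()
            Fp[i, j] += step
            Fm[i, j] -= step
            try:
                up = energy_fn(compute_invariants(Fp, state.N))
                um = energy_fn(compute_invariants(Fm, state.N))
            except InvalidDeformationError as exc:
                raise OracleDomainError(
                    f"stencil left the deformation domain at F[{i},{j}]"
                ) from exc
            if not (math.isfinite(up) and math.isfinite(um)):
                raise OracleDomainError("non-finite energy in the stencil")
            P[i, j] = (up - um) / (2.0 * step)
    sigma = (P @ F.T) / state.J
    return 0.5 * (sigma + sigma.T)


# ---------------------------------------------------------------------------
# incompressible uniaxial helpers (the 1D kinematics used by the ring model)
# ---------------------------------------------------------------------------

def uniaxial_isochoric_F(lam: float) -> np.ndarray:
    """Incompressible uniaxial deformation gradient along axis 1."""
    if lam <= 0:
        raise InvalidDeformationError("stretch must be positive")
    return np.diag([lam, lam ** -0.5, lam ** -0.5])


def martins_uniaxial_parts(lam: float, p: MartinsParams) -> tuple[float, float]:
    """(matrix, fiber) axial Cauchy stresses for incompressible uniaxial
    stretch ``lam`` along the fiber, lateral faces traction free.

    Closed forms (J = 1, Ibar1 = lam^2 + 2/lam, lambdabar_f = lam):

    * matrix: ``2 c b exp(b (Ibar1 - 3)) (lam^2 - 1/lam)``
    * fiber:  ``dU_f/dlf * lam``

    The split feeds the viscoelastic update, where matrix and fiber Maxwell
    branch sets relax their respective contributions independently.
    """
    if lam <= 0:
        raise InvalidDeformationError("stretch must be positive")
    I1 = lam * lam + 2.0 / lam
    x = lam - 1.0
    dU_dI1 = p.c * p.b * math.exp(p.b * (I1 - 3.0))
    sigma_m = 2.0 * dU_dI1 * (lam * lam - 1.0 / lam)
    dU_dlf = 2.0 * p.A * p.a * x * math.exp(p.a * x * x)
    dU_dlf += p.theta * p.T0M * (1.0 - 4.0 * x * x)
    sigma_f = dU_dlf * lam
    return sigma_m, sigma_f


def martins_uniaxial_stress(lam: float, p: MartinsParams) -> float:
    """Axial Cauchy stress for incompressible uniaxial stretch along the fiber."""
    sigma_m, sigma_f = martins_uniaxial_parts(lam, p)
    return sigma_m + sigma_f


def neo_hookean_uniaxial_stress(lam: float, p: NeoHookeanParams) -> float:
    """Closed-form incompressible Neo-Hookean uniaxial stress 2 c10 (lam^2 - 1/lam)."""
    if lam <= 0:
        raise InvalidDeformationError("stretch must be positive")
    return 2.0 * p.c10 * (lam * lam - 1.0 / lam)
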