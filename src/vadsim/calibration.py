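"""Fetal-head elastic calibration from plate-compression curves.

Replicates the calibration workflow used to characterize the fetal head:
an antero-posterior compression between two rigid plates to 5 mm total
deflection, with the Young's modulus optimized until the model
force-deflection curve matches the experimental one (Poisson's ratio held
fixed at 0.25).

With no 3D head mesh in this package the forward model is two-sided
Hertzian contact on an elastic sphere: each plate indents ``delta / 2``, so

    F = (4/3) * E* * sqrt(R) * (delta / 2)^(3/2),   E* = E / (1 - nu^2)

in mm-MPa units (force in N).  This is adequate for exercising the
least-squares recovery loop; it is not a replica of the published
finite-element curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError, OptimizationError

__all__ = [
    "CompressionCurve",
    "CalibrationResult",
    "plate_compression_force",
    "calibrate_young_modulus",
    "DEFAULT_HEAD_RADIUS_MM",
    "DEFAULT_POISSON",
    "MAX_DEFLECTION_MM",
]

#: Effective contact radius, order of a term head's biparietal half-axis (mm).
DEFAULT_HEAD_RADIUS_MM = 45.0
#: Poisson's ratio of the head, held fixed during calibration.
DEFAULT_POISSON = 0.25
#: Total antero-posterior plate displacement of the test (mm).
MAX_DEFLECTION_MM = 5.0


@dataclass(frozen=True)
class CompressionCurve:
    """Force-deflection samples of a plate-compression test."""

    deflection_mm: np.ndarray
    force_N: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.deflection_mm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        object.__setattr__(self, "deflection_mm", d)
        object.__setattr__(self, "force_N", f)
        if d.ndim != 1 or d.shape != f.shape:
            raise DataError("deflection and force must be matching 1-D arrays")
        if len(d) and (np.any(d < 0) or np.any(np.diff(d) <= 0)):
            raise DataError("deflections must be non-negative and strictly increasing")
        if np.any(f < 0):
            raise DataError("forces must be non-negative")

    def __len__(self):
        return len(self.deflection_mm)


def plate_compression_force(E, nu=DEFAULT_POISSON, R=DEFAULT_HEAD_RADIUS_MM,
                            delta=MAX_DEFLECTION_MM):
    """Hertzian two-plate compression force (N) at total deflection ``delta``.

    ``E`` in MPa, lengths in mm.  Force is linear in ``E``.  Vectorized over
    ``delta``.
    """
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise ValueError("deflection must be non-negative")
    if np.any(delta_arr >= R):
        raise ValueError(
            "deflection must stay below the contact radius for the Hertz "
            "model to be meaningful"
        )
    if E <= 0:
        raise ValueError("E must be positive")
    e_star = E / (1.0 - nu * nu)
    F = (4.0 / 3.0) * e_star * np.sqrt(R) * (delta_arr / 2.0) ** 1.5
    return float(F) if np.ndim(delta) == 0 else F


@dataclass(frozen=True)
class CalibrationResult:
    """Recovered modulus with least-squares diagnostics."""

    E_MPa: float
    residual_norm: float
    relative_std_error: float
    n_points: int
    nu: float
    R_mm: float


def calibrate_young_modulus(curve: CompressionCurve, nu=DEFAULT_POISSON,
                            R=DEFAULT_HEAD_RADIUS_MM,
                            E0: float = 1.0) -> CalibrationResult:
    """Least-squares recovery of E (MPa) from a compression curve.

    Minimizes ``sum (F_model(E) - F_data)^2`` with ``nu`` and ``R`` fixed,
    starting from ``E0``.  Reports the residual norm and the relative
    standard error of the estimate (from the Gauss-Newton approximation of
    the covariance).
    """
    if len(curve) < 3:
        raise DataError("calibration needs at least 3 curve points")
    d = curve.deflection_mm
    f = curve.force_N

    def residuals(x):
        return plate_compression_force(x[0], nu=nu, R=R, delta=d) - f

    res = least_squares(residuals, x0=[E0], bounds=([1e-9], [np.inf]))
    if not res.success:
        raise OptimizationError(
            f"modulus calibration did not converge: {res.message}", trace=res
        )
    E_hat = float(res.x[0])
    resid = res.fun
    dof = max(len(curve) - 1, 1)
    s2 = float(resid @ resid) / dof
    jac = plate_compression_force(1.0, nu=nu, R=R, delta=d)  # dF/dE (linear in E)
    var_E = s2 / float(jac @ jac)
    return CalibrationResult(
        E_MPa=E_hat,
        residual_norm=float(np.linalg.norm(resid)),
        relative_std_error=float(np.sqrt(var_E) / E_hat),
        n_points=len(curve),
        nu=nu,
        R_mm=R,
    )
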