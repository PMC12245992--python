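"""Reduced-order birth-canal model: two hiatal rings distended by a head.

The full 3D contact problem is reduced to two material rings — the levator
hiatus (pelvic floor muscle, Martins + viscoelastic) and the urogenital
hiatus (perineum, linear elastic) — kinematically distended by an
axisymmetric, quasi-rigid fetal-head profile descending along the canal
axis per the pull/rest protocol.  The head is treated as quasi-rigid here
because its modulus (1.1 MPa) is large compared with the tissue moduli;
head compliance is exercised separately by the compression-calibration
module.

At cup displacement ``d`` the head apex sits at axial station ``d``; a ring
at station ``z`` sees the head cross-section at head coordinate
``u = d - z`` (measured from the apex), so its hoop stretch is

    lambda = max(1, 2 pi rho(u) / C0)

purely kinematic, hence identical across material configurations.  During
the engagement phase the ring stretch ramps linearly from 1 to an
engagement pre-stretch ``lambda_eng`` so that viscoelastic history exists
before the first pull; during the maneuver the kinematic stretch takes over
once it exceeds that floor.

The ring stress state is incompressible uniaxial along the hoop direction
(the dominant hiatal loading mode), with the muscle fibers circumferential
on the levator ring.  The cup traction force is a membrane-tension
projection: ``F_y = sum_rings sigma1 * A_ring * sin(alpha)`` with ``alpha``
the local head-profile slope angle — absolute newton values are an
order-of-magnitude effective-area model; only cross-scenario orderings are
meaningful.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .constitutive import LinearElasticParams, MartinsParams, martins_uniaxial_parts
from .errors import ConfigurationError, GeometryError
from .protocol import DisplacementHistory, PullProtocol, build_displacement_history
from .viscoelastic import (
    FIBER_BRANCHES,
    MATRIX_BRANCHES,
    ViscoState,
    update_overstress,
)

__all__ = [
    "HeadGeometry",
    "HiatusRing",
    "PfmMaterial",
    "PerineumMaterial",
    "SimulationResult",
    "default_materials",
    "ring_stretch_at",
    "simulate_vad",
    "cup_force",
]

#: Material tags understood by :func:`simulate_vad`.
PFM_MATERIAL = "pfm-martins-viscoelastic"
PERINEUM_MATERIAL = "perineum-linear-elastic"


@dataclass(frozen=True)
class HeadGeometry:
    """Axisymmetric fetal-head profile sampled on an axial grid.

    ``s`` runs from 0 at the leading pole (apex) to the axial length ``L``;
    ``rho(s)`` is the profile radius in mm.  Outside ``[0, L]`` the radius
    is zero (no head section).
    """

    s: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "rho", rho)
        if s.ndim != 1 or s.shape != rho.shape or len(s) < 3:
            raise GeometryError("profile needs matching 1-D grids of >= 3 samples")
        if np.any(np.diff(s) <= 0):
            raise GeometryError("axial grid must be strictly increasing")
        if np.any(rho < 0) or not np.all(np.isfinite(rho)):
            raise GeometryError("profile radii must be finite and non-negative")

    @classmethod
    def spheroid(cls, radius: float = 47.5, length: float | None = None,
                 n: int = 1001) -> "HeadGeometry":
        """Prolate-spheroid profile: equatorial radius ``radius`` (mm) and
        axial length ``length`` (default sphere, ``2 * radius``).

        ``n`` is forced odd so the equator is an exact grid node and the
        maximum radius is attained exactly.
        """
        if radius <= 0:
            raise GeometryError("radius must be positive")
        L = 2.0 * radius if length is None else float(length)
        if L <= 0:
            raise GeometryError("length must be positive")
        if n % 2 == 0:
            n += 1
        s = np.linspace(0.0, L, n)
        half = L / 2.0
        rho = radius * np.sqrt(np.clip(1.0 - ((s - half) / half) ** 2, 0.0, None))
        return cls(s=s, rho=rho)

    @property
    def R(self) -> float:
        """Maximum profile radius (mm)."""
        return float(self.rho.max())

    @property
    def L(self) -> float:
        """Axial length (mm)."""
        return float(self.s[-1] - self.s[0])

    @cached_property
    def _slope(self) -> np.ndarray:
        return np.gradient(self.rho, self.s)

    def radius_at(self, u):
        """Profile radius at head coordinate ``u`` (0 outside the head)."""
        return np.interp(u, self.s, self.rho, left=0.0, right=0.0)

    def sin_slope_at(self, u):
        """sin of the local profile slope angle, |rho'| / sqrt(1 + rho'^2)."""
        dr = np.abs(np.interp(u, self.s, self._slope, left=0.0, right=0.0))
        return dr / np.sqrt(1.0 + dr * dr)

    def signature(self) -> str:
        h = hashlib.sha256()
        h.update(self.s.tobytes())
        h.update(self.rho.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class HiatusRing:
    """One material ring standing in for a stress-evaluation path.

    Attributes
    ----------
    name : str
        ``"levator"`` or ``"urogenital"``.
    C0 : float
        Undeformed circumference (mm).
    z_station : float
        Axial station of the ring plane on the canal axis (mm, measured in
        cup-displacement coordinates: the head apex reaches the ring when
        ``d = z_station``).
    material : str
        Material tag, one of :data:`PFM_MATERIAL` / :data:`PERINEUM_MATERIAL`.
    lambda_eng : float
        Engagement pre-stretch reached at the end of the engagement ramp.
    area_mm2 : float or None
        Effective cross-section area for the traction-force projection.
    """

    name: str
    C0: float
    z_station: float
    material: str = PFM_MATERIAL
    lambda_eng: float = 1.3
    area_mm2: float | None = None

    def __post_init__(self):
        if self.C0 <= 0:
            raise ConfigurationError("ring circumference C0 must be positive")
        if self.lambda_eng < 1.0:
            raise ConfigurationError("engagement pre-stretch must be >= 1")
        if self.material not in (PFM_MATERIAL, PERINEUM_MATERIAL):
            raise ConfigurationError(f"unknown ring material tag {self.material!r}")


@dataclass(frozen=True)
class PfmMaterial:
    """Martins hyperelastic parameters plus the two Maxwell branch sets."""

    params: MartinsParams = MartinsParams()
    matrix_branches: tuple = MATRIX_BRANCHES
    fiber_branches: tuple = FIBER_BRANCHES


@dataclass(frozen=True)
class PerineumMaterial:
    """Linear elastic ring material (perineal body / bulbospongiosus)."""

    params: LinearElasticParams = LinearElasticParams(E=23.8, nu=0.49, unit="kPa")


def default_materials() -> dict:
    """Material map with the published tissue parameters."""
    return {
        PFM_MATERIAL: PfmMaterial(),
        PERINEUM_MATERIAL: PerineumMaterial(),
    }


def ring_stretch_at(d, head: HeadGeometry, ring: HiatusRing):
    """Kinematic hoop stretch of a ring at cup displacement ``d`` (mm).

    ``lambda = max(1, 2 pi rho(d - z_station) / C0)``; 1 when no head
    section intersects the ring plane.  Vectorized over ``d``.
    """
    if not np.isfinite(ring.z_station) or ring.z_station < 0:
        raise GeometryError(
            f"ring station {ring.z_station} lies outside the model axis"
        )
    u = np.asarray(d, dtype=float) - ring.z_station
    lam = 2.0 * np.pi * head.radius_at(u) / ring.C0
    lam = np.maximum(1.0, lam)
    return float(lam) if np.ndim(d) == 0 else lam


@dataclass
class SimulationResult:
    """Time series of one delivery scenario.

    ``stretch`` and ``sigma1`` map ring name to arrays aligned with
    ``time``; ``force`` is the y-direction cup traction (N).
    """

    time: np.ndarray
    displacement: np.ndarray
    phase: np.ndarray
    stretch: dict
    sigma1: dict
    force: np.ndarray
    protocol: PullProtocol
    anatomy_signature: str = ""

    def phase_blocks(self):
        return DisplacementHistory(
            time=self.time, displacement=self.displacement, phase=self.phase
        ).phase_blocks()

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (time sample, ring)."""
        frames = []
        for ring_name in self.stretch:
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "phase": self.phase.astype(str),
                        "displacement_mm": self.displacement,
                        "ring": ring_name,
                        "stretch": self.stretch[ring_name],
                        "sigma1_MPa": self.sigma1[ring_name],
                        "force_N": self.force,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _ring_stretch_series(hist: DisplacementHistory, protocol: PullProtocol,
                         head: HeadGeometry, ring: HiatusRing) -> np.ndarray:
    """Stretch history: engagement ramp to lambda_eng, then kinematics."""
    eng = hist.phase == "engagement"
    lam_kin = ring_stretch_at(hist.displacement, head, ring)
    lam = np.where(
        eng,
        1.0 + (ring.lambda_eng - 1.0) * hist.time / protocol.engagement_duration,
        np.maximum(ring.lambda_eng, lam_kin),
    )
    return lam


def _pfm_stress_series(lam: np.ndarray, time: np.ndarray, mat: PfmMaterial):
    """March the viscoelastic recurrence along a stretch history.

    Matrix and fiber equilibrium contributions relax through their own
    branch sets; the returned series is total (equilibrium + overstress)
    axial Cauchy stress.
    """
    n = len(lam)
    sigma = np.empty(n)
    state_m = ViscoState.zeros(mat.matrix_branches)
    state_f = ViscoState.zeros(mat.fiber_branches)
    S_m_prev = S_f_prev = 0.0
    H_m = H_f = 0.0
    for i in range(n):
        S_m, S_f = martins_uniaxial_parts(lam[i], mat.params)
        dt = time[i] - time[i - 1] if i > 0 else 0.0
        state_m, H_m = update_overstress(state_m, S_m - S_m_prev, dt,
                                         mat.matrix_branches)
        state_f, H_f = update_overstress(state_f, S_f - S_f_prev, dt,
                                         mat.fiber_branches)
        sigma[i] = S_m + S_f + H_m + H_f
        S_m_prev, S_f_prev = S_m, S_f
    return sigma


def cup_force(result: SimulationResult, rings, head: HeadGeometry) -> np.ndarray:
    """Y-direction cup traction force series (N).

    Membrane-tension projection: each ring in kinematic contact contributes
    ``sigma1 * area * sin(alpha)`` with ``alpha`` the head-profile slope
    angle at the ring plane; zero when no ring is in contact.
    """
    F = np.zeros_like(result.displacement, dtype=float)
    for ring in rings:
        if ring.area_mm2 is None:
            raise ConfigurationError(
                f"ring {ring.name!r} has no effective area configured"
            )
        u = result.displacement - ring.z_station
        contact = (u > 0.0) & (u < head.L) & (head.radius_at(u) > 0.0)
        sin_a = head.sin_slope_at(u)
        sigma = np.maximum(result.sigma1[ring.name], 0.0)
        F += np.where(contact, sigma * ring.area_mm2 * sin_a, 0.0)
    return F


def simulate_vad(protocol: PullProtocol, head: HeadGeometry, rings,
                 materials=None) -> SimulationResult:
    """Run one delivery scenario and return its time series.

    At each sample the ring stretch follows the engagement ramp / head
    kinematics, the ring material is evaluated (Martins + viscoelastic
    update for the pelvic-floor ring, linear elastic for the perineal
    ring), and the cup traction force is projected.  The run is fully
    deterministic.
    """
    materials = materials if materials is not None else default_materials()
    hist = build_displacement_history(protocol)
    stretch: dict = {}
    sigma1: dict = {}
    for ring in rings:
        lam = _ring_stretch_series(hist, protocol, head, ring)
        lam_kin = ring_stretch_at(hist.displacement, head, ring)
        if np.max(lam_kin) <= 1.0:
            warnings.warn(
                f"head never stretches ring {ring.name!r}; run is valid with "
                "lambda = engagement ramp only",
                stacklevel=2,
            )
        mat = materials[ring.material]
        if isinstance(mat, PerineumMaterial):
            sig = mat.params.E_MPa * (lam - 1.0)
        else:
            sig = _pfm_stress_series(lam, hist.time, mat)
        stretch[ring.name] = lam
        sigma1[ring.name] = sig

    sig_parts = [head.signature()] + [
        f"{r.name}:{r.C0:.9g}:{r.z_station:.9g}:{r.lambda_eng:.9g}" for r in rings
    ]
    result = SimulationResult(
        time=hist.time,
        displacement=hist.displacement,
        phase=hist.phase,
        stretch=stretch,
        sigma1=sigma1,
        force=np.zeros_like(hist.time),
        protocol=protocol,
        anatomy_signature=hashlib.sha256("|".join(sig_parts).encode()).hexdigest()[:16],
    )
    result.force = cup_force(result, rings, head)
    return result
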