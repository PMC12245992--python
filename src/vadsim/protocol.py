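"""Cup-displacement loading protocols for vacuum-assisted delivery.

A delivery maneuver is an engagement phase (the head settles into the pelvic
floor over hours of stalled labor, cup displacement held at zero) followed
by ``n`` pulls: each pull ramps the vacuum cup down by an equal share of the
total descent over one contraction, and consecutive pulls are separated by
rest intervals during which the cup position is held.  No rest follows the
final pull (delivery is complete when it ends).

The clinical scenario grid crosses contraction durations {60, 90} s with
rest intervals {60, 180} s and pull counts {2, 3, 4} — twelve scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PullProtocol",
    "DisplacementHistory",
    "Scenario",
    "build_scenarios",
    "build_displacement_history",
    "DEFAULT_CONTRACTIONS",
    "DEFAULT_RESTS",
    "DEFAULT_PULLS",
]

DEFAULT_CONTRACTIONS = (60.0, 90.0)
DEFAULT_RESTS = (60.0, 180.0)
DEFAULT_PULLS = (2, 3, 4)


class Scenario(NamedTuple):
    contraction_s: float
    rest_s: float
    n_pulls: int

    @property
    def label(self) -> str:
        return f"c{self.contraction_s:g}_r{self.rest_s:g}_p{self.n_pulls}"


@dataclass(frozen=True)
class PullProtocol:
    """Timing and descent parameters of one delivery scenario.

    Attributes
    ----------
    contraction_duration, rest_duration : float
        Pull and rest durations (s).
    n_pulls : int
        Number of traction pulls (>= 1).
    engagement_duration : float
        Pre-maneuver engagement phase (s); default three hours of prolonged
        labor.
    total_descent : float
        Total vertical cup displacement (mm), split equally across pulls.
    dt : float
        Sample step during pulls and rests (s).
    engagement_dt : float
        Coarser sample step during engagement (s).
    """

    contraction_duration: float
    rest_duration: float
    n_pulls: int
    engagement_duration: float = 10800.0
    total_descent: float = 100.0
    dt: float = 1.0
    engagement_dt: float = 60.0

    def __post_init__(self):
        for name in ("contraction_duration", "rest_duration",
                     "engagement_duration", "total_descent", "dt",
                     "engagement_dt"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if int(self.n_pulls) != self.n_pulls or self.n_pulls < 1:
            raise ConfigurationError("n_pulls must be an integer >= 1")

    @property
    def maneuver_duration(self) -> float:
        """n * contraction + (n - 1) * rest, in seconds."""
        n = self.n_pulls
        return n * self.contraction_duration + (n - 1) * self.rest_duration

    @property
    def pull_increment(self) -> float:
        """Descent per pull, mm."""
        return self.total_descent / self.n_pulls


@dataclass
class DisplacementHistory:
    """Sampled cup displacement with per-sample phase labels.

    Samples at phase boundaries carry the label of the phase that ends
    there; the ``t = 0`` sample is labeled ``engagement``.  Displacement is
    non-decreasing, constant within every rest, and ends at the protocol's
    total descent.
    """

    time: np.ndarray
    displacement: np.ndarray
    phase: np.ndarray

    def phase_blocks(self):
        """Yield ``(label, slice)`` for each contiguous run of phase labels."""
        labels = self.phase
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                yield str(labels[start]), slice(start, i)
                start = i


def build_scenarios(
    contractions: Iterable[float] = DEFAULT_CONTRACTIONS,
    rests: Iterable[float] = DEFAULT_RESTS,
    pulls: Iterable[int] = DEFAULT_PULLS,
) -> pd.DataFrame:
    """Cross the timing sets into a scenario table.

    Duplicate inputs are deduplicated (set semantics); rows are ordered
    lexicographically by (contraction, rest, pulls).  Returns a DataFrame
    with columns ``contraction_s, rest_s, n_pulls, label``.
    """
    cs = sorted({float(c) for c in contractions})
    rs = sorted({float(r) for r in rests})
    ps = sorted({int(p) for p in pulls})
    if not cs or not rs or not ps:
        raise ConfigurationError("scenario sets must be non-empty")
    rows = [Scenario(c, r, p) for c in cs for r in rs for p in ps]
    return pd.DataFrame(
        {
            "contraction_s": [s.contraction_s for s in rows],
            "rest_s": [s.rest_s for s in rows],
            "n_pulls": [s.n_pulls for s in rows],
            "label": [s.label for s in rows],
        }
    )


def _phase_samples(t0, duration, dt):
    """Local sample times (t0, t0+duration] at step dt, endpoint exact."""
    interior = np.arange(dt, duration, dt)
    # guard against float drift producing a near-duplicate of the endpoint
    if len(interior) and duration - interior[-1] < 1e-9 * duration:
        interior = interior[:-1]
    return np.concatenate([t0 + interior, [t0 + duration]])


def build_displacement_history(p: PullProtocol) -> DisplacementHistory:
    """Sample the cup displacement d(t) for one protocol.

    The engagement phase holds ``d = 0`` (the head's pre-load is a stretch
    ramp handled by the canal model); each pull is a linear ramp of
    ``total_descent / n_pulls`` mm over one contraction; rests hold the
    position; no rest after the final pull.
    """
    times = [np.array([0.0])]
    disps = [np.array([0.0])]
    phases = [np.array(["engagement"], dtype=object)]

    t = _phase_samples(0.0, p.engagement_duration, p.engagement_dt)
    times.append(t)
    disps.append(np.zeros_like(t))
    phases.append(np.full(t.shape, "engagement", dtype=object))
    t0 = p.engagement_duration

    for k in range(1, p.n_pulls + 1):
        d0 = p.total_descent * (k - 1) / p.n_pulls
        d1 = p.total_descent * k / p.n_pulls
        t = _phase_samples(t0, p.contraction_duration, p.dt)
        d = d0 + (d1 - d0) * (t - t0) / p.contraction_duration
        d[-1] = d1  # phase boundary exact, immune to float drift in t
        times.append(t)
        disps.append(d)
        phases.append(np.full(t.shape, f"pull_{k}", dtype=object))
        t0 += p.contraction_duration
        if k < p.n_pulls:
            t = _phase_samples(t0, p.rest_duration, p.dt)
            times.append(t)
            disps.append(np.full(t.shape, d1))
            phases.append(np.full(t.shape, f"rest_{k}", dtype=object))
            t0 += p.rest_duration

    time = np.concatenate(times)
    disp = np.concatenate(disps)
    # final pull ends exactly at the prescribed total descent
    disp[-1] = p.total_descent
    phase = np.concatenate(phases)
    return DisplacementHistory(time=time, displacement=disp, phase=phase)
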