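"""Inverse dynamics of the telescoping inverted-pendulum walker.

The body is a point mass on a massless leg of variable length pivoting
about the active ground contact.  Relative to that contact the CoM position
``(x_rel, y)`` maps to polar coordinates

    l   = sqrt(x_rel^2 + y^2),        phi = arctan(x_rel / y),

with ``phi`` measured from the upright, positive when the contact lies
behind the CoM.  Velocities resolve along and across the leg as

    l_dot       = x_dot sin(phi) + y_dot cos(phi)
    phi_dot * l = x_dot cos(phi) - y_dot sin(phi)

and the constraint loads follow from the free-body diagram of the point
mass: an axial leg force ``F`` and a shear force ``S = M / l`` (the
pendular torque ``M`` about the contact, transmitted by the massless leg):

    F = m x_dd sin(phi) + (m y_dd + m g) cos(phi)
    S = m x_dd cos(phi) - (m y_dd + m g) sin(phi)

The instantaneous power splits into a leg-extension part ``P_F = F l_dot``
and a pendular part ``P_M = M phi_dot``; their sum equals the rate of
change of total mechanical energy, ``m (x_dot x_dd + y_dot (y_dd + g))``,
identically.  Rotating the loads back to the ground frame recovers the
model ground-reaction force, ``Fx = m x_dd``, ``Fy = m (y_dd + g)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .segmentation import StepSegment
from .trajectory import CoMTrajectory, GaitParameters

__all__ = [
    "SampleMechanics",
    "StepMechanics",
    "to_polar",
    "polar_velocities",
    "leg_loads",
    "powers",
    "ground_reaction",
    "analyze_steps",
    "energy_rate",
]


def to_polar(x_rel, y):
    """Leg length and leg angle from contact-relative CoM coordinates.

    Requires ``y > 0``; then ``|phi| < pi/2`` automatically.
    """
    x_rel = np.asarray(x_rel, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValidationError("CoM height y must be positive")
    return np.hypot(x_rel, y), np.arctan2(x_rel, y)


def polar_velocities(xdot, ydot, phi):
    """Resolve the CoM velocity along (`l_dot`) and across (`phi_dot * l`) the leg."""
    s, c = np.sin(phi), np.cos(phi)
    return xdot * s + ydot * c, xdot * c - ydot * s


def leg_loads(xddot, yddot, phi, l, params: GaitParameters):
    """Axial force F, pendular torque M and shear S = M/l from accelerations."""
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValidationError("leg length must be positive")
    m, g = params.m, params.g
    s, c = np.sin(phi), np.cos(phi)
    F = m * xddot * s + (m * yddot + m * g) * c
    S = m * xddot * c - (m * yddot + m * g) * s
    return F, S * l, S


def powers(F, ldot, M, phidot):
    """Leg-extension power P_F = F l_dot and pendular power P_M = M phi_dot."""
    return F * ldot, M * phidot


def ground_reaction(F, S, phi):
    """Model ground-reaction force components (Fx, Fy) in the ground frame.

    Algebraically equal to ``(m x_dd, m (y_dd + g))``.
    """
    s, c = np.sin(phi), np.cos(phi)
    return F * s + S * c, F * c - S * s


def energy_rate(traj: CoMTrajectory, params: GaitParameters) -> np.ndarray:
    """d/dt of total mechanical energy, ``m (x_d x_dd + y_d (y_dd + g))`` [W]."""
    if not traj.has_derivatives:
        raise ValidationError("trajectory derivatives required")
    return params.m * (traj.dx * traj.ddx + traj.dy * (traj.ddy + params.g))


@dataclass(frozen=True)
class SampleMechanics:
    """Per-sample polar kinematics and loads over a slice of the record."""

    t: np.ndarray
    l: np.ndarray
    phi: np.ndarray
    ldot: np.ndarray
    phidot: np.ndarray
    F: np.ndarray
    M: np.ndarray
    S: np.ndarray
    P_F: np.ndarray
    P_M: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray


@dataclass(frozen=True)
class StepMechanics:
    """Mechanics of one step, split at the stance-leg switch.

    ``pre`` covers samples ``start..switch`` relative to the old contact and
    ``post`` covers ``switch..end`` relative to the new one; the switch
    sample appears in both, once per leg, so that work integrals treat the
    instantaneous hand-over correctly (the old leg acts up to the switch,
    the new one from it).
    """

    segment: StepSegment
    pre: SampleMechanics
    post: SampleMechanics


def _slice_mechanics(
    traj: CoMTrajectory, lo: int, hi: int, contact: float, params: GaitParameters
) -> SampleMechanics:
    sl = slice(lo, hi + 1)
    l, phi = to_polar(traj.x[sl] - contact, traj.y[sl])
    ldot, phidot_l = polar_velocities(traj.dx[sl], traj.dy[sl], phi)
    F, M, S = leg_loads(traj.ddx[sl], traj.ddy[sl], phi, l, params)
    phidot = phidot_l / l
    P_F, P_M = powers(F, ldot, M, phidot)
    Fx, Fy = ground_reaction(F, S, phi)
    return SampleMechanics(
        t=traj.t[sl], l=l, phi=phi, ldot=ldot, phidot=phidot,
        F=F, M=M, S=S, P_F=P_F, P_M=P_M, Fx=Fx, Fy=Fy,
    )


def analyze_steps(
    traj: CoMTrajectory, segments: list[StepSegment], params: GaitParameters
) -> list[StepMechanics]:
    """Per-sample leg state and loads for every step.

    The trajectory must carry velocity and acceleration fields.
    """
    if not traj.has_derivatives:
        raise ValidationError("trajectory derivatives required; run prepare_kinematics")
    out = []
    for seg in segments:
        out.append(
            StepMechanics(
                segment=seg,
                pre=_slice_mechanics(traj, seg.start_index, seg.switch_index,
                                     seg.contact_before, params),
                post=_slice_mechanics(traj, seg.switch_index, seg.end_index,
                                      seg.contact_after, params),
            )
        )
    return out


def mechanics_table(steps: list[StepMechanics]) -> pd.DataFrame:
    """Flatten per-step mechanics into one row per sample.

    Uses the half-open convention: each sample appears once, assigned to the
    stance leg active at that instant (the switch sample to the new leg).
    """
    frames = []
    for step_id, sm in enumerate(steps):
        last = step_id == len(steps) - 1
        for phase, keep_end in (("pre", False), ("post", last)):
            p: SampleMechanics = getattr(sm, phase)
            stop = None if keep_end else -1
            frames.append(
                pd.DataFrame(
                    {
                        "t": p.t[:stop],
                        "step_id": step_id,
                        "l": p.l[:stop],
                        "phi": p.phi[:stop],
                        "ldot": p.ldot[:stop],
                        "phidot": p.phidot[:stop],
                        "F": p.F[:stop],
                        "M": p.M[:stop],
                        "S": p.S[:stop],
                        "P_F": p.P_F[:stop],
                        "P_M": p.P_M[:stop],
                        "Fx": p.Fx[:stop],
                        "Fy": p.Fy[:stop],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
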