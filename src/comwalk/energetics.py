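"""Per-step energy bookkeeping and the mechanical cost of transport.

Over one step the leg's positive and negative work are tallied separately,

    W+ = sum_i  int [P_i]+ dt,    W- = sum_i  int [P_i]- dt,   i in {F, M},

with ``[P]+ = max(P, 0)`` and ``[P]- = max(-P, 0)``.  Because muscle-tendon
units store little work, negative work is not free: it is charged a
fraction ``b`` (default 0.2, after classical eccentric-work measurements).
The dimensionless mechanical cost of transport per step is then

    C = (W+ + b W-) / (m g d).

For the idealized pendular gait all work is impulsive (heel-strike
collision and the matching toe-off push-off); it cannot appear in the power
integrals and is injected analytically as ``E_impact``, entering once as
positive (push-off) and once as b-weighted negative (collision) work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mechanics import SampleMechanics, StepMechanics
from .trajectory import GaitParameters

__all__ = [
    "StepEnergetics",
    "PendularSolution",
    "split_power",
    "step_work",
    "cost_of_transport",
    "pendular_impact_loss",
    "pendular_cot",
    "step_energetics",
    "summarize",
]


@dataclass(frozen=True)
class StepEnergetics:
    """Energy ledger of one step."""

    W_pos: float          # positive work [J]
    W_neg: float          # negative work magnitude [J]
    E_impact: float       # impulsive collision/push-off work [J] (pendular gait)
    C: float              # dimensionless cost of transport
    d: float              # step length [m]
    t_step: float         # step duration [s]


@dataclass(frozen=True)
class PendularSolution:
    """Shooting solution of the rigid-leg (pendular) gait.

    ``phi0`` is the leg angle at the switch, ``v_mid`` the CoM speed at
    midstance, ``v_hs`` the speed just before the switch, ``t_step`` the
    step duration.  Energy conservation along the arc ties them together:
    ``v_hs^2 = v_mid^2 + 2 g l0 (1 - cos phi0)``.
    """

    phi0: float
    v_mid: float
    v_hs: float
    t_step: float


def split_power(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise positive/negative split: ``[P]+ - [P]- = P``."""
    P = np.asarray(P, dtype=float)
    return np.maximum(P, 0.0), np.maximum(-P, 0.0)


def _phase_work(phase: SampleMechanics) -> tuple[float, float]:
    wp = wn = 0.0
    for P in (phase.P_F, phase.P_M):
        pos, neg = split_power(P)
        wp += float(np.trapezoid(pos, phase.t))
        wn += float(np.trapezoid(neg, phase.t))
    return wp, wn


def step_work(step: StepMechanics) -> tuple[float, float]:
    """Positive and negative work over one step by trapezoidal integration.

    The two stance phases (before/after the switch) are integrated
    separately so the discontinuity at the instantaneous leg hand-over is
    not smeared across the switch interval.  Negative parts are clipped per
    sample with no sub-sample zero-crossing interpolation (second-order
    small on the sample grid).
    """
    wp_a, wn_a = _phase_work(step.pre)
    wp_b, wn_b = _phase_work(step.post)
    return wp_a + wp_b, wn_a + wn_b


def cost_of_transport(
    W_pos: float, W_neg: float, E_impact: float, params: GaitParameters, d: float
) -> float:
    """Dimensionless cost of transport ``C = (W+ + E + b (W- + E)) / (m g d)``.

    The impulsive work ``E_impact`` counts on both sides: the push-off does
    positive work equal to the collision loss (cyclic motion), and the
    collision is b-weighted negative work.
    """
    if d <= 0:
        raise ValidationError("step length d must be positive")
    if min(W_pos, W_neg, E_impact) < 0:
        raise ValidationError("work terms must be non-negative")
    b = params.b
    return (W_pos + E_impact + b * (W_neg + E_impact)) / (params.m * params.g * d)


def pendular_impact_loss(m: float, v: float, phi0: float) -> float:
    """Kinetic energy lost in the heel-strike collision of the rigid-leg gait.

    The pre-impact velocity (speed ``v``, perpendicular to the old leg) is
    projected onto the direction perpendicular to the new leg, which is
    rotated by ``2 phi0``; the loss is ``1/2 m v^2 sin^2(2 phi0)``.
    """
    return 0.5 * m * v**2 * np.sin(2.0 * phi0) ** 2


def pendular_cot(v: float, phi0: float, params: GaitParameters) -> float:
    """Closed-form cost of transport of the pendular gait.

    ``C = (1 + b) v^2 / (g l0) sin(phi0) cos^2(phi0)`` with ``v`` the speed
    just before the switch.  Algebraically identical to routing the impact
    loss through :func:`cost_of_transport` with ``d = 2 l0 sin(phi0)``.
    """
    if params.l0 is None:
        raise ValidationError("pendular_cot requires l0 in GaitParameters")
    return (
        (1.0 + params.b)
        * v**2 / (params.g * params.l0)
        * np.sin(phi0) * np.cos(phi0) ** 2
    )


def step_energetics(
    step: StepMechanics, params: GaitParameters, e_impact: float = 0.0
) -> StepEnergetics:
    """Full per-step ledger: work split, impact term and cost of transport."""
    W_pos, W_neg = step_work(step)
    seg = step.segment
    C = cost_of_transport(W_pos, W_neg, e_impact, params, seg.d)
    return StepEnergetics(
        W_pos=W_pos, W_neg=W_neg, E_impact=e_impact, C=C, d=seg.d, t_step=seg.t_step
    )


def summarize(energetics: list[StepEnergetics]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-step report table plus record-level mean/SD statistics.

    Columns mirror the per-step subject reports: step length, work done
    (positive work), negative work and dimensionless cost of transport.
    """
    if not energetics:
        raise ValidationError("no steps to summarize")
    table = pd.DataFrame(
        {
            "step_id": np.arange(len(energetics)),
            "step_length_m": [e.d for e in energetics],
            "t_step_s": [e.t_step for e in energetics],
            "work_pos_J": [e.W_pos for e in energetics],
            "work_neg_J": [e.W_neg for e in energetics],
            "e_impact_J": [e.E_impact for e in energetics],
            "cost_of_transport": [e.C for e in energetics],
        }
    )
    stats: dict[str, float] = {"n_steps": float(len(energetics))}
    for col in ("step_length_m", "t_step_s", "work_pos_J", "work_neg_J",
                "cost_of_transport"):
        stats[f"{col}_mean"] = float(table[col].mean())
        stats[f"{col}_sd"] = float(table[col].std(ddof=0))
    return table, stats
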