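"""End-to-end analysis: trajectory -> kinematics -> steps -> mechanics -> cost.

The four stages are (i) trajectory acquisition, (ii) velocities and
accelerations, (iii) inverse-dynamics leg loads, (iv) per-step work and
cost of transport.  ``analyze_trajectory`` runs them on any trajectory;
``analyze_synthetic`` is a convenience wrapper that reuses a generator's
exact derivatives, known segments and analytic impact loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import signal as sig
from .energetics import StepEnergetics, step_energetics, summarize
from .mechanics import StepMechanics, analyze_steps, mechanics_table
from .segmentation import (
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_MIN_SEPARATION,
    StepSegment,
    detect_steps,
)
from .synthetic import SyntheticGait
from .trajectory import CoMTrajectory, GaitParameters

__all__ = ["GaitAnalysis", "analyze_trajectory", "analyze_synthetic"]


@dataclass(frozen=True)
class GaitAnalysis:
    """Full pipeline output."""

    trajectory: CoMTrajectory          # conditioned trajectory (with derivatives)
    segments: list[StepSegment]
    steps: list[StepMechanics]
    energetics: list[StepEnergetics]
    samples: pd.DataFrame              # one row per sample: kinematics + loads
    report: pd.DataFrame               # one row per step: d, t_step, W+, W-, C
    stats: dict[str, float]            # record-level means and SDs

    @property
    def mean_cost_of_transport(self) -> float:
        return self.stats["cost_of_transport_mean"]


def analyze_trajectory(
    traj: CoMTrajectory,
    params: GaitParameters,
    *,
    segments: list[StepSegment] | None = None,
    filter_on: bool = True,
    passband_hz: float = sig.DEFAULT_PASSBAND_HZ,
    stopband_hz: float = sig.DEFAULT_STOPBAND_HZ,
    use_exact_derivatives: bool = True,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    e_impact_per_step: float = 0.0,
) -> GaitAnalysis:
    """Run the full analysis on a CoM trajectory.

    Parameters
    ----------
    traj : CoMTrajectory
        Input path.  If it already carries derivative fields (synthetic
        gaits attach exact ones) they are used directly unless
        ``use_exact_derivatives`` is false, in which case the numerical
        differentiation chain runs regardless (convergence testing).
    segments : list of StepSegment, optional
        Known step segments (e.g. from a generator).  When omitted, steps
        are detected from the height extrema of the conditioned trajectory.
    filter_on : bool
        Apply the zero-phase low-pass chain when differentiating
        numerically.  Ignored when exact derivatives are used.
    e_impact_per_step : float
        Analytic impulsive loss [J] added to each step's ledger (pendular
        synthetic gait only; measured and smooth gaits leave it 0).
    """
    if traj.has_derivatives and use_exact_derivatives:
        prepared = traj
    else:
        prepared = sig.prepare_kinematics(
            traj.without_derivatives(), filter_on, passband_hz, stopband_hz
        )
    if segments is None:
        segments = detect_steps(prepared, min_prominence, min_separation)
    steps = analyze_steps(prepared, segments, params)
    energetics = [step_energetics(s, params, e_impact_per_step) for s in steps]
    report, stats = summarize(energetics)
    return GaitAnalysis(
        trajectory=prepared,
        segments=segments,
        steps=steps,
        energetics=energetics,
        samples=mechanics_table(steps),
        report=report,
        stats=stats,
    )


def analyze_synthetic(
    gait: SyntheticGait, params: GaitParameters, **kwargs
) -> GaitAnalysis:
    """Analyze a generated gait with its exact derivatives and known segments."""
    kwargs.setdefault("segments", gait.segments)
    kwargs.setdefault("e_impact_per_step", gait.e_impact)
    return analyze_trajectory(gait.trajectory, params, **kwargs)
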