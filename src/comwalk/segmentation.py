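"""Step detection from the vertical CoM trajectory.

A step runs from midstance to midstance.  Midstance is identified with a
local maximum of CoM height (the stance leg is then upright and the foot
contact sits directly below the CoM), and the instantaneous switch from
swing leg to stance leg with the intervening local minimum.  Samples before
the first and after the last detected midstance are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import SegmentationError, ValidationError
from .trajectory import CoMTrajectory

__all__ = ["StepSegment", "detect_steps", "active_contact"]

#: default peak prominence [m]; rejects millimetre-scale sensor ripple
DEFAULT_MIN_PROMINENCE = 0.002
#: default minimum spacing between midstances [s]
DEFAULT_MIN_SEPARATION = 0.3


@dataclass(frozen=True)
class StepSegment:
    """One step: consecutive midstances with the stance switch in between.

    ``contact_before``/``contact_after`` are the ground contact abscissae of
    the old and new stance leg (the CoM x at the bounding midstances, at
    ground height 0).  The switch sample itself belongs to the *new* stance
    leg, a half-open convention that makes per-step integrals partition the
    record without double counting.
    """

    start_index: int
    switch_index: int
    end_index: int
    contact_before: float
    contact_after: float
    d: float
    t_step: float

    def __post_init__(self) -> None:
        if not self.start_index < self.switch_index < self.end_index:
            raise ValidationError(
                f"require start < switch < end, got "
                f"{self.start_index}, {self.switch_index}, {self.end_index}"
            )
        if self.d <= 0:
            raise ValidationError("step length d must be positive")


def _refine_midstance(
    traj: CoMTrajectory, index: int, halfwin: int
) -> tuple[float, float]:
    """Sub-sample midstance time and contact abscissa.

    Least-squares parabola on the height samples around the discrete
    maximum; the vertex gives the midstance time to sub-sample precision
    (noise-induced whole-sample quantization of the argmax otherwise
    dominates the step-length error), and the contact abscissa is the
    forward position interpolated there.  Falls back to the discrete sample
    when the fit is degenerate.
    """
    lo = max(index - halfwin, 0)
    hi = min(index + halfwin, traj.n_samples - 1)
    tau = traj.t[lo : hi + 1] - traj.t[index]
    c2, c1, _ = np.polyfit(tau, traj.y[lo : hi + 1], 2)
    if c2 >= 0:  # not concave: keep the discrete peak
        return float(traj.t[index]), float(traj.x[index])
    t_peak = float(traj.t[index] - c1 / (2.0 * c2))
    if abs(t_peak - traj.t[index]) > halfwin * traj.dt:
        return float(traj.t[index]), float(traj.x[index])
    return t_peak, float(np.interp(t_peak, traj.t, traj.x))


def detect_steps(
    traj: CoMTrajectory,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    refine: bool = True,
) -> list[StepSegment]:
    """Detect steps from local extrema of CoM height.

    One :class:`StepSegment` per consecutive pair of qualifying height
    maxima; the switch index is the height minimum between them.  Plateau
    extrema resolve to their first sample for determinism.  With ``refine``
    (the default) contact abscissae, step lengths and durations come from
    sub-sample parabolic refinement of the midstance maxima; sample indices
    always stay on the grid.
    """
    y = traj.y
    distance = max(1, int(round(min_separation * traj.sample_rate)))
    maxima, props = find_peaks(
        y, prominence=min_prominence, distance=distance, plateau_size=(1, None)
    )
    maxima = props["left_edges"]  # plateau tie-break: first sample
    if maxima.size < 2:
        raise SegmentationError(
            f"no steps detected: found {maxima.size} qualifying height maxima, need >= 2"
        )
    halfwin = max(2, int(round(min_separation * traj.sample_rate / 3.0)))
    if refine:
        refined = [_refine_midstance(traj, int(i), halfwin) for i in maxima]
    else:
        refined = [(float(traj.t[i]), float(traj.x[i])) for i in maxima]
    segments: list[StepSegment] = []
    for (i0, i1), (r0, r1) in zip(
        zip(maxima[:-1], maxima[1:]), zip(refined[:-1], refined[1:])
    ):
        interior = y[i0 + 1 : i1]
        if interior.size == 0 or np.min(interior) >= min(y[i0], y[i1]):
            raise SegmentationError(
                f"no interior height minimum between maxima at samples {i0} and {i1}"
            )
        switch = i0 + 1 + int(np.argmin(interior))
        (t0, c0), (t1, c1) = r0, r1
        if c1 - c0 <= 0:
            raise SegmentationError(
                f"non-positive step length between samples {i0} and {i1}"
            )
        segments.append(
            StepSegment(
                start_index=int(i0),
                switch_index=switch,
                end_index=int(i1),
                contact_before=c0,
                contact_after=c1,
                d=c1 - c0,
                t_step=t1 - t0,
            )
        )
    return segments


def active_contact(segment: StepSegment, sample_index: int) -> float:
    """Ground contact abscissa of the stance leg at ``sample_index``.

    The switch sample belongs to the new stance leg.
    """
    if not segment.start_index <= sample_index <= segment.end_index:
        raise ValidationError(
            f"sample {sample_index} outside step "
            f"[{segment.start_index}, {segment.end_index}]"
        )
    if sample_index < segment.switch_index:
        return segment.contact_before
    return segment.contact_after
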