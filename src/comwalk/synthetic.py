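"""Synthetic reference gaits: pendular, level and sinusoidal CoM paths.

Three idealized planar gaits bracket human walking, all sharing step length
``d``, maximum leg length ``l0`` and average forward speed ``v0``:

* **pendular** — the stance leg is a rigid inverted pendulum; the CoM rides
  circular arcs joined by velocity cusps.  All work is impulsive at the
  step-to-step transition; the generator records the collision loss
  analytically.
* **level** — the CoM translates at constant speed and constant height
  ``h = sqrt(l0^2 - (d/2)^2)``, the height at which the extending leg
  reaches exactly ``l0`` at the switch.
* **sinusoidal** — constant forward speed with vertical excursion
  ``y = h + a + a cos(2 pi x_rel / d)``: height maxima at midstances and
  minimum ``h`` at the switches, so the leg again reaches ``l0`` exactly at
  hand-over and the ``a -> 0`` limit recovers the level gait.

Generators attach exact analytic derivatives so downstream mechanics is
free of discretization error, and return the known contacts and step
segments so gaits with no height extrema (level) segment correctly.
The records carry half a step of margin on each side so every midstance is
an interior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .energetics import PendularSolution, pendular_impact_loss
from .errors import SolverError, ValidationError
from .segmentation import StepSegment
from .trajectory import CoMTrajectory, GaitParameters

__all__ = [
    "SyntheticGaitSpec",
    "SyntheticGait",
    "gen_level",
    "gen_sinusoidal",
    "solve_pendular",
    "gen_pendular",
    "add_noise",
]


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Parameters of a synthetic gait.

    Defaults reproduce the shared reference conditions: step length
    ``d = 0.77`` m, leg length ``l0 = 1.07`` m, average speed
    ``v0 = 1.4`` m/s, sinusoidal amplitude ``a = 0.02`` m.
    """

    kind: str = "sinusoidal"
    d: float = 0.77
    l0: float = 1.07
    v0: float = 1.4
    a: float = 0.02
    n_steps: int = 4
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("pendular", "level", "sinusoidal"):
            raise ValidationError(f"unknown gait kind {self.kind!r}")
        if not 0 < self.d < 2 * self.l0:
            raise ValidationError("need 0 < d < 2 l0 (step must be reachable)")
        if self.v0 <= 0:
            raise ValidationError("average speed v0 must be positive")
        if self.a < 0 or self.a >= self.l0:
            raise ValidationError("sinusoidal amplitude must satisfy 0 <= a < l0")
        if self.n_steps < 1:
            raise ValidationError("need at least one step")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    @property
    def phi0(self) -> float:
        """Leg angle at the switch [rad]: ``arcsin((d/2)/l0)``."""
        return float(np.arcsin(self.d / 2.0 / self.l0))

    @property
    def h(self) -> float:
        """CoM height at the switch [m]: ``sqrt(l0^2 - (d/2)^2)``."""
        return float(np.sqrt(self.l0**2 - (self.d / 2.0) ** 2))


@dataclass(frozen=True)
class SyntheticGait:
    """A generated gait: trajectory, known contacts/segments and metadata."""

    spec: SyntheticGaitSpec
    trajectory: CoMTrajectory
    contacts: np.ndarray
    segments: list[StepSegment] = field(default_factory=list)
    solution: PendularSolution | None = None
    e_impact: float = 0.0  # impulsive loss per step [J]; pendular only


def _time_grid(spec: SyntheticGaitSpec, t_step: float) -> np.ndarray:
    """Uniform grid over n_steps plus half a step of margin on each side."""
    n = int(round((spec.n_steps + 1) * t_step * spec.sample_rate))
    return np.arange(n + 1) / spec.sample_rate


def _known_segments(
    spec: SyntheticGaitSpec, traj: CoMTrajectory, t_step: float
) -> list[StepSegment]:
    """Segments from the generator's geometry: midstance of step k at
    ``t = (k + 1/2) t_step``, switch at ``t = (k + 1) t_step``."""
    fs = spec.sample_rate
    segs = []
    for k in range(spec.n_steps):
        i0 = int(round((k + 0.5) * t_step * fs))
        isw = int(round((k + 1.0) * t_step * fs))
        i1 = int(round((k + 1.5) * t_step * fs))
        segs.append(
            StepSegment(
                start_index=i0, switch_index=isw, end_index=i1,
                contact_before=float(traj.x[i0]), contact_after=float(traj.x[i1]),
                d=float(traj.x[i1] - traj.x[i0]),
                t_step=float(traj.t[i1] - traj.t[i0]),
            )
        )
    return segs


def gen_level(spec: SyntheticGaitSpec) -> SyntheticGait:
    """Level gait: constant height ``h``, constant forward speed ``v0``."""
    t_step = spec.d / spec.v0
    t = _time_grid(spec, t_step)
    x = spec.v0 * t - spec.d / 2.0  # midstance k over contact k*d
    zero = np.zeros_like(t)
    traj = CoMTrajectory(
        t=t, x=x, y=np.full_like(t, spec.h),
        dx=np.full_like(t, spec.v0), dy=zero, ddx=zero, ddy=zero,
    )
    contacts = spec.d * np.arange(spec.n_steps + 1)
    return SyntheticGait(
        spec=spec, trajectory=traj, contacts=contacts,
        segments=_known_segments(spec, traj, t_step),
    )


def gen_sinusoidal(spec: SyntheticGaitSpec) -> SyntheticGait:
    """Sinusoidal gait: constant forward speed, vertical excursion ``2a``."""
    t_step = spec.d / spec.v0
    t = _time_grid(spec, t_step)
    x = spec.v0 * t - spec.d / 2.0
    om = 2.0 * np.pi * spec.v0 / spec.d  # vertical angular frequency [rad/s]
    theta = 2.0 * np.pi * x / spec.d     # = 0 (mod 2 pi) at midstances
    a = spec.a
    traj = CoMTrajectory(
        t=t,
        x=x,
        y=spec.h + a + a * np.cos(theta),
        dx=np.full_like(t, spec.v0),
        dy=-a * om * np.sin(theta),
        ddx=np.zeros_like(t),
        ddy=-a * om**2 * np.cos(theta),
    )
    contacts = spec.d * np.arange(spec.n_steps + 1)
    return SyntheticGait(
        spec=spec, trajectory=traj, contacts=contacts,
        segments=_known_segments(spec, traj, t_step),
    )


def solve_pendular(
    spec: SyntheticGaitSpec, params: GaitParameters, speed_tol: float = 1e-9
) -> PendularSolution:
    """Find the midstance speed of the rigid-leg gait by shooting.

    Along an arc energy is conserved, ``v(phi)^2 = v_mid^2 +
    2 g l0 (1 - cos phi)``, so the half-step duration is the quadrature

        t_half(v_mid) = l0 * int_0^phi0  dphi / v(phi).

    Bisection on ``v_mid`` enforces the step-average forward speed
    ``d / t_step = v0`` (``v0`` is the average speed, not the midstance
    speed).  Raises :class:`SolverError` when no root lies in the bracket
    ``[0.1 v0, 2 v0]``.
    """
    g, l0, phi0 = params.g, spec.l0, spec.phi0

    def t_half(v_mid: float) -> float:
        val, _ = quad(
            lambda p: l0 / np.sqrt(v_mid**2 + 2 * g * l0 * (1 - np.cos(p))),
            0.0, phi0, epsabs=1e-13, epsrel=1e-12,
        )
        return val

    def mismatch(v_mid: float) -> float:
        return spec.d / (2.0 * t_half(v_mid)) - spec.v0

    lo, hi = 0.1 * spec.v0, 2.0 * spec.v0
    if mismatch(lo) * mismatch(hi) > 0:
        raise SolverError(
            f"no midstance speed in [{lo:.3g}, {hi:.3g}] m/s gives average speed "
            f"{spec.v0} m/s for d={spec.d}, l0={spec.l0}"
        )
    v_mid = brentq(mismatch, lo, hi, xtol=speed_tol)
    v_hs = float(np.sqrt(v_mid**2 + 2 * g * l0 * (1 - np.cos(phi0))))
    # the shooting target fixes t_step = d / v0; using it verbatim keeps the
    # sample grid exactly aligned with the arc boundaries
    return PendularSolution(
        phi0=phi0, v_mid=float(v_mid), v_hs=v_hs, t_step=spec.d / spec.v0
    )


def gen_pendular(spec: SyntheticGaitSpec, params: GaitParameters) -> SyntheticGait:
    """Pendular gait: circular arcs of radius ``l0`` about contacts at ``k d``.

    Within each arc the samples follow the inverted-pendulum time law
    ``phi_dd = (g / l0) sin(phi)``, integrated once over a half arc with a
    high-order adaptive scheme and mapped to the global grid by the odd
    symmetry of ``phi(t)`` about midstance.  Velocity is discontinuous at
    the switch cusp; derivative fields are one-sided there (the switch
    sample carries the new leg's arc), and the collision loss is recorded
    analytically in ``e_impact`` rather than through derivatives.
    """
    sol = solve_pendular(spec, params)
    g, l0 = params.g, spec.l0
    t_step, t_half = sol.t_step, sol.t_step / 2.0

    ivp = solve_ivp(
        lambda _t, s: [s[1], (g / l0) * np.sin(s[0])],
        (0.0, t_half),
        [0.0, sol.v_mid / l0],
        method="DOP853", dense_output=True, rtol=1e-11, atol=1e-13,
    )
    if not ivp.success:
        raise SolverError(f"pendulum integration failed: {ivp.message}")
    end_phi = ivp.sol(t_half)[0]
    if abs(end_phi - spec.phi0) > 1e-7:
        raise SolverError(
            f"arc does not reach phi0: got {end_phi:.9f}, expected {spec.phi0:.9f}"
        )

    t = _time_grid(spec, t_step)
    # arc k spans t in [k t_step, (k+1) t_step]; a sample exactly on the
    # boundary (the cusp) belongs to the new stance leg
    k = np.minimum(np.floor(t / t_step).astype(int), spec.n_steps)
    tau = t - (k + 0.5) * t_step  # arc-local time, midstance at 0
    sgn = np.sign(tau)
    phi_half, om_half = ivp.sol(np.minimum(np.abs(tau), t_half))
    phi = sgn * phi_half
    om = om_half  # phi_dot is even in tau
    phidd = (g / l0) * np.sin(phi)

    s, c = np.sin(phi), np.cos(phi)
    traj = CoMTrajectory(
        t=t,
        x=k * spec.d + l0 * s,
        y=l0 * c,
        dx=l0 * c * om,
        dy=-l0 * s * om,
        ddx=l0 * (c * phidd - s * om**2),
        ddy=-l0 * (s * phidd + c * om**2),
    )
    contacts = spec.d * np.arange(spec.n_steps + 1)
    return SyntheticGait(
        spec=spec,
        trajectory=traj,
        contacts=contacts,
        segments=_known_segments(spec, traj, t_step),
        solution=sol,
        e_impact=float(pendular_impact_loss(params.m, sol.v_hs, sol.phi0)),
    )


def add_noise(traj: CoMTrajectory, sigma: float, seed: int) -> CoMTrajectory:
    """Add independent Gaussian position noise of SD ``sigma`` [m] to x and y.

    Emulates marker/reconstruction noise in motion capture.  Deterministic
    for a fixed seed; derivative fields are dropped.
    """
    if sigma < 0:
        raise ValidationError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    return CoMTrajectory(
        t=traj.t,
        x=traj.x + rng.normal(0.0, sigma, traj.n_samples) if sigma else traj.x,
        y=traj.y + rng.normal(0.0, sigma, traj.n_samples) if sigma else traj.y,
    )
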