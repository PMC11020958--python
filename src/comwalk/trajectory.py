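"""Planar center-of-mass trajectory container and delimited-text I/O.

The whole pipeline works on a single data structure: a uniformly sampled
planar CoM path ``(t, x, y)`` with ``x`` positive in the walking direction,
``y`` vertically upward and the ground at ``y = 0``.  Velocity and
acceleration fields are optional; they are attached either analytically by
the synthetic-gait generators or numerically by
:func:`comwalk.signal.prepare_kinematics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError, ValidationError

__all__ = [
    "CoMTrajectory",
    "GaitParameters",
    "read_trajectory",
    "write_trajectory",
    "scale_vertical_displacement",
]

#: relative tolerance on sample-interval uniformity
_DT_RTOL = 1e-9

_DERIV_COLUMNS = ("dx", "dy", "ddx", "ddy")


@dataclass(frozen=True)
class CoMTrajectory:
    """Uniformly sampled planar CoM path with optional derivatives.

    Parameters
    ----------
    t : ndarray
        Sample times [s], strictly increasing, uniform spacing.
    x : ndarray
        Forward CoM position [m].
    y : ndarray
        Vertical CoM position [m], strictly positive (above the ground plane).
    dx, dy : ndarray, optional
        CoM velocity components [m/s].
    ddx, ddy : ndarray, optional
        CoM acceleration components [m/s^2].
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray | None = None
    dy: np.ndarray | None = None
    ddx: np.ndarray | None = None
    ddy: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("t", "x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 3:
            raise ValidationError(f"trajectory needs at least 3 samples, got {n}")
        if self.x.size != n or self.y.size != n:
            raise ValidationError("t, x, y must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("time vector must be strictly increasing")
        dt0 = float(np.mean(dt))
        if np.max(np.abs(dt - dt0)) > _DT_RTOL * dt0 + 1e-12:
            raise ValidationError("non-uniform sampling exceeds tolerance")
        if np.any(self.y <= 0):
            raise ValidationError("y must be positive everywhere (CoM above ground)")
        for name in _DERIV_COLUMNS:
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValidationError(f"{name} length mismatch")
                object.__setattr__(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Sample interval [s]."""
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate(self) -> float:
        """Sampling frequency [Hz]."""
        return 1.0 / self.dt

    @property
    def has_derivatives(self) -> bool:
        return all(getattr(self, name) is not None for name in _DERIV_COLUMNS)

    def with_derivatives(
        self, dx: np.ndarray, dy: np.ndarray, ddx: np.ndarray, ddy: np.ndarray
    ) -> "CoMTrajectory":
        return replace(self, dx=dx, dy=dy, ddx=ddx, ddy=ddy)

    def without_derivatives(self) -> "CoMTrajectory":
        return replace(self, dx=None, dy=None, ddx=None, ddy=None)


@dataclass(frozen=True)
class GaitParameters:
    """Subject and model parameters.

    Parameters
    ----------
    m : float
        Body mass [kg].
    g : float
        Gravitational field strength [m/s^2].
    b : float
        Negative-work weighting factor (dimensionless); muscles performing
        negative (absorbing) work are charged a fraction ``b`` of that work.
    l0 : float, optional
        Maximum leg length [m]; required only by the synthetic pendular gait.
    """

    m: float
    g: float = 9.81
    b: float = 0.2
    l0: float | None = None

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValidationError("mass m must be positive")
        if self.g <= 0:
            raise ValidationError("gravity g must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ValidationError("negative-work factor b must be in [0, 1]")
        if self.l0 is not None and self.l0 <= 0:
            raise ValidationError("leg length l0 must be positive")


def read_trajectory(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    mm_to_m: bool = False,
    delimiter: str = ",",
) -> CoMTrajectory:
    """Read a CoM trajectory from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    columns : mapping, optional
        Maps canonical names (``t``, ``x``, ``y`` and optionally ``dx``,
        ``dy``, ``ddx``, ``ddy``) to the header names used in the file.
        Defaults to the identity mapping.
    mm_to_m : bool
        Convert position columns from millimetres (common in motion-capture
        exports) to metres on read.  Velocity/acceleration columns are
        scaled accordingly.
    """
    path = Path(path)
    colmap = {k: k for k in ("t", "x", "y", *_DERIV_COLUMNS)}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for canon in ("t", "x", "y"):
        if colmap[canon] not in df.columns:
            raise TrajectoryFormatError(
                f"{path.name}: missing required column {colmap[canon]!r} (for {canon!r})"
            )
    scale = 1e-3 if mm_to_m else 1.0
    data: dict[str, np.ndarray] = {
        "t": df[colmap["t"]].to_numpy(float),
        "x": df[colmap["x"]].to_numpy(float) * scale,
        "y": df[colmap["y"]].to_numpy(float) * scale,
    }
    if all(colmap[c] in df.columns for c in _DERIV_COLUMNS):
        for c in _DERIV_COLUMNS:
            data[c] = df[colmap[c]].to_numpy(float) * scale
    return CoMTrajectory(**data)


def write_trajectory(traj: CoMTrajectory, path: str | Path) -> None:
    """Write a trajectory as CSV at full double precision.

    Writes ``t,x,y`` and, when all derivative fields are present, the four
    derivative columns ``dx,dy,ddx,ddy`` as well.
    """
    cols = {"t": traj.t, "x": traj.x, "y": traj.y}
    if traj.has_derivatives:
        for c in _DERIV_COLUMNS:
            cols[c] = getattr(traj, c)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def scale_vertical_displacement(traj: CoMTrajectory, factor: float) -> CoMTrajectory:
    """Scale the vertical CoM excursion about its mean by ``factor``.

    The mean height, the forward motion and the time base are preserved;
    derivative fields are dropped (they must be recomputed).  Used to probe
    the sensitivity of the cost of transport to the vertical CoM amplitude.
    """
    if factor <= 0:
        raise ValidationError("scale factor must be positive")
    mean_y = float(np.mean(traj.y))
    y = mean_y + factor * (traj.y - mean_y)
    return CoMTrajectory(t=traj.t, x=traj.x, y=y)
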