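"""Per-trajectory descriptive movement metrics.

Step displacements, mean speed, initial/final heading angles, signed turning
angles, and the straightness index I_s (net displacement over path length
measured on fixed windows of steps).  All angles are radians measured
counterclockwise from the +x axis, wrapped to the half-open interval
(-pi, pi]; a perfect reversal is mapped to +pi so binning is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedHeadingError
from .io import Trajectory

#: Default start position index for the initial-heading vector.  The initial
#: heading is taken as the angle of the vector from position
#: ``initial_start`` to position 5, i.e. after the animal has had five frames
#: (> 2 min at 30 s/frame) to settle; trajectories shorter than 6 positions
#: have no initial heading.
INITIAL_HEADING_END = 5


@dataclass(frozen=True)
class PathMetrics:
    """Summary kinematics of one trajectory.

    ``initial_heading`` is NaN for trajectories too short to define it
    (fewer than 6 positions); ``straightness`` lies in [0, 1].
    """

    id: str
    n_steps: int
    duration: float
    mean_speed: float
    straightness: float
    initial_heading: float
    final_heading: float
    treatment: str | None = None


def wrap_angle(angle):
    """Wrap angle(s) to (-pi, pi]; exact reversals map to +pi."""
    a = np.mod(np.asarray(angle, dtype=float), 2.0 * np.pi)
    a = np.where(a > np.pi, a - 2.0 * np.pi, a)
    return a if a.ndim else float(a)


def step_displacements(traj: Trajectory) -> np.ndarray:
    """(n_steps, 2) array of frame-to-frame displacement vectors."""
    return np.diff(traj.positions, axis=0)


def step_lengths(traj: Trajectory) -> np.ndarray:
    return np.linalg.norm(step_displacements(traj), axis=1)


def mean_speed(traj: Trajectory) -> float:
    """Arithmetic mean over steps of step length / frame interval.

    Zero if and only if the animal never moved.
    """
    return float(np.mean(step_lengths(traj)) / traj.frame_interval)


def turning_angles(traj: Trajectory, min_step: float = 0.0) -> np.ndarray:
    """Signed relative angles between successive steps, in (-pi, pi].

    Steps whose displacement is below ``min_step`` (or exactly zero when
    ``min_step`` is 0) have no defined heading and are skipped; the turning
    angle is then measured between the surviving flanking steps.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 positions, or fewer than 2 usable (non-degenerate) steps.
    """
    if traj.n_positions < 3:
        raise InsufficientDataError(
            f"trajectory {traj.id!r}: turning angles need >= 3 positions"
        )
    if min_step < 0:
        raise ValueError("min_step must be >= 0")
    disp = step_displacements(traj)
    lengths = np.linalg.norm(disp, axis=1)
    usable = lengths > min_step if min_step > 0 else lengths > 0
    disp = disp[usable]
    if disp.shape[0] < 2:
        raise InsufficientDataError(
            f"trajectory {traj.id!r}: fewer than 2 usable steps "
            f"(min_step={min_step})"
        )
    head = np.arctan2(disp[:, 1], disp[:, 0])
    return np.asarray(wrap_angle(np.diff(head)))


def headings(
    traj: Trajectory, initial_start: int = 0
) -> tuple[float, float]:
    """Initial and final heading angles of a trajectory.

    The initial heading is the four-quadrant arctangent of the vector from
    position ``initial_start`` (default 0) to position 5 — the animal is
    allowed five frames to settle before its departure bearing is read.  The
    final heading uses the vector from the first to the last position.

    Returns
    -------
    (initial, final) : tuple of float
        Radians in (-pi, pi].

    Raises
    ------
    InsufficientDataError
        Fewer than 6 positions (initial) — the final heading alone is defined
        for any 2-position path; use :func:`final_heading` then.
    UndefinedHeadingError
        A heading vector of exactly zero length.
    """
    if not 0 <= initial_start < INITIAL_HEADING_END:
        raise ValueError("initial_start must be in [0, 5)")
    if traj.n_positions < INITIAL_HEADING_END + 1:
        raise InsufficientDataError(
            f"trajectory {traj.id!r}: initial heading needs >= 6 positions, "
            f"got {traj.n_positions}"
        )
    v0 = traj.positions[INITIAL_HEADING_END] - traj.positions[initial_start]
    if np.allclose(v0, 0.0):
        raise UndefinedHeadingError(
            f"trajectory {traj.id!r}: zero-length initial-heading vector"
        )
    return (_vector_angle(v0), final_heading(traj))


def final_heading(traj: Trajectory) -> float:
    """Angle of the vector connecting the first and last positions."""
    v = traj.positions[-1] - traj.positions[0]
    if np.allclose(v, 0.0):
        raise UndefinedHeadingError(
            f"trajectory {traj.id!r}: zero-length final-heading vector"
        )
    return _vector_angle(v)


def _vector_angle(v: np.ndarray) -> float:
    return float(wrap_angle(np.arctan2(v[1], v[0])))


def straightness_index(traj: Trajectory, window: int = 1) -> float:
    """Straightness index I_s: net displacement over windowed path length.

    The denominator sums Euclidean distances between positions ``window``
    steps apart, on consecutive non-overlapping windows anchored at the first
    point; a trailing remainder shorter than the window contributes its own
    hop, so the numerator's endpoints and the denominator's chain cover the
    same span and I_s <= 1 holds exactly.  1 for a perfectly straight sampled
    path, 0 for a closed loop; defined as 0 when the animal never moves.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if traj.n_positions < window + 1:
        raise InsufficientDataError(
            f"trajectory {traj.id!r}: window {window} needs "
            f">= {window + 1} positions, got {traj.n_positions}"
        )
    idx = list(range(0, traj.n_positions, window))
    if idx[-1] != traj.n_positions - 1:
        idx.append(traj.n_positions - 1)
    pts = traj.positions[idx]
    denom = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if denom == 0.0:
        return 0.0
    num = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return num / denom


def path_metrics(
    traj: Trajectory, window: int = 1, initial_start: int = 0
) -> PathMetrics:
    """Assemble the per-trajectory summary used in the study report.

    Trajectories with fewer than 6 positions get a NaN initial heading
    rather than a fallback estimate.
    """
    try:
        initial, final = headings(traj, initial_start=initial_start)
    except InsufficientDataError:
        initial = float("nan")
        final = final_heading(traj)
    except UndefinedHeadingError:
        initial = float("nan")
        try:
            final = final_heading(traj)
        except UndefinedHeadingError:
            final = float("nan")
    return PathMetrics(
        id=traj.id,
        n_steps=traj.n_steps,
        duration=traj.duration,
        mean_speed=mean_speed(traj),
        straightness=straightness_index(traj, window=window),
        initial_heading=initial,
        final_heading=final,
        treatment=traj.treatment,
    )
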