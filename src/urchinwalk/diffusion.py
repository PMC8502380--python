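"""Anomalous-diffusion characterisation via q-th order structure functions.

For a 2-D trajectory sampled at a fixed frame interval, the q-th order
moment of the displacement modulus

    M(q, tau) = < ||X(t + tau) - X(t)||^q >

(averaged over all ordered position pairs separated by the temporal
increment tau) scales as a power law M(q, tau) ~ tau^zeta(q).  The exponent
function zeta(q) characterises the spreading statistics of the walk
regardless of its scale and intensity: zeta(q) = q/2 for uncorrelated
(Brownian) motion and zeta(q) = q for straight-line (ballistic) motion.
zeta(q) is estimated per q as the OLS slope of log M on log tau, on
log-spaced tau so the regression's observations are equally spaced in the
log-log plane; the whole function is summarised by the slope of zeta(q)
versus q constrained through the origin (zeta(0) = 0 by construction), the
single coefficient locating a path on the Brownian-to-ballistic continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError
from .io import Trajectory

#: Default moment orders.  Moderate q keeps the estimator robust on short
#: paths (high orders amplify the largest displacements).
DEFAULT_Q_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Default number of log-spaced tau candidates and the cap on the largest
#: tau as a fraction of the number of steps.  Capping tau at N/4 keeps at
#: least 3N/4 overlapping pairs in every moment estimate and limits the
#: autocorrelation-induced bias of the log-log regression.
DEFAULT_N_TAUS = 12
DEFAULT_MAX_TAU_FRACTION = 0.25

MIN_POSITIONS = 8  # shortest path for which a zeta estimate is attempted


@dataclass(frozen=True)
class MomentCurve:
    """Structure-function moments M(q, tau) of one trajectory.

    ``moments[i, j]`` is the mean of ``||dX(tau_j)||^q_i`` over all ordered
    pairs; ``degenerate`` flags an all-identical-positions path (all-zero
    moments, no scaling exponent defined).
    """

    q_grid: np.ndarray
    tau_grid: np.ndarray
    moments: np.ndarray
    n_pairs: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("q_grid", "tau_grid", "moments", "n_pairs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class ZetaFunction:
    """Per-q scaling exponents and their one-coefficient summary.

    ``zeta[i]`` is the log-log OLS slope for ``q_grid[i]`` (NaN where fewer
    than 3 tau points with positive moments survive); ``slope`` is the
    least-squares slope of zeta(q) on q through the origin, computed over
    the defined q only.
    """

    q_grid: np.ndarray
    zeta: np.ndarray
    zeta_se: np.ndarray
    r_squared: np.ndarray
    slope: float
    slope_se: float = float("nan")
    dropped_taus: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q_grid", "zeta", "zeta_se", "r_squared"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class DiffusionClass:
    """Diffusive-regime label for a summary slope value."""

    label: str
    slope: float
    band_halfwidth: float


def log_spaced_taus(n_steps: int, n_taus: int, max_tau_fraction: float) -> np.ndarray:
    """Unique integer lags, log-spaced from 1 to floor(max_tau_fraction * n_steps)."""
    tau_max = int(np.floor(max_tau_fraction * n_steps))
    if tau_max < 1:
        raise InsufficientDataError(
            f"max tau < 1 (n_steps={n_steps}, fraction={max_tau_fraction})"
        )
    taus = np.unique(
        np.round(np.logspace(0.0, np.log10(tau_max), n_taus)).astype(int)
    )
    return taus[(taus >= 1) & (taus <= tau_max)]


def moment_curve(
    traj: Trajectory,
    q_grid=DEFAULT_Q_GRID,
    n_taus: int = DEFAULT_N_TAUS,
    max_tau_fraction: float = DEFAULT_MAX_TAU_FRACTION,
) -> MomentCurve:
    """Compute the structure-function moments of a trajectory.

    Overlapping (all-pairs) time averaging: for each lag tau the moment is
    the mean over every ordered pair ``(t, t + tau)`` of the q-th power of
    the displacement modulus — the standard structure-function estimator,
    maximising information on short paths.

    Raises
    ------
    InsufficientDataError
        Fewer than 8 positions.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0 or np.any(q <= 0):
        raise ValueError("q_grid must be non-empty and strictly positive")
    if not 0 < max_tau_fraction <= 0.5:
        raise ValueError("max_tau_fraction must be in (0, 0.5]")
    if traj.n_positions < MIN_POSITIONS:
        raise InsufficientDataError(
            f"trajectory {traj.id!r}: structure functions need >= "
            f"{MIN_POSITIONS} positions, got {traj.n_positions}"
        )
    taus = log_spaced_taus(traj.n_steps, n_taus, max_tau_fraction)
    pos = traj.positions
    moments = np.empty((q.size, taus.size))
    n_pairs = np.empty(taus.size, dtype=int)
    for j, tau in enumerate(taus):
        d = pos[tau:] - pos[:-tau]
        mod = np.hypot(d[:, 0], d[:, 1])
        n_pairs[j] = mod.size
        moments[:, j] = np.mean(mod[None, :] ** q[:, None], axis=1)
    degenerate = bool(np.all(moments == 0.0))
    return MomentCurve(
        q_grid=q,
        tau_grid=taus,
        moments=moments,
        n_pairs=n_pairs,
        degenerate=degenerate,
    )


def zeta_exponents(curve: MomentCurve) -> ZetaFunction:
    """Estimate zeta(q) and the through-origin summary slope from a curve.

    Per q, an unweighted OLS of ``log M(q, tau)`` on ``log tau``; lags with
    zero (or non-finite) moments are dropped for that q, and a q with fewer
    than 3 surviving lags gets zeta = NaN and is excluded from the summary
    fit.  The summary slope minimises ``sum_q (zeta(q) - slope * q)^2``,
    anchoring zeta(0) = 0 as the moment definition forces.
    """
    q = curve.q_grid
    zeta = np.full(q.size, np.nan)
    zeta_se = np.full(q.size, np.nan)
    r_squared = np.full(q.size, np.nan)
    dropped: dict[float, list[int]] = {}
    log_tau_all = np.log(curve.tau_grid)
    for i in range(q.size):
        m = curve.moments[i]
        keep = np.isfinite(m) & (m > 0.0)
        if not np.all(keep):
            dropped[float(q[i])] = [int(t) for t in curve.tau_grid[~keep]]
        if keep.sum() < 3:
            continue
        x = log_tau_all[keep]
        y = np.log(m[keep])
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(xc @ xc)
        b = float(xc @ yc) / sxx
        resid = yc - b * xc
        dof = x.size - 2
        mse = float(resid @ resid) / dof if dof > 0 else 0.0
        zeta[i] = b
        zeta_se[i] = np.sqrt(mse / sxx)
        sst = float(yc @ yc)
        r_squared[i] = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0

    ok = np.isfinite(zeta)
    if not ok.any():
        slope = float("nan")
        slope_se = float("nan")
    else:
        qs = q[ok]
        zs = zeta[ok]
        denom = float(qs @ qs)
        slope = float(qs @ zs) / denom
        resid = zs - slope * qs
        dof = qs.size - 1
        slope_se = (
            float(np.sqrt((resid @ resid) / dof / denom)) if dof > 0 else float("nan")
        )
    return ZetaFunction(
        q_grid=q,
        zeta=zeta,
        zeta_se=zeta_se,
        r_squared=r_squared,
        slope=slope,
        slope_se=slope_se,
        dropped_taus=dropped,
    )


def zeta_slope(
    traj: Trajectory,
    q_grid=DEFAULT_Q_GRID,
    n_taus: int = DEFAULT_N_TAUS,
    max_tau_fraction: float = DEFAULT_MAX_TAU_FRACTION,
) -> float:
    """Convenience: summary zeta(q)-vs-q slope of one trajectory."""
    curve = moment_curve(traj, q_grid, n_taus, max_tau_fraction)
    if curve.degenerate:
        return float("nan")
    return zeta_exponents(curve).slope


def classify_diffusion(slope: float, band_halfwidth: float = 0.05) -> DiffusionClass:
    """Map a summary slope onto the diffusive-regime taxonomy.

    Brownian motion sits at slope 0.5 and ballistic (straight-line) motion
    at slope 1; a band of half-width ``band_halfwidth`` around each
    reference line absorbs estimation noise.  Below the Brownian band is
    subdiffusive, between the bands superdiffusive, and at or above the
    ballistic band the path is classed ballistic (including the "marginal
    ballistic" edge).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if not 0 < band_halfwidth < 0.25:
        raise ValueError("band_halfwidth must be in (0, 0.25)")
    b = band_halfwidth
    if slope < 0.5 - b:
        label = "subdiffusive"
    elif abs(slope - 0.5) <= b:
        label = "brownian"
    elif slope < 1.0 - b:
        label = "superdiffusive"
    else:
        label = "ballistic"
    return DiffusionClass(label=label, slope=float(slope), band_halfwidth=b)
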