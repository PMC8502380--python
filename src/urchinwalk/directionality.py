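"""Orientation statistics: directional entropy and the Rayleigh test.

Directional entropy measures the unpredictability of a path's heading
changes: the turning angles are binned on a fixed grid over (-pi, pi]
(default bin width 0.05 rad) and the Shannon H of the bin counts is
reported in nats.  Low entropy means stereotyped, predictable heading
changes; the maximum ln(K) is reached when every bin is equally occupied.

The Rayleigh test checks a sample of angles for circular uniformity
against a unimodal alternative, via the mean resultant length R-bar and
the statistic z = n * R-bar^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

DEFAULT_BIN_WIDTH = 0.05  # radians


@dataclass(frozen=True)
class EntropyResult:
    """Binned turning-angle distribution and its Shannon entropy (nats)."""

    bin_width: float
    counts: np.ndarray
    H: float
    n_angles: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class RayleighResult:
    """Rayleigh uniformity test: n, mean resultant length, z, p."""

    n: int
    mean_resultant_length: float
    z: float
    p_value: float


def angle_bin_edges(bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Fixed bin edges partitioning (-pi, pi] from -pi upward.

    With width 0.05 the 2*pi range yields 126 bins, the last one narrower
    because 2*pi is not a multiple of 0.05.  Bins are half-open on the left,
    ``(edge_i, edge_{i+1}]``, so every angle in (-pi, pi] lands in exactly
    one bin and counts are deterministic.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_full = int(np.ceil(2.0 * np.pi / bin_width - 1e-12))
    edges = -np.pi + bin_width * np.arange(n_full + 1)
    edges[-1] = np.pi
    return edges


def directional_entropy(
    angles, bin_width: float = DEFAULT_BIN_WIDTH
) -> EntropyResult:
    """Shannon entropy (nats) of the binned relative-angle distribution.

    Plug-in (maximum-likelihood) estimator: H = -sum p_i ln p_i over
    non-empty bins with p_i = count_i / n.  No bias correction is applied
    by default — the statistic is the Shannon H of the raw bin counts.

    Raises
    ------
    InsufficientDataError
        Empty angle sequence.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InsufficientDataError("directional entropy needs >= 1 angle")
    if np.any(~np.isfinite(a)) or np.any(a <= -np.pi) or np.any(a > np.pi):
        raise ValueError("angles must be finite and lie in (-pi, pi]")
    edges = angle_bin_edges(bin_width)
    # (edge_i, edge_{i+1}] binning: an angle equal to an edge joins the bin
    # below it; searchsorted(side="left") - 1 implements exactly that.
    idx = np.searchsorted(edges, a, side="left") - 1
    counts = np.bincount(idx, minlength=edges.size - 1)
    p = counts[counts > 0] / a.size
    H = float(-np.sum(p * np.log(p)))
    return EntropyResult(
        bin_width=float(bin_width), counts=counts, H=H, n_angles=int(a.size)
    )


def rayleigh_test(angles, method: str = "series") -> RayleighResult:
    """Rayleigh test of circular uniformity.

    The statistic is z = n * R-bar^2 with R-bar the mean resultant length.
    ``method="series"`` (default) uses the standard two-term series
    approximation of the p-value,

        p = exp(-z) * [1 + (2z - z^2)/(4n)
                         - (24z - 132 z^2 + 76 z^3 - 9 z^4)/(288 n^2)],

    clamped to [0, 1]; ``method="monte_carlo"`` draws the null distribution
    of z under uniformity (the null is fully specified, so this is the
    exact small-n alternative; see :func:`rayleigh_monte_carlo_p`).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 angles.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 3:
        raise InsufficientDataError("Rayleigh test needs n >= 3 angles")
    rbar = float(np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a))))
    z = n * rbar**2
    if method == "series":
        p = np.exp(-z) * (
            1.0
            + (2.0 * z - z**2) / (4.0 * n)
            - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
            / (288.0 * n**2)
        )
        p = float(np.clip(p, 0.0, 1.0))
    elif method == "monte_carlo":
        p = rayleigh_monte_carlo_p(a, seed=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return RayleighResult(n=int(n), mean_resultant_length=rbar, z=float(z), p_value=p)


def rayleigh_monte_carlo_p(
    angles, n_sim: int = 10000, seed: int | None = None
) -> float:
    """Monte-Carlo p-value for the Rayleigh statistic under uniformity.

    Useful as an exact-null alternative to the series approximation when n
    is very small.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 3:
        raise InsufficientDataError("Rayleigh test needs n >= 3 angles")
    obs = rayleigh_test(a).z
    rng = np.random.default_rng(seed)
    sims = rng.uniform(-np.pi, np.pi, size=(n_sim, n))
    rbar = np.hypot(
        np.mean(np.cos(sims), axis=1), np.mean(np.sin(sims), axis=1)
    )
    z = n * rbar**2
    return float((np.sum(z >= obs) + 1) / (n_sim + 1))
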