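"""Synthetic trajectories with known diffusive properties.

Two layers:

* :func:`simulate_trajectory` draws a single path from one of four movement
  models — ``brownian`` (i.i.d. Gaussian displacements), ``ballistic``
  (constant speed and heading, optional heading jitter), ``crw`` (correlated
  random walk: gamma-distributed speeds, von Mises turning angles with
  concentration kappa) and ``levy`` (constant speed, heavy-tailed run
  durations between uniform reorientations).  The models bracket the
  Brownian-to-ballistic continuum: the summary zeta(q) slope is 0.5 for
  ``brownian``, 1 for noiseless ``ballistic``, and in between for ``crw``
  at moderate kappa.

* :func:`simulate_study` assembles a whole two-treatment experiment in a
  circular arena: every animal starts at the centre and its trial ends at
  the drawn duration or at the first frame within a stop margin of the
  wall, whichever comes first.  The control group draws a broad per-
  individual range of turning concentrations (movement spanning Brownian to
  near-ballistic), while the predator-cue group draws concentrated high
  kappa and elevated speed (homogeneous, fast, near-ballistic escape).

Distances are in a single internal length unit of 0.1 cm (mm): the default
step scale of 36 is one 3.6-cm body length per 30-s frame, and the default
arena is 3 m across (radius 1500) with a 100-unit (10 cm) stop margin.
All draws are deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import StudyDataset, Trajectory

MODELS = ("brownian", "ballistic", "crw", "levy")

#: Shape of the gamma speed distribution in the CRW model; mean step length
#: stays at step_scale, the shape only sets the per-step speed variability
#: (shape 4 gives CV = 0.5, a plausible spread for slow benthic crawlers).
CRW_GAMMA_SHAPE = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated trajectory.

    ``step_scale`` is the mean displacement per frame in internal units
    (default 36 = one body length in mm); ``persistence`` is the von Mises
    turning concentration for ``crw`` (0 = uniform turning); ``levy_exponent``
    is the power-law exponent mu of run durations for ``levy``;
    ``heading_jitter`` is the SD in radians of per-step heading noise for
    ``ballistic``.
    """

    model: str
    n_steps: int
    frame_interval: float = 30.0
    step_scale: float = 36.0
    persistence: float = 0.0
    levy_exponent: float = 2.0
    heading_jitter: float = 0.0
    start: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        if self.persistence < 0:
            raise ValueError("persistence (kappa) must be >= 0")
        if not 1.0 < self.levy_exponent <= 3.0:
            raise ValueError("levy_exponent must be in (1, 3]")


@dataclass(frozen=True)
class StudyConfig:
    """Design of a simulated two-treatment arena experiment.

    Group sizes default to the reference design (29 control, 21 predator);
    trial durations are drawn uniformly over ``duration_steps`` (16-208
    steps = 8-104 min at 30 s/frame).  ``control_kappa`` and
    ``predator_kappa`` are (low, high) bounds of log-uniform draws of the
    per-individual turning concentration; ``predator_speed_factor``
    multiplies the predator group's mean step length (default 1.34, a 34%
    mean-speed elevation).
    """

    n_control: int = 29
    n_predator: int = 21
    arena_radius: float = 1500.0
    stop_margin: float = 100.0
    duration_steps: tuple[int, int] = (16, 208)
    frame_interval: float = 30.0
    step_scale: float = 36.0
    control_kappa: tuple[float, float] = (0.2, 50.0)
    predator_kappa: tuple[float, float] = (30.0, 120.0)
    predator_speed_factor: float = 1.34
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_predator < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.stop_margin < self.arena_radius:
            raise ValueError("stop_margin must be in [0, arena_radius)")
        lo, hi = self.duration_steps
        if lo < 2 or hi < lo:
            raise ValueError("duration_steps must satisfy 2 <= low <= high")
        for name in ("control_kappa", "predator_kappa"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} bounds must satisfy 0 < low <= high")
        if self.predator_speed_factor <= 0:
            raise ValueError("predator_speed_factor must be > 0")


def _displacements(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_steps
    s = config.step_scale
    if config.model == "brownian":
        return rng.normal(0.0, s, size=(n, 2))
    if config.model == "ballistic":
        base = rng.uniform(-np.pi, np.pi)
        theta = np.full(n, base)
        if config.heading_jitter > 0:
            theta = theta + rng.normal(0.0, config.heading_jitter, size=n)
        return s * np.column_stack([np.cos(theta), np.sin(theta)])
    if config.model == "crw":
        speeds = rng.gamma(CRW_GAMMA_SHAPE, s / CRW_GAMMA_SHAPE, size=n)
        turns = rng.vonmises(0.0, config.persistence, size=n - 1)
        theta = np.concatenate([[rng.uniform(-np.pi, np.pi)], turns]).cumsum()
        return speeds[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    # levy: straight runs with power-law durations, uniform reorientations
    mu = config.levy_exponent
    theta = np.empty(n)
    i = 0
    while i < n:
        run = int(np.ceil(rng.uniform() ** (-1.0 / (mu - 1.0))))
        run = min(run, n - i)
        theta[i : i + run] = rng.uniform(-np.pi, np.pi)
        i += run
    return s * np.column_stack([np.cos(theta), np.sin(theta)])


def simulate_trajectory(
    config: SimulationConfig,
    traj_id: str = "sim",
    treatment: str | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Draw one trajectory from the configured movement model.

    Deterministic given ``config.seed`` (an explicit ``rng`` overrides it,
    for callers managing their own stream).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    disp = _displacements(config, rng)
    pos = np.vstack([np.asarray(config.start, dtype=float), disp]).cumsum(axis=0)
    return Trajectory(
        id=traj_id,
        positions=pos,
        frame_interval=config.frame_interval,
        treatment=treatment,
        unit="mm",
    )


def _truncate_at_wall(
    positions: np.ndarray, arena_radius: float, stop_margin: float
) -> np.ndarray:
    """Cut a path at the first frame within stop_margin of the arena edge.

    The offending frame is kept as the trial's last observation; if the
    drawn displacement would overshoot the wall itself, the final position
    is pulled radially back onto the wall (the animal cannot leave the
    tank).
    """
    r = np.linalg.norm(positions, axis=1)
    hit = np.nonzero(r >= arena_radius - stop_margin)[0]
    if hit.size:
        positions = positions[: hit[0] + 1].copy()
        r_last = np.linalg.norm(positions[-1])
        if r_last > arena_radius:
            positions[-1] *= arena_radius / r_last
    return positions


def simulate_study(config: StudyConfig = StudyConfig()) -> StudyDataset:
    """Simulate a full two-treatment arena experiment.

    Every animal starts at the arena centre; its path is a correlated
    random walk with a per-individual turning concentration drawn from the
    group's log-uniform range, truncated at the drawn trial duration or at
    the first frame within ``stop_margin`` of the wall.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    trajectories = []
    groups = [
        ("control", config.n_control, config.control_kappa, 1.0),
        ("predator", config.n_predator, config.predator_kappa,
         config.predator_speed_factor),
    ]
    for label, n_ind, (k_lo, k_hi), speed_factor in groups:
        for i in range(n_ind):
            kappa = float(np.exp(rng.uniform(np.log(k_lo), np.log(k_hi))))
            n_steps = int(
                rng.integers(config.duration_steps[0], config.duration_steps[1] + 1)
            )
            sim = SimulationConfig(
                model="crw",
                n_steps=n_steps,
                frame_interval=config.frame_interval,
                step_scale=config.step_scale * speed_factor,
                persistence=kappa,
            )
            traj = simulate_trajectory(
                sim, traj_id=f"{label}_{i + 1:02d}", treatment=label, rng=rng
            )
            pos = _truncate_at_wall(
                traj.positions, config.arena_radius, config.stop_margin
            )
            trajectories.append(
                Trajectory(
                    id=traj.id,
                    positions=pos,
                    frame_interval=traj.frame_interval,
                    treatment=label,
                    unit="mm",
                )
            )
    return StudyDataset(trajectories)


def null_study_config(seed: int | None = None, **kwargs) -> StudyConfig:
    """A study configuration with identical group parameters (no treatment
    effect) — both groups share the control kappa range and speed.

    Used for type-I-error calibration of the treatment tests.
    """
    base = StudyConfig(seed=seed, **kwargs)
    return replace(
        base, predator_kappa=base.control_kappa, predator_speed_factor=1.0
    )
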