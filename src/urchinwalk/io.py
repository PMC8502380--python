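"""Reading, validating and writing trajectory datasets.

The canonical on-disk format is a long ("tidy") CSV with one row per
digitized frame and columns ``id, frame, x, y`` plus optional ``treatment``,
``frame_interval`` and ``unit`` columns.  Frames must be consecutive integers
per individual: the animals are imaged at a fixed interval (30 s in the
reference design) and a missing frame is a data-integrity error, never
silently interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

DEFAULT_FRAME_INTERVAL = 30.0  # seconds between frames in the reference design

REQUIRED_COLUMNS = ("id", "frame", "x", "y")


@dataclass(frozen=True)
class Trajectory:
    """One individual's regularly sampled 2-D path.

    Parameters
    ----------
    id : str
        Unique individual identifier.
    positions : (n, 2) ndarray
        Ordered coordinates, one row per frame; position ``i`` is observed at
        time ``i * frame_interval`` seconds.
    frame_interval : float
        Seconds between consecutive positions (> 0).
    treatment : str or None
        Experimental group label, if any.
    unit : str
        Length unit of the coordinates (``"px"`` unless converted on read).
    """

    id: str
    positions: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    treatment: str | None = None
    unit: str = "px"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise IntegrityError(
                f"trajectory {self.id!r}: positions must be an (n, 2) array, "
                f"got shape {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise IntegrityError(
                f"trajectory {self.id!r}: needs at least 2 positions, "
                f"got {pos.shape[0]}"
            )
        if not np.all(np.isfinite(pos)):
            raise IntegrityError(
                f"trajectory {self.id!r}: non-finite coordinates"
            )
        if not self.frame_interval > 0:
            raise IntegrityError(
                f"trajectory {self.id!r}: frame_interval must be > 0"
            )
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def duration(self) -> float:
        """Elapsed time in seconds from the first to the last position."""
        return self.n_steps * self.frame_interval

    def scaled(self, factor: float, unit: str) -> "Trajectory":
        """Return a copy with coordinates multiplied by ``factor``."""
        return Trajectory(
            id=self.id,
            positions=self.positions * float(factor),
            frame_interval=self.frame_interval,
            treatment=self.treatment,
            unit=unit,
        )


@dataclass
class StudyDataset:
    """A labelled collection of trajectories from one experiment."""

    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate trajectory ids: {dupes}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, traj_id: str) -> Trajectory:
        for t in self.trajectories:
            if t.id == traj_id:
                return t
        raise KeyError(traj_id)

    @property
    def treatments(self) -> set[str]:
        return {t.treatment for t in self.trajectories if t.treatment is not None}

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for t in self.trajectories:
            key = t.treatment if t.treatment is not None else ""
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def subset(self, treatment: str) -> "StudyDataset":
        return StudyDataset([t for t in self.trajectories if t.treatment == treatment])

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of the dataset (the canonical CSV layout)."""
        parts = []
        for t in self.trajectories:
            df = pd.DataFrame(
                {
                    "id": t.id,
                    "frame": np.arange(t.n_positions),
                    "x": t.positions[:, 0],
                    "y": t.positions[:, 1],
                }
            )
            if t.treatment is not None:
                df["treatment"] = t.treatment
            df["frame_interval"] = t.frame_interval
            df["unit"] = t.unit
            parts.append(df)
        if not parts:
            return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
        return pd.concat(parts, ignore_index=True)

    def write(self, path) -> None:
        """Write the dataset as a long CSV (full float precision)."""
        self.to_frame().to_csv(path, index=False)


def read_trajectories(
    path,
    frame_interval: float | None = None,
    scale: float | None = None,
    unit: str | None = None,
) -> StudyDataset:
    """Read a long-CSV trajectory file into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path : str or path-like or buffer
        CSV with columns ``id, frame, x, y`` and optionally ``treatment``,
        ``frame_interval``, ``unit``.
    frame_interval : float, optional
        Overrides any per-file value; default 30 s when absent everywhere.
    scale : float, optional
        Multiplicative unit conversion applied to coordinates on read
        (e.g. cm per pixel).  When given, ``unit`` names the new unit.
    unit : str, optional
        Length-unit label; defaults to a ``unit`` column or ``"px"``.

    Raises
    ------
    FormatError
        A required column is missing.
    IntegrityError
        Duplicated ``(id, frame)`` rows, a gap in frame numbering, or
        non-finite coordinates.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    trajectories = []
    # preserve first-appearance order of individuals
    for traj_id, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(frames) != len(np.unique(frames)):
            dupes = sorted(set(frames[pd.Series(frames).duplicated().to_numpy()]))
            raise IntegrityError(
                f"trajectory {traj_id!r}: duplicated frame(s) {dupes}"
            )
        expected = np.arange(frames[0], frames[0] + len(frames))
        if not np.array_equal(frames, expected):
            gap = int(expected[np.argmax(frames != expected)])
            raise IntegrityError(
                f"trajectory {traj_id!r}: missing frame {gap} "
                f"(frames must be consecutive; no gap-filling is performed)"
            )

        fi = frame_interval
        if fi is None and "frame_interval" in grp.columns:
            vals = grp["frame_interval"].dropna().unique()
            if len(vals) > 1:
                raise IntegrityError(
                    f"trajectory {traj_id!r}: inconsistent frame_interval values"
                )
            if len(vals) == 1:
                fi = float(vals[0])
        if fi is None:
            fi = DEFAULT_FRAME_INTERVAL

        treatment = None
        if "treatment" in grp.columns:
            tvals = grp["treatment"].dropna().unique()
            if len(tvals) > 1:
                raise IntegrityError(
                    f"trajectory {traj_id!r}: inconsistent treatment labels {tvals}"
                )
            if len(tvals) == 1:
                treatment = str(tvals[0])

        u = unit
        if u is None and "unit" in grp.columns and grp["unit"].notna().any():
            u = str(grp["unit"].dropna().iloc[0])
        if u is None:
            u = "px"

        pos = grp[["x", "y"]].to_numpy(dtype=float)
        if scale is not None:
            pos = pos * float(scale)
        trajectories.append(
            Trajectory(
                id=str(traj_id),
                positions=pos,
                frame_interval=fi,
                treatment=treatment,
                unit=u,
            )
        )
    return StudyDataset(trajectories)


def write_metrics(metrics: pd.DataFrame, path) -> None:
    """Write a per-individual metrics table to CSV, round-trip stable.

    One row per trajectory id; floats written at full precision so that
    ``read_metrics(write_metrics(X)) == X``.
    """
    if "id" in metrics.columns and metrics["id"].duplicated().any():
        dupes = sorted(metrics.loc[metrics["id"].duplicated(), "id"].unique())
        raise IntegrityError(f"metrics table has duplicated ids: {dupes}")
    metrics.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    """Read a per-individual metrics table written by :func:`write_metrics`."""
    return pd.read_csv(path, float_precision="round_trip")
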