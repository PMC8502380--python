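"""End-to-end study analysis: dataset in, report out.

``analyze_study`` turns a labelled :class:`~urchinwalk.io.StudyDataset` into
a :class:`StudyReport`: a per-individual metrics table (speed, straightness,
zeta slope, directional entropy, headings), Rayleigh uniformity tests of the
initial and final headings per treatment, the four treatment-comparison
models, and per-group summaries with percent differences.  Individuals too
short for a metric carry missing values and are excluded from the models
that need that metric, with a warning logged — never dropped silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffusion import (
    DEFAULT_MAX_TAU_FRACTION,
    DEFAULT_N_TAUS,
    DEFAULT_Q_GRID,
    MIN_POSITIONS,
    moment_curve,
    zeta_exponents,
)
from .directionality import DEFAULT_BIN_WIDTH, RayleighResult, directional_entropy, rayleigh_test
from .errors import InsufficientDataError, UrchinwalkError
from .inference import ModelResult, ancova_entropy, gls_heteroscedastic, levene_test, lm_treatment
from .io import StudyDataset
from .kinematics import path_metrics, turning_angles

logger = logging.getLogger("urchinwalk")

METRIC_COLUMNS = [
    "id",
    "treatment",
    "n_steps",
    "duration_s",
    "mean_speed",
    "straightness",
    "zeta_slope",
    "entropy",
    "initial_heading",
    "final_heading",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis stages."""

    window: int = 1
    initial_start: int = 0
    q_grid: tuple = DEFAULT_Q_GRID
    n_taus: int = DEFAULT_N_TAUS
    max_tau_fraction: float = DEFAULT_MAX_TAU_FRACTION
    bin_width: float = DEFAULT_BIN_WIDTH
    min_step: float = 0.0
    gls_test: str = "lrt"
    ancova_ss_type: int = 1


@dataclass
class StudyReport:
    """Machine-readable result of one study analysis."""

    per_individual: pd.DataFrame
    rayleigh: dict[str, RayleighResult]
    models: dict[str, ModelResult]
    levene: dict
    group_summaries: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_individual": self.per_individual.to_dict(orient="records"),
            "rayleigh": {k: asdict(v) for k, v in self.rayleigh.items()},
            "models": {
                k: {
                    "response": m.response,
                    "model_type": m.model_type,
                    "effects": m.to_rows(),
                    "n_per_group": m.n_per_group,
                    "aic": m.aic,
                    "group_sd_ratio": m.group_sd_ratio,
                    "group_means": m.group_means,
                    "group_sds": m.group_sds,
                    "extra": m.extra,
                }
                for k, m in self.models.items()
            },
            "levene": self.levene,
            "group_summaries": self.group_summaries,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, indent: int = 2) -> str | None:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        text = json.dumps(self.to_dict(), indent=indent, default=_default,
                          allow_nan=True, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def model_table(self) -> pd.DataFrame:
        """Flat table of every tested effect across models."""
        rows = []
        for m in self.models.values():
            rows.extend(m.to_rows())
        return pd.DataFrame(rows)


def compute_metrics(dataset: StudyDataset, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Per-individual metrics table; one row per trajectory.

    Metrics whose preconditions a trajectory fails (fewer than 8 positions
    for the zeta slope and the entropy of its turning angles, fewer than 6
    for the initial heading) are NaN, and the exclusion is logged.
    """
    rows = []
    for traj in dataset:
        pm = path_metrics(traj, window=config.window, initial_start=config.initial_start)
        if np.isnan(pm.initial_heading):
            logger.warning(
                "trajectory %s: initial heading undefined (%d positions)",
                traj.id, traj.n_positions,
            )
        zslope = np.nan
        entropy = np.nan
        if traj.n_positions >= MIN_POSITIONS:
            curve = moment_curve(
                traj, config.q_grid, config.n_taus, config.max_tau_fraction
            )
            if not curve.degenerate:
                zslope = zeta_exponents(curve).slope
            try:
                ta = turning_angles(traj, min_step=config.min_step)
                entropy = directional_entropy(ta, config.bin_width).H
            except InsufficientDataError:
                pass
        if np.isnan(zslope) or np.isnan(entropy):
            logger.warning(
                "trajectory %s: too short for zeta/entropy (%d positions); "
                "excluded from slope-dependent models",
                traj.id, traj.n_positions,
            )
        rows.append(
            {
                "id": traj.id,
                "treatment": traj.treatment,
                "n_steps": traj.n_steps,
                "duration_s": pm.duration,
                "mean_speed": pm.mean_speed,
                "straightness": pm.straightness,
                "zeta_slope": zslope,
                "entropy": entropy,
                "initial_heading": pm.initial_heading,
                "final_heading": pm.final_heading,
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def _percent_diff(control_mean: float, predator_mean: float) -> float:
    return 100.0 * (predator_mean - control_mean) / control_mean


def group_summaries(metrics: pd.DataFrame) -> dict:
    """Per-treatment means and SDs plus predator-vs-control percent differences."""
    out: dict = {"by_treatment": {}, "percent_difference": {}}
    numeric = ["mean_speed", "straightness", "zeta_slope", "entropy"]
    for treatment, grp in metrics.groupby("treatment"):
        out["by_treatment"][treatment] = {
            "n": int(len(grp)),
            **{
                col: {
                    "mean": float(grp[col].mean()),
                    "sd": float(grp[col].std(ddof=1)),
                }
                for col in numeric
            },
        }
    by = out["by_treatment"]
    if "control" in by and "predator" in by:
        for col in numeric:
            out["percent_difference"][col] = _percent_diff(
                by["control"][col]["mean"], by["predator"][col]["mean"]
            )
    return out


def analyze_study(
    dataset: StudyDataset, config: AnalysisConfig = AnalysisConfig()
) -> StudyReport:
    """Run the full analysis on a labelled two-treatment dataset.

    Deterministic for fixed input and configuration.

    Raises
    ------
    UrchinwalkError
        A treatment with fewer than 3 analyzable trajectories, or a dataset
        without exactly two treatment labels.
    """
    treatments = sorted(dataset.treatments)
    if len(treatments) != 2:
        raise UrchinwalkError(
            f"inference needs exactly 2 treatment labels, got {treatments}"
        )
    logger.info("computing per-individual metrics for %d trajectories", len(dataset))
    metrics = compute_metrics(dataset, config)
    for treatment in treatments:
        n_ok = int(metrics.loc[metrics["treatment"] == treatment, "mean_speed"].notna().sum())
        if n_ok < 3:
            raise UrchinwalkError(
                f"treatment {treatment!r} has {n_ok} analyzable trajectories; "
                f"needs >= 3"
            )

    logger.info("running Rayleigh uniformity tests")
    rayleigh: dict[str, RayleighResult] = {}
    for treatment in treatments:
        grp = metrics[metrics["treatment"] == treatment]
        for which in ("initial_heading", "final_heading"):
            angles = grp[which].dropna().to_numpy()
            key = f"{which.split('_')[0]}_{treatment}"
            try:
                rayleigh[key] = rayleigh_test(angles)
            except InsufficientDataError:
                logger.warning("Rayleigh %s skipped: n=%d < 3", key, angles.size)

    logger.info("fitting treatment-comparison models")
    models: dict[str, ModelResult] = {}

    def _fit(name, func, *args, **kwargs):
        # degenerate data (e.g. zero-variance groups) leave the model
        # undefined with a warning instead of aborting the report
        try:
            models[name] = func(*args, **kwargs)
        except (ValueError, InsufficientDataError) as exc:
            logger.warning("model %s undefined: %s", name, exc)

    complete = metrics.dropna(subset=["mean_speed", "straightness"])
    _fit("straightness", lm_treatment, complete["straightness"],
         complete["treatment"], response="straightness index")
    _fit("mean_speed", lm_treatment, complete["mean_speed"],
         complete["treatment"], response="mean speed")
    slope_ok = metrics.dropna(subset=["zeta_slope"])
    _fit("zeta_slope", gls_heteroscedastic, slope_ok["zeta_slope"],
         slope_ok["treatment"], response="slope of zeta(q)", test=config.gls_test)
    try:
        lev_stat, lev_p = levene_test(slope_ok["zeta_slope"], slope_ok["treatment"])
    except (ValueError, InsufficientDataError) as exc:
        logger.warning("Levene's test undefined: %s", exc)
        lev_stat, lev_p = float("nan"), float("nan")
    both_ok = metrics.dropna(subset=["zeta_slope", "entropy"])
    _fit("entropy", ancova_entropy, both_ok["entropy"], both_ok["zeta_slope"],
         both_ok["treatment"], ss_type=config.ancova_ss_type)

    from . import __version__

    report = StudyReport(
        per_individual=metrics,
        rayleigh=rayleigh,
        models=models,
        levene={"response": "slope of zeta(q)", "statistic": lev_stat, "p_value": lev_p},
        group_summaries=group_summaries(metrics),
        provenance={
            "software": "urchinwalk",
            "version": __version__,
            "config": asdict(config),
            "n_trajectories": len(dataset),
            "treatments": treatments,
        },
    )
    logger.info("analysis complete")
    return report
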