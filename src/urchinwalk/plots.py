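"""Diagnostic figures: metric violins, zeta(q) fans, entropy vs slope."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diffusion import moment_curve, zeta_exponents
from .io import StudyDataset

GROUP_COLORS = {"control": "#3b6fb5", "predator": "#e07b39"}


def _color(label: str) -> str:
    return GROUP_COLORS.get(label, "0.4")


def violin_metrics(metrics: pd.DataFrame, path=None):
    """Violin plots of straightness, mean speed and zeta slope by treatment."""
    cols = [("straightness", "straightness index"),
            ("mean_speed", "mean speed (units/s)"),
            ("zeta_slope", "slope of zeta(q)")]
    labels = sorted(metrics["treatment"].dropna().unique())
    fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 4))
    for ax, (col, title) in zip(np.atleast_1d(axes), cols):
        data = [metrics.loc[metrics["treatment"] == lab, col].dropna() for lab in labels]
        parts = ax.violinplot(data, showmeans=True)
        for body, lab in zip(parts["bodies"], labels):
            body.set_facecolor(_color(lab))
        for i, vals in enumerate(data, start=1):
            ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(
                -0.05, 0.05, len(vals)), vals, "k.", ms=3, alpha=0.6)
        if col == "zeta_slope":
            ax.axhline(0.5, ls="--", c="0.3", lw=1)
            ax.axhline(1.0, ls=":", c="0.3", lw=1)
        ax.set_xticks(range(1, len(labels) + 1), labels)
        ax.set_ylabel(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def zeta_fan(dataset: StudyDataset, path=None, **moment_kwargs):
    """Per-individual zeta(q) curves against the Brownian and ballistic lines.

    Line transparency scales with the summary slope: opaque lines are
    near-ballistic individuals.
    """
    labels = sorted(dataset.treatments)
    fig, axes = plt.subplots(1, len(labels), figsize=(5 * len(labels), 4),
                             squeeze=False)
    for ax, lab in zip(axes[0], labels):
        slopes = []
        curves = []
        for traj in dataset.subset(lab):
            if traj.n_positions < 8:
                continue
            zf = zeta_exponents(moment_curve(traj, **moment_kwargs))
            if np.isfinite(zf.slope):
                slopes.append(zf.slope)
                curves.append(zf)
        lo, hi = (min(slopes), max(slopes)) if slopes else (0.0, 1.0)
        for zf in curves:
            alpha = 0.15 + 0.85 * ((zf.slope - lo) / (hi - lo) if hi > lo else 1.0)
            ax.plot(zf.q_grid, zf.zeta, color=_color(lab), alpha=float(alpha))
        qmax = max(zf.q_grid.max() for zf in curves) if curves else 3.0
        q = np.linspace(0, qmax, 50)
        ax.plot(q, q, ":", c="0.2", lw=1, label="ballistic: zeta(q)=q")
        ax.plot(q, q / 2, "--", c="0.2", lw=1, label="Brownian: zeta(q)=q/2")
        ax.set_xlabel("q")
        ax.set_ylabel("zeta(q)")
        ax.set_title(lab)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def entropy_vs_slope(metrics: pd.DataFrame, path=None):
    """Scatter of directional entropy against zeta slope, per treatment."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, grp in metrics.groupby("treatment"):
        ok = grp.dropna(subset=["zeta_slope", "entropy"])
        ax.plot(ok["zeta_slope"], ok["entropy"], "o", ms=5,
                color=_color(lab), label=f"{lab} (n={len(ok)})")
    ax.set_xlabel("slope of zeta(q)")
    ax.set_ylabel("directional entropy (nats)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
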