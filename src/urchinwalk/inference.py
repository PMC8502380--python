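"""Treatment-comparison statistics for two-group movement studies.

Four analyses mirror the study design:

* ``levene_test`` — equality of group variances (the diagnostic motivating
  the heteroscedastic model for the diffusion slopes);
* ``lm_treatment`` — one-way fixed-effects linear model (speed, straightness);
* ``gls_heteroscedastic`` — Gaussian mean comparison allowing a distinct
  residual variance per treatment group, the analogue of an identity
  variance structure per factor level; treatment tested by a likelihood-ratio
  chi-square on 1 df (Wald available);
* ``ancova_entropy`` — linear model of directional entropy on treatment, the
  diffusion summary slope, and their interaction, with sequential (type-I)
  F tests.

All likelihoods are maximised (ML, not REML) so that likelihood-ratio tests
across mean structures are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import InsufficientDataError


@dataclass(frozen=True)
class EffectTest:
    """One tested model term: name, df, statistic and p-value."""

    term: str
    df: int
    statistic_name: str  # "F" or "chi2"
    statistic: float
    p_value: float


@dataclass(frozen=True)
class ModelResult:
    """One fitted statistical comparison.

    ``group_sd_ratio`` (second group over first, in sorted-label order of
    the supplied ``order``) is populated by the heteroscedastic GLS only;
    ``aic`` counts every estimated parameter including variances, so AICs
    are comparable across the homoscedastic and heteroscedastic fits.
    """

    response: str
    model_type: str
    effects: tuple[EffectTest, ...]
    n_per_group: dict
    aic: float
    group_sd_ratio: float = float("nan")
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        """Table-shaped view: one row per tested effect."""
        return [
            {
                "response": self.response,
                "model_type": self.model_type,
                "effect": e.term,
                "df": e.df,
                "statistic": e.statistic_name,
                "value": e.statistic,
                "p_value": e.p_value,
            }
            for e in self.effects
        ]


def _two_groups(values, groups, min_per_group: int):
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D sequences")
    if np.any(~np.isfinite(y)):
        raise ValueError("values must be finite")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"exactly 2 group labels required, got {labels}")
    ya, yb = y[g == labels[0]], y[g == labels[1]]
    for lab, arr in zip(labels, (ya, yb)):
        if arr.size < min_per_group:
            raise InsufficientDataError(
                f"group {lab!r} has {arr.size} observations; "
                f"needs >= {min_per_group}"
            )
    return y, g, labels, ya, yb


def levene_test(values, groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances across groups.

    Absolute deviations from the group center (mean by default, median for
    the Brown-Forsythe variant) are compared by a one-way ANOVA F.

    Returns ``(statistic, p_value)``.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g).tolist()
    if len(labels) < 2:
        raise ValueError("Levene's test needs >= 2 groups")
    samples = [y[g == lab] for lab in labels]
    for lab, arr in zip(labels, samples):
        if arr.size < 2:
            raise InsufficientDataError(
                f"group {lab!r} has {arr.size} observation(s); needs >= 2"
            )
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    stat, p = scipy.stats.levene(*samples, center=center)
    return float(stat), float(p)


def lm_treatment(values, groups, response: str = "y") -> ModelResult:
    """One-way fixed-effects linear model for a two-level treatment.

    The treatment F on (1, n - 2) df equals the square of the
    pooled-variance two-sample t statistic.  AIC counts three parameters
    (two means, one residual variance).
    """
    y, g, labels, ya, yb = _two_groups(values, groups, min_per_group=2)
    if np.var(y) == 0.0:
        raise ValueError("response has zero total variance; model undefined")
    df = pd.DataFrame({"y": y, "treatment": g})
    fit = smf.ols("y ~ C(treatment)", data=df).fit()
    table = anova_lm(fit, typ=1)
    f_val = float(table.loc["C(treatment)", "F"])
    p_val = float(table.loc["C(treatment)", "PR(>F)"])
    aic = -2.0 * fit.llf + 2.0 * 3  # 2 means + 1 variance
    return ModelResult(
        response=response,
        model_type="linear model",
        effects=(
            EffectTest("treatment", 1, "F", f_val, p_val),
            EffectTest(
                "residuals", int(fit.df_resid), "F", float("nan"), float("nan")
            ),
        ),
        n_per_group={labels[0]: int(ya.size), labels[1]: int(yb.size)},
        aic=float(aic),
        group_means={labels[0]: float(ya.mean()), labels[1]: float(yb.mean())},
        group_sds={
            labels[0]: float(ya.std(ddof=1)),
            labels[1]: float(yb.std(ddof=1)),
        },
    )


def _hetero_loglik(ya, yb, ma, mb, va, vb) -> float:
    lla = -0.5 * ya.size * np.log(2 * np.pi * va) - 0.5 * np.sum(
        (ya - ma) ** 2
    ) / va
    llb = -0.5 * yb.size * np.log(2 * np.pi * vb) - 0.5 * np.sum(
        (yb - mb) ** 2
    ) / vb
    return float(lla + llb)


def gls_heteroscedastic(
    values,
    groups,
    response: str = "y",
    test: str = "lrt",
    tol: float = 1e-12,
    max_iter: int = 200,
) -> ModelResult:
    """Two-group Gaussian mean comparison with a variance per group.

    ML fit of the model ``y_gi ~ N(mu_g, sigma_g^2)``; the treatment effect
    is tested against the equal-means, per-group-variance null.  The full
    model has a closed-form ML solution (group means, group mean squared
    deviations); the null's common mean is found by a fixed-point iteration
    of inverse-variance weighting, which converges in a handful of steps.

    Parameters
    ----------
    test : {"lrt", "wald"}
        ``"lrt"`` (default) reports the likelihood-ratio chi-square on
        1 df; ``"wald"`` the squared Wald z using the ML variances.

    Notes
    -----
    ``extra["aic_homoscedastic"]`` carries the AIC of the equal-variance
    fit (three parameters) for variance-structure model selection.
    """
    y, g, labels, ya, yb = _two_groups(values, groups, min_per_group=3)
    na, nb = ya.size, yb.size
    ma, mb = float(ya.mean()), float(yb.mean())
    va = float(np.mean((ya - ma) ** 2))
    vb = float(np.mean((yb - mb) ** 2))
    if va == 0.0 or vb == 0.0:
        raise ValueError("a group has zero variance; GLS fit is degenerate")
    ll_full = _hetero_loglik(ya, yb, ma, mb, va, vb)

    if test == "lrt":
        # null: common mean, per-group variance; fixed-point ML
        mu = float(y.mean())
        for _ in range(max_iter):
            va0 = float(np.mean((ya - mu) ** 2))
            vb0 = float(np.mean((yb - mu) ** 2))
            mu_new = (na * ma / va0 + nb * mb / vb0) / (na / va0 + nb / vb0)
            if abs(mu_new - mu) <= tol * (1.0 + abs(mu)):
                mu = mu_new
                break
            mu = mu_new
        va0 = float(np.mean((ya - mu) ** 2))
        vb0 = float(np.mean((yb - mu) ** 2))
        ll_null = _hetero_loglik(ya, yb, mu, mu, va0, vb0)
        stat = max(0.0, 2.0 * (ll_full - ll_null))
    elif test == "wald":
        stat = (mb - ma) ** 2 / (va / na + vb / nb)
    else:
        raise ValueError("test must be 'lrt' or 'wald'")
    p = float(scipy.stats.chi2.sf(stat, df=1))

    # homoscedastic comparator for the variance-structure AIC screen
    v_pool = float(np.mean(np.concatenate([(ya - ma) ** 2, (yb - mb) ** 2])))
    ll_homo = _hetero_loglik(ya, yb, ma, mb, v_pool, v_pool)
    return ModelResult(
        response=response,
        model_type="generalized least squares",
        effects=(EffectTest("treatment", 1, "chi2", float(stat), p),),
        n_per_group={labels[0]: na, labels[1]: nb},
        aic=float(-2.0 * ll_full + 2.0 * 4),  # 2 means + 2 variances
        group_sd_ratio=float(np.sqrt(vb / va)),
        group_means={labels[0]: ma, labels[1]: mb},
        group_sds={labels[0]: float(np.sqrt(va)), labels[1]: float(np.sqrt(vb))},
        extra={"aic_homoscedastic": float(-2.0 * ll_homo + 2.0 * 3)},
    )


def ancova_entropy(
    entropy,
    zeta_slope,
    groups,
    response: str = "directional entropy",
    ss_type: int = 1,
) -> ModelResult:
    """Linear model entropy ~ treatment + slope + treatment:slope.

    Sequential (type-I) F tests by default, each on 1 df with n - 4
    residual df; ``ss_type=2`` or ``3`` gives marginal tests instead.

    Raises
    ------
    InsufficientDataError
        Fewer than 8 observations.
    ValueError
        A constant predictor, or the slope constant within both groups
        (the interaction is then collinear).
    """
    y = np.asarray(entropy, dtype=float)
    x = np.asarray(zeta_slope, dtype=float)
    g = np.asarray(groups)
    if not (y.shape == x.shape == g.shape) or y.ndim != 1:
        raise ValueError("entropy, zeta_slope, groups must be equal-length 1-D")
    if y.size < 8:
        raise InsufficientDataError(
            f"ANCOVA needs n >= 8 observations, got {y.size}"
        )
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"exactly 2 group labels required, got {labels}")
    if np.ptp(x) == 0.0:
        raise ValueError("zeta_slope is constant; slope term undefined")
    if all(np.ptp(x[g == lab]) == 0.0 for lab in labels):
        raise ValueError(
            "zeta_slope constant within both groups; interaction collinear"
        )
    df = pd.DataFrame({"H": y, "slope": x, "treatment": g})
    fit = smf.ols("H ~ C(treatment) + slope + C(treatment):slope", data=df).fit()
    table = anova_lm(fit, typ=ss_type)
    effects = []
    name_map = {
        "C(treatment)": "treatment",
        "slope": "slope",
        "C(treatment):slope": "treatment:slope",
    }
    for raw, clean in name_map.items():
        effects.append(
            EffectTest(
                clean,
                int(table.loc[raw, "df"]),
                "F",
                float(table.loc[raw, "F"]),
                float(table.loc[raw, "PR(>F)"]),
            )
        )
    effects.append(
        EffectTest("residuals", int(fit.df_resid), "F", float("nan"), float("nan"))
    )
    sizes = {lab: int(np.sum(g == lab)) for lab in labels}
    return ModelResult(
        response=response,
        model_type="linear model",
        effects=tuple(effects),
        n_per_group=sizes,
        aic=float(-2.0 * fit.llf + 2.0 * 5),  # 4 coefficients + 1 variance
    )
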