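"""Statistical machinery for the group comparisons.

Implements the inference chain applied to per-participant summaries:
pooled-variance two-sample t tests (from raw data or from printed summary
statistics), the 2x2 mixed ANOVA for the valence x age interaction via
its exact difference/mean-score reduction, the covariate-adjusted ANCOVA,
Pearson and partial correlations, and Fisher r-to-z comparisons of
correlation coefficients.

The 2x2 mixed design admits an exact reduction: with two within-subject
levels, the valence x group interaction F(1, N-2) equals the squared
pooled two-sample t comparing the per-participant difference scores
(here, the update bias) between groups; the valence main effect tests the
unweighted grand mean of the group difference-score means against zero
with the same pooled error; and the group main effect is the squared
two-sample t on each participant's mean across the two valence levels.
This reduction is algebraically identical to the sum-to-zero cell-means
least-squares fit and is what we implement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "StatResult",
    "AnovaTable",
    "two_sample_t_summary",
    "two_sample_t",
    "mixed_anova_2x2",
    "ancova_interaction",
    "pearson",
    "partial_pearson",
    "fisher_z_compare",
    "fisher_z_compare_dependent",
    "ROI_BONFERRONI_ALPHA",
]

#: Familywise threshold for the four primary ROI correlations
#: (0.05 corrected for four tests).
ROI_BONFERRONI_ALPHA = 0.0125


@dataclass
class StatResult:
    """A named test statistic with degrees of freedom and p-value."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    tails: str = "two"
    n: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p must be in [0, 1], got {self.p}")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "tails": self.tails,
        }
        if self.n is not None:
            d["n"] = self.n
        d.update(self.extra)
        return d


@dataclass
class AnovaTable:
    """Results of the 2x2 mixed ANOVA (valence within, age group between)."""

    valence: StatResult
    age: StatResult
    interaction: StatResult
    n: int
    group_sizes: dict
    n_covariates: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "group_sizes": self.group_sizes,
            "n_covariates": self.n_covariates,
            "valence": self.valence.to_dict(),
            "age": self.age.to_dict(),
            "interaction": self.interaction.to_dict(),
        }


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def two_sample_t_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    name: str = "two-sample t",
) -> StatResult:
    """Pooled-variance (Student) two-sample t from summary statistics.

    The statistic's sign follows ``mean2 - mean1``, so when called as
    (young, older) a positive t means the older group scored higher.
    Degrees of freedom are n1 + n2 - 2 (pooled, not Welch).
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp = _pooled_sd(sd1, n1, sd2, n2)
    if sp == 0.0:
        if mean1 == mean2:
            raise ValueError("zero pooled variance with equal means: t undefined")
        t = math.inf if mean2 > mean1 else -math.inf
        return StatResult(name, t, (n1 + n2 - 2,), 0.0, "two", n=n1 + n2)
    df = n1 + n2 - 2
    t = (mean2 - mean1) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(name, t, (df,), float(p), "two", n=n1 + n2)


def two_sample_t(x, y, name: str = "two-sample t") -> StatResult:
    """Pooled two-sample t on raw data; sign follows mean(y) - mean(x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return two_sample_t_summary(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
        name=name,
    )


def mixed_anova_2x2(
    table: pd.DataFrame,
    group_col: str = "age_group",
    desirable_col: str = "mean_update_desirable",
    undesirable_col: str = "mean_update_undesirable",
) -> AnovaTable:
    """2x2 mixed ANOVA (valence within-subjects, group between-subjects)
    via the exact difference/mean-score reduction.

    ``table`` must contain one row per participant with the two
    within-condition values and the group label.  All three effects carry
    df (1, N-2).
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 participants, got {n1} and {n2}")
    n = n1 + n2
    df_err = n - 2

    d1 = (g1[desirable_col] - g1[undesirable_col]).to_numpy(float)
    d2 = (g2[desirable_col] - g2[undesirable_col]).to_numpy(float)
    m1 = ((g1[desirable_col] + g1[undesirable_col]) / 2.0).to_numpy(float)
    m2 = ((g2[desirable_col] + g2[undesirable_col]) / 2.0).to_numpy(float)

    sp_d = _pooled_sd(d1.std(ddof=1), n1, d2.std(ddof=1), n2)
    inv_n = 1.0 / n1 + 1.0 / n2

    # interaction: two-sample t on the difference scores, squared
    t_int = (d2.mean() - d1.mean()) / (sp_d * math.sqrt(inv_n)) if sp_d > 0 else np.nan
    # valence main effect: unweighted grand mean of group difference means
    grand = 0.5 * (d1.mean() + d2.mean())
    t_val = grand / (sp_d * 0.5 * math.sqrt(inv_n)) if sp_d > 0 else np.nan
    # age main effect: two-sample t on the per-participant valence means
    sp_m = _pooled_sd(m1.std(ddof=1), n1, m2.std(ddof=1), n2)
    t_age = (m2.mean() - m1.mean()) / (sp_m * math.sqrt(inv_n)) if sp_m > 0 else np.nan

    def _f(name: str, t: float) -> StatResult:
        f = t * t
        p = float(stats.f.sf(f, 1, df_err)) if np.isfinite(f) else float("nan")
        return StatResult(name, float(f), (1, df_err), p, "two", n=n)

    return AnovaTable(
        valence=_f("valence main effect", t_val),
        age=_f("age main effect", t_age),
        interaction=_f("valence x age interaction", t_int),
        n=n,
        group_sizes={groups[0]: n1, groups[1]: n2},
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns involved in a rank deficiency (QR diagnostic)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.where(diag <= tol)[0]]


def ancova_interaction(
    table: pd.DataFrame,
    covariate_columns: list[str],
    group_col: str = "age_group",
    response_col: str = "update_bias",
) -> StatResult:
    """Covariate-adjusted valence x age interaction.

    The per-participant update bias already encodes the within-subject
    valence contrast, so regressing it on group plus mean-centred
    covariates yields the interaction term of the covariate-adjusted
    mixed model: F(1, N - 2 - k) is the squared t of the group
    coefficient.  With zero covariates this reproduces the unadjusted
    mixed-ANOVA interaction row exactly.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    data = table.dropna(subset=[response_col] + list(covariate_columns))
    n = len(data)
    k = len(covariate_columns)
    if n < k + 3:
        raise ValueError(f"need N > n_covariates + 2, got N={n}, k={k}")

    y = data[response_col].to_numpy(float)
    g = (data[group_col] == groups[1]).to_numpy(float)  # second group indicator
    cov = data[list(covariate_columns)].to_numpy(float) if k else np.empty((n, 0))
    cov = cov - cov.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(n), g, cov])
    names = ["intercept", group_col] + list(covariate_columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")

    fit = sm.OLS(y, X).fit()
    t_group = float(fit.tvalues[1])
    df_den = n - 2 - k
    f = t_group**2
    p = float(stats.f.sf(f, 1, df_den))
    return StatResult(
        "valence x age interaction (covariate-adjusted)",
        f,
        (1, df_den),
        p,
        "two",
        n=n,
        extra={"n_covariates": k, "group_coefficient": float(fit.params[1])},
    )


def pearson(x, y, name: str = "Pearson r", tails: str = "two") -> StatResult:
    """Product-moment correlation with p from the t transform,
    t = r sqrt(n-2) / sqrt(1-r^2), df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p_two = stats.pearsonr(x, y)
    p = float(p_two) if tails == "two" else float(p_two) / 2.0
    return StatResult(name, float(r), (n - 2,), p, tails, n=n)


def partial_pearson(
    x, y, controls, name: str = "partial Pearson r", tails: str = "two"
) -> StatResult:
    """Correlation of the least-squares residuals of x and y on the
    control matrix; df = n - 2 - n_controls."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.asarray(controls, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, k = Z.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y and controls must have matching length")
    if n <= k + 2:
        raise ValueError(f"need n > n_controls + 2, got n={n}, k={k}")
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient control matrix")
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is an exact linear function of the controls")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * math.sqrt(df) / math.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    if tails == "one":
        p /= 2.0
    return StatResult(name, r, (df,), min(p, 1.0), tails, n=n)


def fisher_z_compare(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    tails: str = "one",
    name: str = "Fisher r-to-z comparison",
) -> StatResult:
    """Compare two independent correlations via the variance-stabilising
    transform: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).

    One-tailed by default (directional comparisons of correlation
    strength); the statistic's sign follows r1 - r2.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = float(stats.norm.sf(abs(z)))
    if tails == "two":
        p *= 2.0
    return StatResult(name, z, (math.inf,), p, tails, n=n1 + n2)


def fisher_z_compare_dependent(
    r1: float,
    r2: float,
    r12: float,
    n: int,
    tails: str = "one",
    name: str = "Steiger dependent-correlation comparison",
) -> StatResult:
    """Steiger's Z1* for two overlapping dependent correlations.

    ``r1`` and ``r2`` share a variable (e.g. update bias correlated with
    dorsal and with ventral volume in the same participants) and ``r12``
    is the correlation between the two non-shared variables.  Provided
    behind this separate entry point; the independent-samples form above
    is the default used to mirror the original analysis.
    """
    for label, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if abs(r) >= 1.0:
            raise ValueError(f"|{label}| must be < 1, got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    rbar = 0.5 * (r1 + r2)
    rbar2 = rbar * rbar
    psi = r12 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r12 * r12)
    s = psi / (1.0 - rbar2) ** 2
    z = (math.atanh(r1) - math.atanh(r2)) * math.sqrt((n - 3) / (2.0 - 2.0 * s))
    p = float(stats.norm.sf(abs(z)))
    if tails == "two":
        p *= 2.0
    return StatResult(name, z, (math.inf,), p, tails, n=n)
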