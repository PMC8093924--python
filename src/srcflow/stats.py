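"""Behavioral metrics and group statistics.

Implements the statistics layer of the case-control analysis: flanker
behavioral summaries (accuracy, reaction time and its variability on
correct trials only), sample-characterization tests (pooled t,
Yates-corrected chi-square), the MANOVA -> ANOVA -> ANCOVA cascade on
the four band powers (theta, alpha, low beta, high beta), and Pearson
partial correlations controlling for age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatTestResult",
    "behavioral_metrics",
    "two_group_t",
    "chi2_yates",
    "anova_group",
    "ancova_group",
    "manova_bands",
    "partial_correlation",
    "manova_then_anovas",
]


@dataclass
class StatTestResult:
    """A single test outcome: statistic, degrees of freedom, p-value."""

    test: str
    statistic: float
    df: tuple | float
    p: float
    effect_context: str = ""

    def __repr__(self):  # compact, table-friendly
        df = self.df if not isinstance(self.df, tuple) else ",".join(
            f"{d:g}" for d in self.df
        )
        return f"{self.test}({df}) = {self.statistic:.3g}, p = {self.p:.4g}"


# ---------------------------------------------------------------------------
# behavioral metrics
# ---------------------------------------------------------------------------


def behavioral_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy (%), mean RT and RT SD on correct trials.

    No-response trials (rt absent) count as incorrect for accuracy but are
    excluded from RT statistics, which additionally use correct trials
    only.  RT statistics are NaN when fewer than 2 correct responded
    trials exist.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rows = []
    for cond, sub in trials.groupby("condition", sort=True):
        if len(sub) == 0:
            raise ValueError(f"no trials in condition {cond}")
        acc = 100.0 * sub["correct"].sum() / len(sub)
        ok = sub["correct"] & sub["rt"].notna()
        if ok.sum() >= 2:
            rt_mean = float(sub.loc[ok, "rt"].mean())
            rt_sd = float(sub.loc[ok, "rt"].std(ddof=1))
        else:
            rt_mean = rt_sd = np.nan
        rows.append(
            dict(condition=cond, accuracy_pct=float(acc), rt_mean_ms=rt_mean,
                 rt_sd_ms=rt_sd, n_trials=len(sub), n_correct=int(sub["correct"].sum()))
        )
    return pd.DataFrame(rows).set_index("condition")


# ---------------------------------------------------------------------------
# sample characterization
# ---------------------------------------------------------------------------


def two_group_t(values: np.ndarray, groups: np.ndarray) -> StatTestResult:
    """Two-tailed pooled-variance t-test between the two group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return StatTestResult(
        test="t",
        statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        effect_context=f"{names[0]} vs {names[1]}",
    )


def chi2_yates(counts: np.ndarray) -> StatTestResult:
    """Yates-continuity-corrected chi-square on a 2x2 table (df = 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=True)
    return StatTestResult(test="chi2_yates", statistic=float(stat), df=float(df), p=float(p))


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA
# ---------------------------------------------------------------------------


def _group_dummy(groups: np.ndarray) -> np.ndarray:
    names = pd.unique(np.asarray(groups))
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    return (np.asarray(groups) == names[1]).astype(float)


def anova_group(dep: np.ndarray, groups: np.ndarray) -> StatTestResult:
    """One-way two-group ANOVA: F with df (1, N - 2).

    Algebraically identical to the squared pooled t."""
    y = np.asarray(dep, dtype=float)
    g = _group_dummy(groups)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    names = pd.unique(np.asarray(groups))
    f, p = sps.f_oneway(y[g == 0], y[g == 1])
    return StatTestResult(
        test="anova_F",
        statistic=float(f),
        df=(1.0, float(len(y) - 2)),
        p=float(p),
        effect_context=f"{names[0]} vs {names[1]}",
    )


def ancova_group(
    dep: np.ndarray, groups: np.ndarray, covariate: np.ndarray, name: str = "covariate"
) -> StatTestResult:
    """Group F from the linear model dep ~ group + covariate.

    Type-III style partial F for the group term with df (1, N - 3); one
    covariate per call, mirroring per-covariate re-runs of significant
    group effects.
    """
    y = np.asarray(dep, dtype=float)
    g = _group_dummy(groups)
    z = np.asarray(covariate, dtype=float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), g, z])
    X_red = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(X_full) < 3:
        raise ValueError("rank-deficient design (covariate confounded with group?)")
    rss_full = _rss(y, X_full)
    rss_red = _rss(y, X_red)
    df_resid = n - 3
    f = (rss_red - rss_full) / (rss_full / df_resid)
    p = float(sps.f.sf(f, 1, df_resid))
    return StatTestResult(
        test="ancova_F", statistic=float(f), df=(1.0, float(df_resid)), p=p,
        effect_context=f"controlling for {name}",
    )


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# MANOVA on band powers
# ---------------------------------------------------------------------------


def manova_bands(band_powers: np.ndarray, groups: np.ndarray) -> StatTestResult:
    """Wilks' Lambda MANOVA with Rao's F approximation.

    ``band_powers`` is (n_subjects, q) — typically the four band powers —
    and ``groups`` a two-level factor.  For two groups Rao's F is exact
    with df (q, N - q - 1); with q = 4 and N = 74 this is the (4, 69)
    pattern.
    """
    Y = np.asarray(band_powers, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    n, q = Y.shape
    g = len(names)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = [(groups == nm).sum() for nm in names]
    if min(counts) < q + 2:
        raise ValueError("need at least q + 2 subjects per group")

    grand = Y.mean(axis=0)
    W = np.zeros((q, q))
    B = np.zeros((q, q))
    for nm in names:
        sub = Y[groups == nm]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        delta = (mu - grand)[:, None]
        B += len(sub) * (delta @ delta.T)
    sign, logdet_W = np.linalg.slogdet(W)
    if sign <= 0:
        raise ValueError("singular within-group covariance")
    sign_t, logdet_T = np.linalg.slogdet(W + B)
    lam = float(np.exp(logdet_W - logdet_T))

    # Rao's F approximation (exact for g = 2 or q <= 2)
    p_ = q
    vh = g - 1.0
    ve = n - g
    m = ve + vh - (p_ + vh + 1.0) / 2.0
    s = np.sqrt(
        (p_**2 * vh**2 - 4.0) / (p_**2 + vh**2 - 5.0)
    ) if (p_**2 + vh**2 - 5.0) > 0 else 1.0
    df1 = p_ * vh
    df2 = m * s - p_ * vh / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1
    p_val = float(sps.f.sf(f, df1, df2))
    return StatTestResult(
        test="manova_wilks",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p=p_val,
        effect_context=f"Wilks lambda = {lam:.4f}",
    )


def manova_then_anovas(
    band_powers: np.ndarray,
    groups: np.ndarray,
    band_names: list[str] | None = None,
    gate_alpha: float = 0.05,
) -> tuple[StatTestResult, list[StatTestResult]]:
    """MANOVA gate followed by per-band univariate ANOVAs.

    Univariate follow-ups run only when the MANOVA p falls below
    ``gate_alpha``; otherwise the returned list is empty.
    """
    man = manova_bands(band_powers, groups)
    follow: list[StatTestResult] = []
    if man.p < gate_alpha:
        names = band_names or [f"band{i}" for i in range(band_powers.shape[1])]
        for i, nm in enumerate(names):
            r = anova_group(band_powers[:, i], groups)
            r.effect_context = nm
            follow.append(r)
    return man, follow


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> StatTestResult:
    """Pearson correlation of x and y after regressing out one covariate.

    r is computed between the residuals of x ~ covariate and
    y ~ covariate; the p-value is t-based with df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    Z = np.column_stack([np.ones(n), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance after removing the covariate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatTestResult(test="partial_r", statistic=r, df=float(df), p=p)
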