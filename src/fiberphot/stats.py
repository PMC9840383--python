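"""Repeated-measures inference on per-animal peri-event summaries.

Implements the inferential layer used on per-animal bin means:
one-way repeated-measures (RM) ANOVA with Dunnett contrasts against
the pre-onset baseline bin, two-way RM ANOVA for the time ×
(signal vs random) interaction with Bonferroni post hocs, and the
unpaired two-tailed t test used for group comparisons.

Sphericity is assumed (uncorrected integer degrees of freedom); a
Greenhouse–Geisser correction is available but off by default.
Dunnett adjustment uses a seeded Monte Carlo estimate of the max-|t|
null distribution over the same subjects × levels layout, which also
yields simultaneous confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "Contrast",
    "rm_anova_oneway",
    "dunnett_vs_control",
    "rm_anova_twoway_interaction",
    "unpaired_t",
    "paired_t",
]

ALPHA = 0.05


@dataclass(frozen=True)
class Contrast:
    """One comparison vs the control level."""

    level: str
    estimate: float
    t: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    adjust: str


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    contrasts: tuple = ()
    sphericity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float


def _check_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D subjects × levels matrix")
    if np.any(~np.isfinite(X)):
        raise ValueError("design matrix is incomplete (non-finite cells)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    return X


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the sample covariance of levels."""
    S = np.cov(X, rowvar=False)
    k = S.shape[0]
    d = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = (np.trace(d)) ** 2
    den = (k - 1) * np.sum(d * d)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_oneway(X: np.ndarray, correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects × levels matrix.

    F = MS_levels / MS_error with the within-subject decomposition
    SS_error = SS_within − SS_subjects; df1 = k−1, df2 = (k−1)(n−1).
    With ``correction=True`` a Greenhouse–Geisser epsilon scales both
    dfs before the p value is computed.
    """
    X = _check_design(X)
    n, k = X.shape
    grand = X.mean()
    ss_levels = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_levels - ss_subjects
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df2
    # guard the 0/0 case (both SS at rounding level) -> no level effect
    tiny = 1e-12 * max(ss_total, 1e-300)
    if ss_error <= tiny:
        F = 0.0 if ss_levels <= tiny else np.inf
    else:
        F = (ss_levels / df1) / ms_error
    eps = _gg_epsilon(X) if correction else 1.0
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return AnovaResult(float(F), df1 * eps, df2 * eps, p,
                       sphericity_corrected=correction)


def dunnett_vs_control(
    X: np.ndarray,
    control: int = 0,
    level_labels: list[str] | None = None,
    adjust: str = "dunnett",
    n_mc: int = 100_000,
    seed: int = 12345,
    alpha: float = ALPHA,
) -> tuple[Contrast, ...]:
    """Paired comparisons of every level against a control level.

    Each contrast is a paired t statistic on the per-subject
    differences.  ``adjust="dunnett"`` calibrates adjusted p values and
    simultaneous CIs against the Monte Carlo null distribution of the
    maximum |t| over the same layout (n subjects, k levels, iid
    normal); ``adjust="bonferroni"`` uses the conservative closed form.

    With a single non-control level the adjusted p equals the plain
    paired t p (both adjustments are exact there).
    """
    X = _check_design(X)
    n, k = X.shape
    if not 0 <= control < k:
        raise ValueError(f"control index {control} out of range")
    if adjust not in ("dunnett", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = level_labels or [f"level{j}" for j in range(k)]
    others = [j for j in range(k) if j != control]
    m = len(others)
    if m < 1:
        raise ValueError("need at least one non-control level")

    def contrast_t(data: np.ndarray) -> np.ndarray:
        d = data[:, others] - data[:, [control]]
        se = d.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, d.mean(axis=0) / se, 0.0)
        return t

    t_obs = contrast_t(X)
    d_mean = (X[:, others] - X[:, [control]]).mean(axis=0)
    d_se = (X[:, others] - X[:, [control]]).std(axis=0, ddof=1) / np.sqrt(n)

    if m == 1:
        p_adj = np.array([2.0 * sps.t.sf(abs(t_obs[0]), n - 1)])
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, m * 2.0 * sps.t.sf(np.abs(t_obs), n - 1))
        crit = sps.t.ppf(1 - alpha / (2 * m), n - 1)
    else:
        rng = np.random.default_rng(seed)
        max_abs_t = np.empty(n_mc)
        block = 2000  # vectorize in blocks to bound memory
        for start in range(0, n_mc, block):
            b = min(block, n_mc - start)
            null = rng.standard_normal((b, n, k))
            d = null[:, :, others] - null[:, :, [control]]
            se = d.std(axis=1, ddof=1) / np.sqrt(n)
            t = d.mean(axis=1) / se
            max_abs_t[start:start + b] = np.abs(t).max(axis=1)
        # add-one smoothing keeps p in (0, 1]
        p_adj = np.array([
            (np.sum(max_abs_t >= abs(t0)) + 1) / (n_mc + 1) for t0 in t_obs
        ])
        crit = float(np.quantile(max_abs_t, 1 - alpha))

    return tuple(
        Contrast(
            level=labels[j],
            estimate=float(d_mean[i]),
            t=float(t_obs[i]),
            p_adjusted=float(p_adj[i]),
            ci_low=float(d_mean[i] - crit * d_se[i]),
            ci_high=float(d_mean[i] + crit * d_se[i]),
            adjust=adjust if m > 1 else "none",
        )
        for i, j in enumerate(others)
    )


def rm_anova_twoway_interaction(Y: np.ndarray) -> AnovaResult:
    """Interaction F of a fully within-subject two-way design.

    ``Y`` has shape (subjects, a, b) — e.g. factor A = time (baseline
    vs event window) and factor B = condition (time-locked signal vs
    random sampling).  The interaction is tested against the
    subject × A × B residual:

        F = [SS_AB / (a−1)(b−1)] / [SS_ABS / (a−1)(b−1)(n−1)]

    In the 2 × 2 case this F equals the squared paired t statistic on
    the per-subject difference of differences.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("two-way design must be subjects × a × b")
    if np.any(~np.isfinite(Y)):
        raise ValueError("design is incomplete (non-finite cells)")
    n, a, b = Y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    grand = Y.mean()
    mj = Y.mean(axis=(0, 2))        # A level means
    mk = Y.mean(axis=(0, 1))        # B level means
    mjk = Y.mean(axis=0)            # cell means
    ss_ab = n * np.sum((mjk - mj[:, None] - mk[None, :] + grand) ** 2)
    # subject-wise residual for the three-way (error) term
    mi = Y.mean(axis=(1, 2))        # subject means
    mij = Y.mean(axis=2)            # subject × A
    mik = Y.mean(axis=1)            # subject × B
    resid = (
        Y
        - mjk[None, :, :]
        - mij[:, :, None]
        - mik[:, None, :]
        + mj[None, :, None]
        + mk[None, None, :]
        + mi[:, None, None]
        - grand
    )
    ss_err = np.sum(resid**2)
    df1 = (a - 1) * (b - 1)
    df2 = (a - 1) * (b - 1) * (n - 1)
    ms_err = ss_err / df2
    tiny = 1e-12 * max(float(np.sum((Y - grand) ** 2)), 1e-300)
    if ss_err <= tiny:
        F = 0.0 if ss_ab <= tiny else np.inf
    else:
        F = (ss_ab / df1) / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)


def paired_t(a: np.ndarray, b: np.ndarray, alpha: float = ALPHA) -> TTestResult:
    """Paired two-tailed t test with a CI on the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    se = d.std(ddof=1) / np.sqrt(n)
    if se == 0:
        if d.mean() == 0:
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero variance with nonzero mean difference")
    else:
        t = d.mean() / se
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    crit = sps.t.ppf(1 - alpha / 2, n - 1)
    return TTestResult(float(t), n - 1, float(p), float(d.mean()),
                       float(d.mean() - crit * se), float(d.mean() + crit * se))


def unpaired_t(a: np.ndarray, b: np.ndarray, alpha: float = ALPHA) -> TTestResult:
    """Unpaired two-tailed t test (pooled variance), df = n1 + n2 − 2.

    Zero pooled variance with equal means yields t = 0, p = 1; zero
    pooled variance with unequal means is an error (the statistic is
    undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 values per group")
    df = n1 + n2 - 2
    diff = a.mean() - b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means")
    else:
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df)
    crit = sps.t.ppf(1 - alpha / 2, df)
    return TTestResult(float(t), df, float(p), float(diff),
                       float(diff - crit * se), float(diff + crit * se))
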