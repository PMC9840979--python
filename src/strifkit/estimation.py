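"""Estimation statistics for behavioral contrasts.

Effect sizes are reported alongside interval estimates instead of bare
p-values: Glass Δ (mean difference over the control SD), Cohen's d (mean
difference over the pooled SD; for paired designs, over the SD of the
within-pair differences), a bias-corrected and accelerated (BCa) bootstrap
95% CI of the mean difference, and a two-sided permutation test on the mean
difference.  Magnitudes follow the conventional 0.2 / 0.5 / 0.8 cuts
(negligible / small / moderate / large).

The permutation test enumerates all arrangements exactly when feasible
(label reassignments for unpaired data, sign flips for paired data) and
counts the identity arrangement in both numerator and denominator, so p is
never zero.  All resampling is seeded and reproducible.

No multiple-testing correction is applied by default (a deliberate caveat);
Benjamini-Hochberg adjustment is available separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectResult",
    "RegressionResult",
    "glass_delta",
    "cohens_d",
    "bca_ci",
    "permutation_test",
    "compare_groups",
    "magnitude_band",
    "effect_matrix",
    "delta_regression",
    "power_ttest",
    "bh_adjust",
]

_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"))


def magnitude_band(effect: float) -> str:
    """Conventional interpretation of a standardized effect size."""
    a = abs(effect)
    for cut, name in _BANDS:
        if a < cut:
            return name
    return "large"


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def glass_delta(experiment, control) -> float:
    """(mean_exp - mean_ctrl) / SD(ctrl), sample SD with n-1 denominator."""
    exp = np.asarray(experiment, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control values")
    sd = _sd(ctrl)
    if sd == 0:
        raise ValueError("control SD is zero; Glass delta undefined")
    return float((exp.mean() - ctrl.mean()) / sd)


def cohens_d(experiment, control, paired: bool = False, standardizer: str = "diff") -> float:
    """Standardized mean difference (experiment - control).

    Unpaired: pooled SD with n-1 weights.  Paired: the mean within-pair
    difference over the SD of the differences (``standardizer="diff"``,
    default) or over the average of the two group SDs
    (``standardizer="average"``).
    """
    exp = np.asarray(experiment, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if paired:
        if len(exp) != len(ctrl):
            raise ValueError("paired samples must have equal length")
        if len(exp) < 2:
            raise ValueError("need at least 2 pairs")
        diff = exp - ctrl
        if standardizer == "diff":
            s = _sd(diff)
        elif standardizer == "average":
            s = (_sd(exp) + _sd(ctrl)) / 2
        else:
            raise ValueError(f"unknown standardizer {standardizer!r}")
        if s == 0:
            raise ValueError("zero standardizer; d undefined")
        return float(diff.mean() / s)
    if len(exp) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 values per group")
    n1, n2 = len(exp), len(ctrl)
    pooled = math.sqrt(
        ((n1 - 1) * np.var(exp, ddof=1) + (n2 - 1) * np.var(ctrl, ddof=1))
        / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD; d undefined")
    return float((exp.mean() - ctrl.mean()) / pooled)


def _bca_interval(
    boots: np.ndarray, theta_hat: float, jack: np.ndarray, alpha: float
) -> tuple[float, float]:
    """BCa endpoints from a bootstrap distribution and jackknife values."""
    frac = np.mean(boots < theta_hat)
    if frac in (0.0, 1.0):
        raise FloatingPointError("degenerate bootstrap distribution")
    z0 = stats.norm.ppf(frac)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boots, adj)
    return float(lo), float(hi)


def bca_ci(
    samples,
    statistic=np.mean,
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    samples2=None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI.

    One-sample by default; with ``samples2`` the statistic is applied to each
    group and the interval covers ``statistic(samples) -
    statistic(samples2)`` (independent resampling per group, jackknife over
    the concatenation).  Degenerate resamples (all bootstrap replicates
    equal) fall back to the percentile interval with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    if samples2 is None:
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boots = np.apply_along_axis(statistic, 1, x[idx]) if statistic is not np.mean else x[idx].mean(axis=1)
        theta = float(statistic(x))
        if statistic is np.mean:
            jack = (x.sum() - x) / (len(x) - 1)
        else:
            jack = np.array([statistic(np.delete(x, i)) for i in range(len(x))])
    else:
        y = np.asarray(samples2, dtype=float)
        if len(y) < 5:
            raise ValueError("need at least 5 observations per group")
        bx = x[rng.integers(0, len(x), size=(n_boot, len(x)))]
        by = y[rng.integers(0, len(y), size=(n_boot, len(y)))]
        if statistic is np.mean:
            boots = bx.mean(axis=1) - by.mean(axis=1)
        else:
            boots = np.apply_along_axis(statistic, 1, bx) - np.apply_along_axis(
                statistic, 1, by
            )
        theta = float(statistic(x) - statistic(y))
        jack = np.array(
            [statistic(np.delete(x, i)) - statistic(y) for i in range(len(x))]
            + [statistic(x) - statistic(np.delete(y, j)) for j in range(len(y))]
        )
    if np.ptp(boots) == 0:
        return float(boots[0]), float(boots[0])
    try:
        return _bca_interval(boots, theta, jack, alpha)
    except FloatingPointError:
        warnings.warn(
            "degenerate bootstrap distribution; falling back to percentile CI",
            stacklevel=2,
        )
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)


_EXACT_LIMIT = 20000


def permutation_test(
    group_a,
    group_b,
    paired: bool = False,
    n_perm: int = 10000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Two-sided permutation test on the mean difference.

    Unpaired: group labels are reshuffled; paired: the signs of within-pair
    differences are flipped.  With ``method="auto"`` all arrangements are
    enumerated exactly when their number is at most 20,000, otherwise
    ``n_perm`` random arrangements are drawn; ``"exact"`` and ``"sampled"``
    force one route.  The identity arrangement is counted in numerator and
    denominator, so p > 0 always.
    """
    if method not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        d = a - b
        n = len(d)
        observed = abs(d.mean())
        use_exact = method == "exact" or (method == "auto" and 2**n <= _EXACT_LIMIT)
        if use_exact:
            if 2**n > _EXACT_LIMIT:
                raise ValueError("too many sign arrangements for exact enumeration")
            signs = np.array(
                [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
            )
            means = np.abs((signs * d).mean(axis=1))
            return float(np.mean(means >= observed - 1e-12))
        if n_perm < 1000:
            raise ValueError("n_perm must be >= 1000")
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm - 1, n))
        means = np.abs((signs * d).mean(axis=1))
        hits = 1 + int(np.sum(means >= observed - 1e-12))
        return hits / n_perm
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    observed = abs(a.mean() - b.mean())
    total = math.comb(n1 + n2, n1)
    use_exact = method == "exact" or (method == "auto" and total <= _EXACT_LIMIT)
    if use_exact:
        if total > _EXACT_LIMIT:
            raise ValueError("too many label arrangements for exact enumeration")
        hits = 0
        idx_all = range(n1 + n2)
        psum = pooled.sum()
        for comb in combinations(idx_all, n1):
            sa = pooled[list(comb)].sum()
            diff = abs(sa / n1 - (psum - sa) / n2)
            if diff >= observed - 1e-12:
                hits += 1
        return hits / total
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    hits = 1  # identity arrangement
    # vectorised shuffles in blocks
    block = 2000
    done = 0
    while done < n_perm - 1:
        m = min(block, n_perm - 1 - done)
        order = np.argsort(rng.random((m, n1 + n2)), axis=1)
        perm = pooled[order]
        diffs = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
        hits += int(np.sum(diffs >= observed - 1e-12))
        done += m
    return hits / n_perm


@dataclass
class EffectResult:
    """Complete estimation summary for one contrast."""

    label: str
    n_exp: int
    n_ctrl: int
    mean_difference: float
    cohens_d: float
    glass_delta: float  # nan for paired contrasts
    ci95: tuple[float, float]
    p_permutation: float
    magnitude: str
    paired: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_exp": self.n_exp,
            "n_ctrl": self.n_ctrl,
            "mean_difference": self.mean_difference,
            "cohens_d": self.cohens_d,
            "glass_delta": self.glass_delta,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_permutation": self.p_permutation,
            "magnitude": self.magnitude,
            "paired": self.paired,
            "seed": self.seed,
        }


def compare_groups(
    experiment,
    control,
    label: str = "",
    paired: bool = False,
    n_boot: int = 5000,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EffectResult:
    """One-stop contrast: effect sizes, BCa 95% CI of the mean difference,
    and a two-sided permutation p."""
    exp = np.asarray(experiment, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if paired:
        diff = exp - ctrl
        md = float(diff.mean())
        d = cohens_d(exp, ctrl, paired=True)
        gd = float("nan")
        ci = bca_ci(diff, np.mean, n_boot=n_boot, alpha=alpha, seed=seed)
    else:
        md = float(exp.mean() - ctrl.mean())
        d = cohens_d(exp, ctrl)
        gd = glass_delta(exp, ctrl)
        ci = bca_ci(exp, np.mean, n_boot=n_boot, alpha=alpha, seed=seed, samples2=ctrl)
    p = permutation_test(exp, ctrl, paired=paired, n_perm=n_perm, seed=seed)
    return EffectResult(
        label=label,
        n_exp=len(exp),
        n_ctrl=len(ctrl),
        mean_difference=md,
        cohens_d=d,
        glass_delta=gd,
        ci95=ci,
        p_permutation=p,
        magnitude=magnitude_band(d),
        paired=paired,
        seed=seed,
    )


def effect_matrix(
    results: list[EffectResult],
    keys: list[tuple[str, str]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble (intervention x parameter) effect-size and significance grids.

    ``keys[i]`` is the (intervention, parameter) cell of ``results[i]``.
    Returns ``(d_matrix, asterisk_mask)`` as aligned DataFrames; cells with no
    result are NaN / False.  Duplicate keys are an error.
    """
    if not results:
        raise ValueError("need at least one result")
    if len(keys) != len(results):
        raise ValueError("one key per result required")
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (intervention, parameter) keys")
    rows = sorted({k[0] for k in keys})
    cols = sorted({k[1] for k in keys})
    dmat = pd.DataFrame(np.nan, index=rows, columns=cols)
    marks = pd.DataFrame(False, index=rows, columns=cols)
    for res, (r, c) in zip(results, keys):
        dmat.loc[r, c] = res.cohens_d
        marks.loc[r, c] = res.p_permutation < alpha
    return dmat, marks


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2_adj: float
    p_slope: float
    n_points: int
    x_label: str = "x"
    y_label: str = "y"


def delta_regression(
    x_deltas, y_deltas, x_label: str = "x", y_label: str = "y"
) -> RegressionResult:
    """OLS of per-manipulation effect deltas: does one paradigm's change
    predict the other's?

    Reports the slope, adjusted R² ``1 - (1 - R²)(n - 1)/(n - 2)`` and a
    two-sided slope p from the t distribution with n - 2 df.
    """
    x = np.asarray(x_deltas, dtype=float)
    y = np.asarray(y_deltas, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero x-variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_adj=float(r2_adj),
        p_slope=float(res.pvalue),
        n_points=n,
        x_label=x_label,
        y_label=y_label,
    )


def power_ttest(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided two-sample t-test.

    Noncentral t with noncentrality ``d * sqrt(n/2)`` and ``2n - 2`` degrees
    of freedom.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if d < 0:
        raise ValueError("d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; none applied by
    default anywhere in the package)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
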