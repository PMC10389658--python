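"""Replication statistics for language-environment associations.

Covers the statistical toolkit of the analysis: ordinary least-squares
association with R^2 and a two-sided slope test, 2x2 Pearson chi-square
tests of trait presence against a dichotomised environmental variable,
boxplot-style group summaries by tone level, Welch two-group mean
comparisons, and a Pearson correlation matrix (correlogram).

All operations drop incomplete pairs (pairwise-complete deletion) and
record the dropped count in the result, so each analysis carries its own
effective n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """Ordinary least-squares fit of y on x."""

    n: int
    slope: float
    intercept: float
    r2: float
    p: float
    n_dropped: int = 0


@dataclass
class ContingencyResult:
    """Pearson chi-square on a 2x2 presence/absence table."""

    table: np.ndarray
    chi2: float
    p: float
    expected_minimum: float
    correction_applied: bool
    n_dropped: int = 0

    @property
    def low_expected(self) -> bool:
        """True when any expected cell count is below 5."""
        return self.expected_minimum < 5


def _paired(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int(len(x) - keep.sum())
    if dropped:
        logger.info("dropped %d incomplete pairs", dropped)
    return x[keep], y[keep], dropped


def linear_assoc(x, y) -> LinearFit:
    """Least-squares linear association with R^2 and slope p-value.

    R^2 is the squared Pearson correlation; ``p`` is the two-sided test on
    the slope.  A constant x is rejected; a constant y returns slope 0 and
    R^2 = 0 by convention (p = 1).
    """
    x, y, dropped = _paired(x, y)
    if len(x) < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("x has zero variance")
    if np.ptp(y) == 0:
        mean_y = float(y[0])
        return LinearFit(len(x), 0.0, mean_y, 0.0, 1.0, dropped)
    fit = sps.linregress(x, y)
    return LinearFit(
        n=len(x),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_dropped=dropped,
    )


def dichotomize(values, rule: str | Callable[[float], bool] = "median",
                threshold: float | None = None) -> np.ndarray:
    """Split a numeric vector into a high/low boolean vector.

    ``rule="median"`` marks values strictly above the median as True
    (exact-median ties join the lower group); ``rule="threshold"`` uses
    ``value > threshold``.  NaNs propagate as NaN-masked False with a
    warning left to the caller via the returned mask semantics — callers
    should drop missing values first.
    """
    x = np.asarray(values, dtype=float)
    if rule == "median":
        finite = x[np.isfinite(x)]
        if len(finite) == 0 or np.ptp(finite) == 0:
            raise ValidationError("cannot median-split an all-equal vector")
        cut = float(np.median(finite))
        return x > cut
    if rule == "threshold":
        if threshold is None:
            raise ValidationError("threshold rule requires a threshold value")
        return x > threshold
    raise ValidationError(f"unknown dichotomization rule {rule!r}")


def chi_square_presence(
    trait, env_high, correction: bool = False
) -> ContingencyResult:
    """Pearson chi-square of a binary trait against a binary environment.

    No Yates continuity correction is applied by default.  Pairs with a
    missing side are dropped; expected cell counts below 5 are flagged on
    the result.  A zero marginal row or column is rejected.
    """
    t = np.asarray(trait, dtype=float)
    e = np.asarray(env_high, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("trait and environment vectors must align")
    keep = np.isfinite(t) & np.isfinite(e)
    dropped = int(len(t) - keep.sum())
    t, e = t[keep].astype(bool), e[keep].astype(bool)
    table = np.array(
        [
            [np.sum(~t & ~e), np.sum(~t & e)],
            [np.sum(t & ~e), np.sum(t & e)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero marginal")
    chi2, p, _, expected = sps.chi2_contingency(table, correction=correction)
    result = ContingencyResult(
        table=table,
        chi2=float(chi2),
        p=float(p),
        expected_minimum=float(expected.min()),
        correction_applied=correction,
        n_dropped=dropped,
    )
    if result.low_expected:
        logger.warning(
            "chi-square: minimum expected cell count %.2f < 5",
            result.expected_minimum,
        )
    return result


def group_summary(values, level) -> pd.DataFrame:
    """Boxplot statistics of a variable per ordinal level (e.g. tone 0-3).

    Quartiles use linear interpolation (type 7); whiskers extend to the
    most extreme values within 1.5 IQR of the quartiles; values beyond the
    whiskers are listed as outliers.  Empty levels are omitted.
    """
    x = np.asarray(values, dtype=float)
    lv = np.asarray(level)
    keep = np.isfinite(x)
    x, lv = x[keep], lv[keep]
    rows = []
    for lev in sorted(set(lv.tolist())):
        grp = x[lv == lev]
        if len(grp) == 0:
            continue
        q1, med, q3 = np.quantile(grp, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        inside = grp[(grp >= q1 - 1.5 * iqr) & (grp <= q3 + 1.5 * iqr)]
        outliers = grp[(grp < q1 - 1.5 * iqr) | (grp > q3 + 1.5 * iqr)]
        rows.append(
            {
                "level": lev,
                "n": len(grp),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_lo": float(inside.min()),
                "whisker_hi": float(inside.max()),
                "outliers": sorted(outliers.tolist()),
            }
        )
    return pd.DataFrame(rows)


def two_group_means(values, flag) -> tuple[float, float, float | None]:
    """Group means and Welch's unequal-variance two-sided p-value.

    Returns ``(mean_true, mean_false, p)``; ``p`` is None when either
    group has fewer than 2 observations.  Identical samples give p = 1.
    """
    x = np.asarray(values, dtype=float)
    f = np.asarray(flag, dtype=bool)
    if x.shape != f.shape:
        raise ValidationError("values and flag must align")
    keep = np.isfinite(x)
    x, f = x[keep], f[keep]
    a, b = x[f], x[~f]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    mean_true, mean_false = float(np.mean(a)), float(np.mean(b))
    if len(a) < 2 or len(b) < 2:
        return mean_true, mean_false, None
    if np.ptp(a) == 0 and np.ptp(b) == 0 and mean_true == mean_false:
        return mean_true, mean_false, 1.0
    t = sps.ttest_ind(a, b, equal_var=False)
    return mean_true, mean_false, float(t.pvalue)


def correlogram(table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over the named columns.

    Pairwise-complete observations; a variable with zero variance is
    dropped from both rows and columns (its correlations are undefined).
    """
    if len(variables) < 2:
        raise ValidationError("need at least 2 variables")
    sub = table[list(variables)].astype(float)
    usable = [v for v in variables if np.ptp(sub[v].dropna().to_numpy()) > 0]
    skipped = set(variables) - set(usable)
    if skipped:
        logger.warning("correlogram: zero-variance variables omitted: %s", skipped)
    corr = sub[usable].corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


# -- optional plotting ---------------------------------------------------

def plot_scatter_fit(x, y, fit: LinearFit, xlabel: str, ylabel: str, path) -> None:
    """Scatter with the fitted line and R^2/p annotation, saved to path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(x, y, s=12, alpha=0.6)
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="crimson")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"$R^2$ = {fit.r2:.4f}, p = {fit.p:.2e}, n = {fit.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlogram(corr: pd.DataFrame, path) -> None:
    """Dot-matrix correlogram: dot size/hue encode |r| and sign."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(corr)
    fig, ax = plt.subplots(figsize=(0.5 * n + 2, 0.5 * n + 2))
    xs, ys, sizes, colors = [], [], [], []
    for i, row in enumerate(corr.index):
        for j, col in enumerate(corr.columns):
            r = corr.iloc[i, j]
            if math.isnan(r):
                continue
            xs.append(j)
            ys.append(n - 1 - i)
            sizes.append(300 * abs(r))
            colors.append(r)
    sc = ax.scatter(xs, ys, s=sizes, c=colors, cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(n), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(n), list(corr.index)[::-1], fontsize=7)
    fig.colorbar(sc, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_boxes(summary: pd.DataFrame, ylabel: str, path) -> None:
    """Boxplots from a group_summary table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    stats = [
        {
            "label": str(row["level"]),
            "med": row["median"],
            "q1": row["q1"],
            "q3": row["q3"],
            "whislo": row["whisker_lo"],
            "whishi": row["whisker_hi"],
            "fliers": row["outliers"],
        }
        for _, row in summary.iterrows()
    ]
    ax.bxp(stats, showfliers=True)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
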