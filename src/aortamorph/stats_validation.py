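"""Method-agreement statistics: linear fits and Bland-Altman analysis.

Two measurement series of the same quantity (e.g. manual vs automatic
stenosis per section) are compared by ordinary least squares of method B
on method A and by Bland-Altman limits of agreement: the mean difference
(bias) plus/minus a multiple (default 1.96) of the standard deviation of
the differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "agreement",
    "paired_pipeline_validation",
    "group_compare",
    "bland_altman_plot",
]


@dataclass
class AgreementResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    bias: float  # mean(B - A)
    loa_low: float
    loa_high: float
    outside_loa: int
    means: np.ndarray  # (A + B) / 2, plot abscissa
    diffs: np.ndarray  # B - A, plot ordinate


def agreement(a, b, loa_multiplier: float = 1.96) -> AgreementResult:
    """OLS of b on a plus Bland-Altman limits of agreement.

    ``a`` is the reference method (x-axis), ``b`` the method under test.
    """
    import statsmodels.api as sm

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 3:
        raise ValueError("agreement needs at least 3 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("agreement needs finite values")
    if np.ptp(a) == 0:
        raise ValueError("reference series has zero variance; fit is degenerate")

    fit = sm.OLS(b, sm.add_constant(a)).fit()
    diffs = b - a
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = bias - loa_multiplier * sd, bias + loa_multiplier * sd
    return AgreementResult(
        n=a.size,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        outside_loa=int(np.sum((diffs < lo) | (diffs > hi))),
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def paired_pipeline_validation(
    automatic: pd.DataFrame,
    manual: pd.DataFrame,
    metrics: tuple[str, ...] = ("stenosis_pct", "lesion_length_fraction_pct"),
    section_col: str = "slice_index",
    loa_multiplier: float = 1.96,
) -> dict[str, AgreementResult]:
    """Agreement between automatic per-slice metrics and manual readings.

    ``manual`` may contain several repeats per section (rows sharing a
    ``section_col`` value); repeats are averaged before comparison, as in
    a triplicate manual-reading design.  ``automatic`` holds one row per
    section.  Sections must match exactly between the two tables.
    """
    man = manual.groupby(section_col, as_index=True)[list(metrics)].mean()
    auto = automatic.set_index(section_col)
    if set(man.index) != set(auto.index):
        missing = set(man.index) ^ set(auto.index)
        raise ValueError(f"section identifiers do not match between tables: {sorted(missing)}")
    auto = auto.loc[man.index]
    return {
        m: agreement(man[m].to_numpy(), auto[m].to_numpy(), loa_multiplier)
        for m in metrics
    }


def group_compare(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA across specimen groups; returns (F, p)."""
    from scipy import stats

    if len(groups) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    f, p = stats.f_oneway(*[np.asarray(v, float) for v in groups.values()])
    return float(f), float(p)


def bland_altman_plot(result: AgreementResult, ax=None, title: str | None = None):
    """Difference-vs-mean plot with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.diffs, s=18, alpha=0.8)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias = {result.bias:.3g}")
    for y, ls in ((result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, color="gray", lw=1, ls=ls)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (B − A)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    return ax
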