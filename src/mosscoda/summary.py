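"""Per-element summary statistics and two-group comparisons.

For each element (optionally split by site class) the battery is: min,
lower quartile, median, arithmetic mean, upper quartile, max, SD, and MADN
— the median absolute deviation about the median scaled by 1.4826 so that
it estimates the SD for Gaussian data.  The mean/median and SD/MADN ratios
are reported as skewness and outlier diagnostics: both are near 1 for clean
symmetric data and grow with right skew and heavy tails.

Group differences (lowland vs mountain site classes) are tested with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact when both groups
have at most 10 tie-free observations, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compositional import InsufficientDataError

__all__ = [
    "madn",
    "summarize_element",
    "wilcoxon_group_test",
    "summary_table",
    "ElementSummary",
    "GroupComparison",
    "MADN_CONSTANT",
]

#: Gaussian consistency constant: MADN = 1.4826 * MAD estimates sigma.
MADN_CONSTANT = 1.4826


def madn(x) -> float:
    """Normalised median absolute deviation about the median."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return float(MADN_CONSTANT * np.median(np.abs(x - med)))


@dataclass
class ElementSummary:
    element: str
    group: str
    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float
    madn: float
    mean_median_ratio: float
    sd_madn_ratio: float


@dataclass
class GroupComparison:
    element: str
    p_value: float
    direction: str
    significant: bool


def summarize_element(values, element: str = "", group: str = "") -> ElementSummary:
    """Summary battery for one element's concentrations.

    Quartiles use linear interpolation of order statistics; SD uses the
    sample (n-1) convention.  The ratio diagnostics are NaN-safe: a zero
    median or MADN (possible for constant data) yields ratio 1 when the
    numerator matches and inf otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("summary needs at least 3 values")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    m = madn(x)
    mm_ratio = 1.0 if mean == med else (mean / med if med != 0 else float("inf"))
    sm_ratio = 1.0 if sd == m else (sd / m if m != 0 else float("inf"))
    return ElementSummary(
        element=element,
        group=group,
        n=int(x.size),
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        mean=mean,
        q3=float(q3),
        max=float(x.max()),
        sd=sd,
        madn=m,
        mean_median_ratio=float(mm_ratio),
        sd_madn_ratio=float(sm_ratio),
    )


def wilcoxon_group_test(a, b, element: str = "", alpha: float = 0.05) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two independent groups.

    Exact enumeration of the rank-sum distribution when both groups have at
    most 10 observations and the pooled data are tie-free; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        import warnings

        warnings.warn("all pooled values tied; comparison is uninformative", stacklevel=2)
        p = 1.0
    else:
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= 10 and b.size <= 10 and not ties) else "asymptotic"
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    med_a, med_b = np.median(a), np.median(b)
    if med_a > med_b:
        direction = "group1"
    elif med_b > med_a:
        direction = "group2"
    else:
        direction = "tie"
    return GroupComparison(
        element=element, p_value=p, direction=direction, significant=p < alpha
    )


def summary_table(
    values: pd.DataFrame,
    site_class: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-element, per-group summary battery with a Wilcoxon column.

    Parameters
    ----------
    values : DataFrame (samples x elements)
    site_class : Series aligned with ``values.index``, optional
        Group labels; with exactly two groups a two-sided Wilcoxon rank-sum
        p-value, direction and significance flag are appended to every row
        of the element.  Absent (or single-group) data yield a single-group
        summary with the comparison columns NaN.

    Returns
    -------
    DataFrame with one row per element per group.
    """
    if site_class is not None:
        site_class = pd.Series(site_class).reindex(values.index)
        groups = [g for g in pd.unique(site_class.dropna())]
    else:
        groups = []
    rows = []
    for element in values.columns:
        col = values[element].astype(float)
        if len(groups) >= 2:
            comparison = None
            if len(groups) == 2:
                g1 = col[site_class == groups[0]]
                g2 = col[site_class == groups[1]]
                try:
                    comparison = wilcoxon_group_test(g1, g2, element=element, alpha=alpha)
                except InsufficientDataError:
                    comparison = None
            for g in groups:
                summ = summarize_element(col[site_class == g], element, str(g))
                row = summ.__dict__.copy()
                if comparison is not None:
                    row["wilcox_p"] = comparison.p_value
                    row["direction"] = {
                        "group1": str(groups[0]),
                        "group2": str(groups[1]),
                        "tie": "tie",
                    }[comparison.direction]
                    row["significant"] = comparison.significant
                else:
                    row["wilcox_p"] = np.nan
                    row["direction"] = ""
                    row["significant"] = np.nan
                rows.append(row)
        else:
            summ = summarize_element(col, element, "all")
            row = summ.__dict__.copy()
            row["wilcox_p"] = np.nan
            row["direction"] = ""
            row["significant"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
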