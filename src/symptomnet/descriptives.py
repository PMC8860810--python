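"""Two-group descriptive comparisons of subscale scores.

Mirrors the usual clinical-sample characterization table: per-variable
group means +/- SDs with Mann-Whitney tests, and per-maltreatment-type
occurrence rates (scores dichotomized at the published CTQ cut-offs)
compared by a 2x2 chi-squared test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SubscaleDataset


class DescriptivesError(ValueError):
    """Raised for invalid comparison inputs."""


#: CTQ occurrence cut-offs (score >= cut-off flags the maltreatment type).
DEFAULT_CM_CUTOFFS: dict[str, int] = {
    "emotional_neglect": 15,
    "emotional_abuse": 10,
    "sexual_abuse": 8,
    "physical_neglect": 8,
    "physical_abuse": 8,
}


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (group-1 convention) with two-sided p.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the ties.  The
    p-value is exact (full enumeration) when n1*n2 <= 400 and the pooled
    data have no ties, otherwise the tie- and continuity-corrected normal
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DescriptivesError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_squared_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table [[a, b], [c, d]], df = 1.

    Without correction the statistic is n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d));
    ``yates=True`` applies the continuity correction
    n(max(0, |ad - bc| - n/2))^2 / (same denominator).
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise DescriptivesError("counts must be nonnegative")
    n = counts.sum()
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise DescriptivesError(f"zero margin in table {(a, b, c, d)}")
    det = abs(a * d - b * c)
    if yates:
        det = max(0.0, det - n / 2.0)
    statistic = n * det**2 / np.prod(np.array(margins, dtype=float))
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def dichotomize_cm(
    data: SubscaleDataset, cutoffs: dict[str, int] | None = None
) -> pd.DataFrame:
    """Occurrence flags per subject per maltreatment type (score >= cut-off)."""
    cutoffs = cutoffs or DEFAULT_CM_CUTOFFS
    missing = [c for c in cutoffs if c not in data.scores.columns]
    if missing:
        raise DescriptivesError(f"missing maltreatment column(s): {missing}")
    flags = {c: data.scores[c] >= cut for c, cut in cutoffs.items()}
    return pd.DataFrame(flags)


def group_comparison_table(
    group1: SubscaleDataset,
    group2: SubscaleDataset,
    cutoffs: dict[str, int] | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-variable and per-maltreatment-type two-group comparison.

    Returns one row per variable (means, SDs, Mann-Whitney U, p) followed
    by one row per maltreatment type (counts/percentages above cut-off,
    chi-squared, p).  Column ``block`` distinguishes the two parts.
    """
    cutoffs = cutoffs or DEFAULT_CM_CUTOFFS
    if group1.variable_names != group2.variable_names:
        raise DescriptivesError("groups must share the same variables in order")
    rows = []
    for v in group1.variable_names:
        x = group1.scores[v].to_numpy(dtype=float)
        y = group2.scores[v].to_numpy(dtype=float)
        U, p = mann_whitney(x, y)
        rows.append(
            {
                "block": "scores",
                "variable": v,
                "mean1": x.mean(),
                "sd1": x.std(ddof=1),
                "mean2": y.mean(),
                "sd2": y.std(ddof=1),
                "statistic": U,
                "p": p,
                "cutoff": np.nan,
                "count1": np.nan,
                "pct1": np.nan,
                "count2": np.nan,
                "pct2": np.nan,
            }
        )
    flags1 = dichotomize_cm(group1, cutoffs)
    flags2 = dichotomize_cm(group2, cutoffs)
    n1, n2 = group1.n_subjects, group2.n_subjects
    # deterministic row order: dataset column order, then leftovers sorted
    order = [v for v in group1.variable_names if v in cutoffs]
    order += sorted(set(cutoffs) - set(order))
    for v in order:
        cut = cutoffs[v]
        a = int(flags1[v].sum())
        c = int(flags2[v].sum())
        chi2, p = chi_squared_2x2(a, n1 - a, c, n2 - c, yates=yates)
        rows.append(
            {
                "block": "cm_occurrence",
                "variable": v,
                "mean1": np.nan,
                "sd1": np.nan,
                "mean2": np.nan,
                "sd2": np.nan,
                "statistic": chi2,
                "p": p,
                "cutoff": cut,
                "count1": a,
                "pct1": 100.0 * a / n1,
                "count2": c,
                "pct2": 100.0 * c / n2,
            }
        )
    return pd.DataFrame(rows)
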