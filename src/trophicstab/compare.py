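"""Statistical comparison of the fishing and non-fishing scenarios.

Metric null ensembles are compared with the two-sample Anderson-Darling
test; the effect size is the difference of ensemble medians divided by the
pooled standard deviation; QSS proportions are compared with a Pearson
chi-squared test on the 2x2 stable/unstable table.  IQR trimming is a
display-only convenience and is never used for statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .nullmodels import NullEnsemble
from .stability import QSSResult

__all__ = [
    "MetricComparison",
    "QSSComparison",
    "ComparisonReport",
    "anderson_darling_2sample",
    "effect_size",
    "chi_squared_qss",
    "iqr_trim",
    "compare_ensembles",
]

#: p-value caps of the Anderson-Darling approximation (scipy's bounds).
AD_P_FLOOR = 0.001
AD_P_CAP = 0.25


def anderson_darling_2sample(x, y) -> tuple[float, float]:
    """Two-sample Anderson-Darling test (midrank tie treatment).

    Returns (statistic, p).  The p-value comes from the published
    approximation and is floored at 0.001 / capped at 0.25, the
    approximation's validity bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns when p hits the cap/floor
        res = scipy.stats.anderson_ksamp([x, y], midrank=True)
    return float(res.statistic), float(res.significance_level)


def effect_size(x, y) -> tuple[float, float, float]:
    """(median difference, pooled sd, effect).

    median_difference = median(x) - median(y); pooled sd is the
    root-mean-square of the two sample (n-1) standard deviations (the
    ensembles are equal-sized by construction); effect = difference /
    pooled sd.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    med_diff = float(np.median(x) - np.median(y))
    pooled = float(np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0))
    if pooled == 0.0:
        if med_diff == 0.0:
            return 0.0, 0.0, 0.0
        warnings.warn("pooled sd is zero with nonzero median difference")
        return med_diff, 0.0, math.copysign(math.inf, med_diff)
    return med_diff, pooled, med_diff / pooled


def chi_squared_qss(a: QSSResult, b: QSSResult) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on the 2x2 table of
    stable/unstable counts of two QSS runs; falls back to Fisher's exact
    test when an expected count drops below 5."""
    table = np.array(
        [
            [a.n_stable, a.n_samples - a.n_stable],
            [b.n_stable, b.n_samples - b.n_stable],
        ]
    )
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        # a margin is empty: the two runs are indistinguishable on this axis
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        warnings.warn("expected count < 5; using Fisher's exact test")
        _, p = scipy.stats.fisher_exact(table)
        return float("nan"), float(p)
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def iqr_trim(values) -> tuple[np.ndarray, int]:
    """Drop points below Q1 - 1.5*IQR or above Q3 + 1.5*IQR (quartiles by
    linear interpolation).  Display-only; returns (trimmed, n_removed)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to trim")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    keep = (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
    return values[keep], int(values.size - keep.sum())


@dataclass
class MetricComparison:
    """One row of the scenario-comparison table."""

    metric: str
    weighted: bool
    median_nonfishing: float
    median_fishing: float
    median_difference: float
    pooled_sd: float
    effect_size: float
    ad_statistic: float
    ad_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class QSSComparison:
    weighted: bool
    prop_nonfishing: float
    prop_fishing: float
    chi2: float
    p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ComparisonReport:
    """Per-metric comparison rows plus the QSS rows."""

    rows: list[MetricComparison] = field(default_factory=list)
    qss_rows: list[QSSComparison] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "metrics": [r.as_dict() for r in self.rows],
            "qss": [r.as_dict() for r in self.qss_rows],
            "meta": self.meta,
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([r.as_dict() for r in self.rows])


def compare_ensembles(
    nonfishing: NullEnsemble, fishing: NullEnsemble
) -> MetricComparison:
    """Build one comparison row from a pair of null ensembles."""
    if nonfishing.metric != fishing.metric:
        raise ValueError("ensembles measure different metrics")
    x, y = nonfishing.values, fishing.values
    med_diff, pooled, effect = effect_size(x, y)
    stat, p = anderson_darling_2sample(x, y)
    return MetricComparison(
        metric=nonfishing.metric,
        weighted=bool(nonfishing.recipe.get("weighted", False)),
        median_nonfishing=float(np.median(x)),
        median_fishing=float(np.median(y)),
        median_difference=med_diff,
        pooled_sd=pooled,
        effect_size=effect,
        ad_statistic=stat,
        ad_p=p,
    )
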