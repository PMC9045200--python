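"""Phenotype formulas: growth, acid survival, GAD activity, group tests.

These are the classical small-sample statistics used for the mutant
characterization assays: a two-point exponential doubling time from Klett
turbidity readings, percent survival from CFU counts before/after an acid
challenge, an ordinary least-squares line for the colorimetric GAD activity
(OD620) versus viable-cell input, and an unpaired two-tailed Student t test
(equal variance, alpha 0.05) for two-group assay comparisons. Note the
contrast with the sequencing side, which uses Welch's t on log2 CPM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = (145.0, 240.0)  # minutes: mid-exponential to late window


def doubling_time(t1: float, n1: float, t2: float, n2: float) -> float:
    """Two-point exponential doubling time, (t2-t1)*ln2 / ln(n2/n1).

    ``n1``/``n2`` are Klett readings at minutes ``t1`` < ``t2``; the default
    analysis window is readings at 140-150 min and 240 min. Scale-invariant
    in the readings.
    """
    if not (t2 > t1):
        raise ValueError("need t2 > t1")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("Klett readings must be positive")
    if n2 <= n1:
        raise ValueError("no growth in window (n2 <= n1)")
    return (t2 - t1) * math.log(2) / math.log(n2 / n1)


def percent_survival(cfu_before: float, cfu_after: float) -> float:
    """100 x CFU/mL after acidification / CFU/mL before acidification."""
    if cfu_before <= 0:
        raise ValueError("CFU before acidification must be positive")
    if cfu_after < 0:
        raise ValueError("CFU must be non-negative")
    return 100.0 * cfu_after / cfu_before


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of y on x (e.g. OD620 vs CFU/mL)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("all x values equal; slope undefined")
    if np.ptp(y) == 0:
        return LinearFit(slope=0.0, intercept=float(y.mean()), r_squared=0.0)
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class AssayComparison:
    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    p_value: float
    alpha: float = 0.05
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(a, b, alpha: float = 0.05) -> AssayComparison:
    """Two-tailed unpaired Student's t test (equal variance).

    Degenerate zero-variance inputs: identical groups give p = 1; separated
    constant groups give p = 0 with the zero-variance flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return AssayComparison(tuple(a), tuple(b), 0.0, 1.0, alpha,
                                   zero_variance=True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return AssayComparison(tuple(a), tuple(b), t, 0.0, alpha,
                               zero_variance=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return AssayComparison(
        tuple(a), tuple(b), float(res.statistic), float(res.pvalue), alpha
    )


# ---------------------------------------------------------------------------
# tidy-table drivers


def doubling_times_from_curves(
    curves: pd.DataFrame,
    t1_range: tuple[float, float] = (140.0, 150.0),
    t2: float = 240.0,
) -> pd.DataFrame:
    """Doubling time per (strain, replicate) from a tidy growth table.

    ``curves`` has columns strain_id, replicate_id, time_min, klett. The
    early reading is the one closest to the t1 window (within it when
    possible); the late reading is the one closest to ``t2``.
    """
    required = {"strain_id", "replicate_id", "time_min", "klett"}
    if not required <= set(curves.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    rows = []
    mid_t1 = 0.5 * (t1_range[0] + t1_range[1])
    for (strain, rep), sub in curves.groupby(["strain_id", "replicate_id"]):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValueError(
                f"times not strictly increasing for {strain}/{rep}"
            )
        klett = sub["klett"].to_numpy(dtype=float)
        i1 = int(np.argmin(np.abs(times - mid_t1)))
        i2 = int(np.argmin(np.abs(times - t2)))
        rows.append(
            {
                "strain_id": strain,
                "replicate_id": rep,
                "t1": times[i1],
                "t2": times[i2],
                "doubling_time_min": doubling_time(
                    times[i1], klett[i1], times[i2], klett[i2]
                ),
            }
        )
    return pd.DataFrame(rows)


def survival_from_cfu(table: pd.DataFrame) -> pd.DataFrame:
    """Percent survival per row of a tidy CFU table.

    Columns: strain_id, replicate_id, cfu_before, cfu_after.
    """
    out = table.copy()
    out["percent_survival"] = [
        percent_survival(b, a)
        for b, a in zip(table["cfu_before"], table["cfu_after"])
    ]
    return out
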