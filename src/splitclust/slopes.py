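"""Within-cluster slope comparison across group strata.

For a response/predictor pair found inside a cluster, ordinary least
squares is fitted separately in each stratum (e.g. CVS vs no CVS) and the
difference between the two slopes is tested with the interaction
coefficient of the pooled model ``y ~ x + stratum + x:stratum`` (two-sided
t-test, common residual variance).  A Welch-type z on
``(b1 - b0) / sqrt(SE1^2 + SE0^2)`` is available as an option.  The effect
is also reported as the percent slope increase ``100*(b1/b0 - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Cohort
from .stability import ClusterSet

__all__ = ["SlopeComparison", "stratum_slopes", "percent_slope_increase",
           "cluster_slope_table"]


@dataclass(frozen=True)
class SlopeComparison:
    response: str
    predictor: str
    beta_cvs: float
    beta_nocvs: float
    se_cvs: float
    se_nocvs: float
    p_difference: float

    def __post_init__(self) -> None:
        if not (self.se_cvs > 0 and self.se_nocvs > 0):
            raise ValueError("slope standard errors must be positive")
        if not 0 <= self.p_difference <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def percent_increase(self) -> float:
        return percent_slope_increase(self.beta_cvs, self.beta_nocvs)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1])


def stratum_slopes(
    x: Sequence[float],
    y: Sequence[float],
    stratum: Sequence[int],
    response: str = "y",
    predictor: str = "x",
    method: str = "interaction",
) -> SlopeComparison:
    """Per-stratum OLS slopes of y on x plus a slope-difference p-value.

    ``stratum`` is a binary indicator (1 = CVS).  With
    ``method="interaction"`` the p-value comes from the interaction
    coefficient of the pooled model; ``method="welch_z"`` uses the normal
    approximation on the difference of the independently fitted slopes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.asarray(stratum, dtype=int)
    if not set(np.unique(s)) <= {0, 1}:
        raise ValueError("stratum must be a binary 0/1 indicator")
    for lab in (0, 1):
        m = s == lab
        if m.sum() < 3:
            raise ValueError(f"stratum {lab} has fewer than 3 points")
        if np.var(x[m]) == 0:
            raise ValueError(f"stratum {lab} has zero predictor variance")
    b1, se1 = _ols_slope(x[s == 1], y[s == 1])
    b0, se0 = _ols_slope(x[s == 0], y[s == 0])
    if method == "interaction":
        design = sm.add_constant(np.column_stack([x, s, x * s]))
        res = sm.OLS(y, design).fit()
        p = float(res.pvalues[3])
    elif method == "welch_z":
        z = (b1 - b0) / np.hypot(se1, se0)
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("method must be 'interaction' or 'welch_z'")
    return SlopeComparison(response, predictor, b1, b0, se1, se0, p)


def percent_slope_increase(beta_a: float, beta_b: float) -> float:
    """Percent increase of slope a over slope b, 100*(a/b - 1)."""
    if beta_b == 0:
        raise ValueError("reference slope is zero; percent increase undefined")
    return 100.0 * (beta_a / beta_b - 1.0)


def cluster_slope_table(
    cohort: Cohort,
    clusters: ClusterSet,
    method: str = "interaction",
) -> pd.DataFrame:
    """Slope comparisons for all ordered pairs within each cluster.

    Variables are expected in the transformed, standardized state in which
    the clusters were found.  Direction is explicit: each row names the
    response and the predictor.
    """
    s = cohort.data[cohort.schema.group_label].to_numpy(dtype=int)
    rows = []
    for cluster in clusters.clusters:
        for response, predictor in permutations(sorted(cluster), 2):
            comp = stratum_slopes(
                cohort.data[predictor].to_numpy(dtype=float),
                cohort.data[response].to_numpy(dtype=float),
                s,
                response=response,
                predictor=predictor,
                method=method,
            )
            rows.append(
                {
                    "response": response,
                    "predictor": predictor,
                    "beta_cvs": comp.beta_cvs,
                    "beta_nocvs": comp.beta_nocvs,
                    "se_cvs": comp.se_cvs,
                    "se_nocvs": comp.se_nocvs,
                    "percent_increase": (
                        comp.percent_increase if comp.beta_nocvs != 0 else np.nan
                    ),
                    "p_difference": comp.p_difference,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "response", "predictor", "beta_cvs", "beta_nocvs",
            "se_cvs", "se_nocvs", "percent_increase", "p_difference",
        ],
    )
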