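"""Yeo-Johnson power transformation and standardization.

Skewed serum concentrations are mapped toward approximate normality with
the Yeo-Johnson transform, whose exponent lambda is estimated per variable
by maximizing the profile log-likelihood (normal likelihood of the
transformed values plus the Jacobian term), then centred and scaled to zero
mean and unit sample standard deviation.  The transform is defined for all
reals and strictly increasing in its argument for every lambda:

    y >= 0:  ((y+1)^lam - 1)/lam          (lam != 0),   log(y+1)   (lam = 0)
    y <  0:  -((1-y)^(2-lam) - 1)/(2-lam) (lam != 2),  -log(1-y)   (lam = 2)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import Cohort, TRAINING

__all__ = [
    "LAMBDA_INTERVAL",
    "TransformParams",
    "yeo_johnson",
    "yeo_johnson_loglik",
    "fit_lambda",
    "standardize",
    "transform_cohort",
]

#: bounded search interval for the exponent; covers realistic biomarker skews
LAMBDA_INTERVAL = (-5.0, 5.0)


def yeo_johnson(y, lam: float):
    """Apply the Yeo-Johnson map elementwise; scalar in, scalar out."""
    y_arr = np.asarray(y, dtype=float)
    out = np.empty_like(y_arr)
    pos = y_arr >= 0
    if abs(lam) > 1e-12:
        out[pos] = (np.power(y_arr[pos] + 1.0, lam) - 1.0) / lam
    else:
        out[pos] = np.log1p(y_arr[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -(np.power(1.0 - y_arr[~pos], 2.0 - lam) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-y_arr[~pos])
    return out if out.ndim else float(out)


def yeo_johnson_loglik(values: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of lambda under transformed-normality.

    ll(lam) = -n/2 log sigma_hat^2(lam) + (lam-1) * sum sign(y) log(|y|+1)
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    t = yeo_johnson(values, lam)
    var = t.var()  # MLE variance (ddof 0)
    if var <= 0 or not np.isfinite(var):
        return -np.inf
    jac = np.sum(np.sign(values) * np.log1p(np.abs(values)))
    return -n / 2.0 * math.log(var) + (lam - 1.0) * jac


def fit_lambda(values: Sequence[float]) -> float:
    """Maximum-likelihood Yeo-Johnson exponent over :data:`LAMBDA_INTERVAL`.

    Bounded scalar optimization to 1e-6; requires >= 3 distinct values.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 3:
        raise ValueError("need >= 3 distinct values to estimate lambda")
    res = optimize.minimize_scalar(
        lambda lam: -yeo_johnson_loglik(values, lam),
        bounds=LAMBDA_INTERVAL,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Centre and scale to sample SD 1 (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot standardize a constant vector")
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class TransformParams:
    """Per-variable fitted transform: exponent, post-transform mean and SD."""

    lam: float
    post_mean: float
    post_sd: float

    def __post_init__(self) -> None:
        lo, hi = LAMBDA_INTERVAL
        if not (np.isfinite(self.lam) and lo <= self.lam <= hi):
            raise ValueError(f"lambda {self.lam} outside search interval")
        if not self.post_sd > 0:
            raise ValueError("post-transform SD must be > 0")

    def apply(self, values) -> np.ndarray:
        return (yeo_johnson(values, self.lam) - self.post_mean) / self.post_sd


def transform_cohort(
    cohort: Cohort,
    variables: Sequence[str] | None = None,
    per_set: bool = False,
) -> tuple[Cohort, dict[str, TransformParams]]:
    """Transform and standardize the skewed analysis variables.

    By default the ten biomarkers and age are transformed, fitted on the
    combined cohort (training + validation); ordinal scores are left on
    their original scale.  With ``per_set`` the exponent and the moments are
    fitted within each set separately (an option, not the default
    procedure).

    Returns the transformed cohort and the fitted parameters per variable
    (for ``per_set`` the params of the training set are reported).
    """
    schema = cohort.schema
    if variables is None:
        variables = schema.biomarkers + [
            v.name
            for v in schema.variables
            if v.role == "demographic" and v.scale == "continuous"
        ]
    df = cohort.data.copy()
    params: dict[str, TransformParams] = {}

    def _fit_apply(col: np.ndarray) -> tuple[np.ndarray, TransformParams]:
        lam = fit_lambda(col)
        t = yeo_johnson(col, lam)
        mean, sd = t.mean(), t.std(ddof=1)
        if not sd > 0:
            raise ValueError("degenerate variance after transform")
        return (t - mean) / sd, TransformParams(lam, float(mean), float(sd))

    for name in variables:
        col = df[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(
                f"variable {name!r} has missing values; exclude incomplete rows first"
            )
        if per_set:
            out = np.empty_like(col)
            for set_name in (TRAINING, "validation"):
                m = (df[schema.set_label] == set_name).to_numpy()
                if m.any():
                    out[m], p = _fit_apply(col[m])
                    if set_name == TRAINING:
                        params[name] = p
            df[name] = out
        else:
            df[name], params[name] = _fit_apply(col)
    return Cohort(df, schema, list(cohort.exclusion_log)), params


# -- parameter (de)serialisation --------------------------------------------

def save_params(params: Mapping[str, TransformParams], path: str | Path) -> None:
    payload = {
        k: {"lambda": p.lam, "post_mean": p.post_mean, "post_sd": p.post_sd}
        for k, p in params.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_params(path: str | Path) -> dict[str, TransformParams]:
    raw = json.loads(Path(path).read_text())
    return {
        k: TransformParams(v["lambda"], v["post_mean"], v["post_sd"])
        for k, v in raw.items()
    }
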