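"""Random-split resampling validation of the correlation thresholds.

Repeatedly re-splits the cohort into training and validation sets at the
configured ratio (default 2:1, 10,000 splits) and recomputes every pairwise
correlation on both sides.  Per pair the simulation aggregates

* the mean training correlation over sign-consistent splits,
* the fraction of sign-consistent splits, and
* the mean absolute training-validation difference,

which together quantify how plausible the consistency (delta) and
relevance (tau) thresholds are for the cohort at hand: a threshold is
credible when sign-consistent correlations stay above tau and the typical
split-to-split difference stays below delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Cohort

__all__ = [
    "SimulationSummary",
    "PlausibilityReport",
    "generate_split_masks",
    "simulate_splits",
    "random_split_simulation",
    "threshold_plausibility_report",
    "masked_mean_correlation_frame",
]

#: mask pairs whose sign flips in more than this fraction of the splits
OPPOSITE_SIGN_MASK_FRACTION = 0.05


@dataclass
class SimulationSummary:
    """Per-pair aggregates over repeated random training/validation splits."""

    table: pd.DataFrame  # var_i, var_j, mean_r_train_signconsistent,
    #                      fraction_sign_consistent, mean_abs_diff
    n_splits: int
    ratio: float
    rng_seed: int

    def pair_row(self, a: str, b: str) -> pd.Series:
        t = self.table
        m = ((t["var_i"] == a) & (t["var_j"] == b)) | (
            (t["var_i"] == b) & (t["var_j"] == a)
        )
        if not m.any():
            raise KeyError((a, b))
        return t[m].iloc[0]


@dataclass
class PlausibilityReport:
    """Pairs challenging the chosen thresholds."""

    below_tau: list[tuple[str, str]]
    above_delta: list[tuple[str, str]]
    delta: float
    tau: float


def training_size(n: int, ratio: float) -> int:
    """Training-set size for an n-patient cohort; half-up rounding."""
    return int(np.floor(ratio * n + 0.5))


def generate_split_masks(
    n: int, n_splits: int, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_splits, n) matrix; True marks the training side.

    Every row has exactly ``training_size(n, ratio)`` True entries, so each
    split is an exact partition of the cohort.
    """
    n_train = training_size(n, ratio)
    order = np.argsort(rng.random((n_splits, n)), axis=1)
    masks = np.zeros((n_splits, n), dtype=bool)
    np.put_along_axis(masks, order[:, :n_train], True, axis=1)
    return masks


def _pair_correlations(
    x: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Correlations of every column pair on both sides of every split.

    Returns (r_train, r_val), each of shape (n_splits, n_pairs); fully
    vectorized over splits.
    """
    n, p = x.shape
    ii, jj = np.triu_indices(p, k=1)
    prod = x[:, ii] * x[:, jj]
    sq = x * x
    m = masks.astype(float)
    n_t = m.sum(axis=1, keepdims=True)
    n_v = n - n_t

    def _corr(s1, s2, s12, cnt):
        mean = s1 / cnt
        var = s2 / cnt - mean**2
        cov = s12 / cnt - mean[:, ii] * mean[:, jj]
        denom = np.sqrt(var[:, ii] * var[:, jj])
        with np.errstate(invalid="ignore", divide="ignore"):
            return cov / denom

    s1_t, s2_t, s12_t = m @ x, m @ sq, m @ prod
    s1_all, s2_all, s12_all = x.sum(0), sq.sum(0), prod.sum(0)
    r_train = _corr(s1_t, s2_t, s12_t, n_t)
    r_val = _corr(s1_all - s1_t, s2_all - s2_t, s12_all - s12_t, n_v)
    return r_train, r_val


def simulate_splits(
    data: pd.DataFrame,
    variables: Sequence[str],
    n_splits: int,
    ratio: float,
    rng_seed: int,
) -> SimulationSummary:
    """Resample random splits of *data* and aggregate pair correlations."""
    n = len(data)
    n_train = training_size(n, ratio)
    if n_train < 3 or n - n_train < 3:
        raise ValueError(
            f"cohort of {n} is too small for a {ratio:.2f} training ratio"
        )
    rng = np.random.default_rng(rng_seed)
    masks = generate_split_masks(n, n_splits, ratio, rng)
    x = data[list(variables)].to_numpy(dtype=float)
    r_train, r_val = _pair_correlations(x, masks)
    sign_ok = r_train * r_val >= 0
    frac = sign_ok.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_r = np.where(
            sign_ok.any(axis=0),
            np.nansum(np.where(sign_ok, r_train, 0.0), axis=0)
            / np.maximum(sign_ok.sum(axis=0), 1),
            np.nan,
        )
    mean_abs_diff = np.abs(r_train - r_val).mean(axis=0)
    ii, jj = np.triu_indices(len(variables), k=1)
    table = pd.DataFrame(
        {
            "var_i": [variables[i] for i in ii],
            "var_j": [variables[j] for j in jj],
            "mean_r_train_signconsistent": mean_r,
            "fraction_sign_consistent": frac,
            "mean_abs_diff": mean_abs_diff,
        }
    )
    return SimulationSummary(table, n_splits, ratio, rng_seed)


def random_split_simulation(
    cohort: Cohort,
    config: AnalysisConfig,
    stratified: bool | None = None,
) -> dict[object, SimulationSummary]:
    """Split-resampling simulation, by default within each group stratum.

    Returns a summary per stratum value (keys 0/1), or under the key
    ``"all"`` for the unstratified whole-cohort mode.
    """
    if stratified is None:
        stratified = config.stratified_splits
    variables = cohort.schema.analysis_variables
    if stratified:
        return {
            value: simulate_splits(
                sub.data, variables, config.n_splits, config.split_ratio,
                config.rng_seed + int(value),
            )
            for value, sub in cohort.strata().items()
        }
    return {
        "all": simulate_splits(
            cohort.data, variables, config.n_splits, config.split_ratio,
            config.rng_seed,
        )
    }


def threshold_plausibility_report(
    summary: SimulationSummary, delta: float, tau: float
) -> PlausibilityReport:
    """Flag pairs challenging the thresholds.

    ``below_tau``: sign-consistent mean training correlation with magnitude
    below tau.  ``above_delta``: mean absolute training-validation
    difference exceeding delta.
    """
    t = summary.table
    weak = np.abs(t["mean_r_train_signconsistent"]) < tau
    unstable = t["mean_abs_diff"] > delta
    pairs = list(zip(t["var_i"], t["var_j"]))
    return PlausibilityReport(
        below_tau=[p for p, w in zip(pairs, weak) if w],
        above_delta=[p for p, u in zip(pairs, unstable) if u],
        delta=delta,
        tau=tau,
    )


def masked_mean_correlation_frame(summary: SimulationSummary) -> pd.DataFrame:
    """Mean sign-consistent training correlation as a square frame.

    Pairs whose correlation sign flips between the two sides in more than
    5% of the runs are masked (NaN), matching the exported heatmap rule.
    """
    t = summary.table
    names = sorted(set(t["var_i"]) | set(t["var_j"]))
    frame = pd.DataFrame(np.nan, index=names, columns=names)
    for _, row in t.iterrows():
        if 1.0 - row["fraction_sign_consistent"] <= OPPOSITE_SIGN_MASK_FRACTION:
            frame.loc[row["var_i"], row["var_j"]] = row[
                "mean_r_train_signconsistent"
            ]
            frame.loc[row["var_j"], row["var_i"]] = row[
                "mean_r_train_signconsistent"
            ]
    np.fill_diagonal(frame.values, 1.0)
    return frame
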