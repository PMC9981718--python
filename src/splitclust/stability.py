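"""Split-consistency correlation screening and correlation-graph clustering.

The core of the pipeline.  Pairwise correlations among the analysis
variables are computed separately on the training set, the validation set,
and the combined cohort.  A pair is

* *consistent* when its training and validation correlations have the same
  sign (product >= 0, so an exact zero never triggers the opposite-sign
  rule) and differ by at most delta (default 0.25);
* *relevant* when the magnitude of its combined-set correlation is at least
  tau (default 0.25);
* *retained* when both hold.

Clusters are connected components of size >= ``min_cluster_size`` (default
3) in the graph whose edges are the retained pairs; smaller components are
reported as residual pairs.  The whole screen is run separately within each
group stratum (CVS / no CVS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import AnalysisConfig, Cohort

__all__ = [
    "CorrelationMatrixPair",
    "StabilityReport",
    "ClusterSet",
    "correlation_matrices",
    "classify_consistency",
    "filter_pairs",
    "find_clusters",
    "stratified_analysis",
    "masked_heatmap_frame",
]


@dataclass(frozen=True)
class CorrelationMatrixPair:
    """Correlation matrices over the same variables on train/val/combined."""

    variables: tuple[str, ...]
    r_train: np.ndarray
    r_val: np.ndarray
    r_combined: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.variables)
        for name in ("r_train", "r_val", "r_combined"):
            m = getattr(self, name)
            if m.shape != (p, p):
                raise ValueError(f"{name} has shape {m.shape}, expected {(p, p)}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} is not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError(f"{name} diagonal must be 1")
            if np.nanmax(np.abs(m)) > 1 + 1e-12:
                raise ValueError(f"{name} has entries outside [-1, 1]")

    def pairs(self) -> Iterable[tuple[int, int]]:
        return combinations(range(len(self.variables)), 2)


@dataclass
class StabilityReport:
    """Per-pair correlations plus consistency/relevance/retention flags."""

    table: pd.DataFrame  # columns: var_i, var_j, r_train, r_val, r_combined,
    #                               consistent, relevant, retained
    delta: float
    tau: float

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def n_consistent(self) -> int:
        return int(self.table["consistent"].sum())

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    def retained_pairs(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["retained"]]
        return list(zip(sub["var_i"], sub["var_j"]))


@dataclass
class ClusterSet:
    """Variable groupings induced by the retained-pair graph."""

    clusters: list[frozenset[str]]
    residual_pairs: list[tuple[str, str]]

    def containing(self, names: Iterable[str]) -> frozenset[str] | None:
        """The cluster containing all *names*, if any."""
        wanted = set(names)
        for c in self.clusters:
            if wanted <= c:
                return c
        return None


def correlation_matrices(
    cohort: Cohort,
    variables: Sequence[str] | None = None,
    kind: str = "pearson",
) -> CorrelationMatrixPair:
    """Pairwise correlations on training rows, validation rows and all rows.

    Raises
    ------
    ValueError
        A variable with zero variance within one of the sets, or a set with
        fewer than 3 patients.
    """
    if kind not in ("pearson", "spearman"):
        raise ValueError("correlation kind must be pearson or spearman")
    variables = list(variables or cohort.schema.analysis_variables)
    train, val = cohort.split()
    mats = []
    for name, frame in (("training", train), ("validation", val),
                        ("combined", cohort.data)):
        if len(frame) < 3:
            raise ValueError(f"{name} set has fewer than 3 patients")
        block = frame[variables].astype(float)
        sd = block.std(ddof=1)
        flat = sd[sd == 0].index.tolist()
        if flat:
            raise ValueError(f"zero variance in {name} set: {flat}")
        mats.append(block.corr(method=kind).to_numpy())
    return CorrelationMatrixPair(tuple(variables), *mats)


def classify_consistency(r_train: float, r_val: float, delta: float) -> bool:
    """True iff the two correlations agree in sign and differ by <= delta.

    Sign agreement is ``r_train * r_val >= 0``: a correlation of exactly 0
    never triggers the opposite-sign rule.
    """
    for r in (r_train, r_val):
        if not -1 <= r <= 1:
            raise ValueError("correlations must lie in [-1, 1]")
    return r_train * r_val >= 0 and abs(r_train - r_val) <= delta


def filter_pairs(
    matrices: CorrelationMatrixPair, config: AnalysisConfig
) -> StabilityReport:
    """Apply the consistency and relevance filters to every unordered pair.

    Consistency is judged on (r_train, r_val); relevance on the combined-set
    correlation magnitude (``config.relevance_on`` may switch the reference
    matrix to the training set).  Retained = consistent AND relevant.
    """
    ref = (
        matrices.r_combined if config.relevance_on == "combined" else matrices.r_train
    )
    rows = []
    for i, j in matrices.pairs():
        rt = float(matrices.r_train[i, j])
        rv = float(matrices.r_val[i, j])
        rc = float(matrices.r_combined[i, j])
        consistent = classify_consistency(rt, rv, config.delta_consistency)
        relevant = abs(float(ref[i, j])) >= config.tau_magnitude
        rows.append(
            {
                "var_i": matrices.variables[i],
                "var_j": matrices.variables[j],
                "r_train": rt,
                "r_val": rv,
                "r_combined": rc,
                "consistent": consistent,
                "relevant": relevant,
                "retained": consistent and relevant,
            }
        )
    return StabilityReport(
        pd.DataFrame(rows), config.delta_consistency, config.tau_magnitude
    )


def find_clusters(
    report: StabilityReport,
    min_size: int = 3,
    method: str = "components",
) -> ClusterSet:
    """Clusters in the retained-pair graph.

    ``components`` (default): connected components with >= ``min_size``
    vertices; components below the threshold are reported as residual
    pairs.  ``cliques``: disjoint clusters built greedily from maximal
    cliques of size >= ``min_size`` (largest first), a stricter reading of
    "mutually correlated" grouping.
    """
    g = nx.Graph()
    g.add_edges_from(report.retained_pairs())
    clusters: list[frozenset[str]] = []
    covered: set[str] = set()
    if method == "components":
        for comp in nx.connected_components(g):
            if len(comp) >= min_size:
                clusters.append(frozenset(comp))
                covered |= comp
    elif method == "cliques":
        cliques = sorted(
            (c for c in nx.find_cliques(g) if len(c) >= min_size),
            key=lambda c: (-len(c), sorted(c)),
        )
        for c in cliques:
            if not covered & set(c):
                clusters.append(frozenset(c))
                covered |= set(c)
    else:
        raise ValueError("cluster method must be 'components' or 'cliques'")
    residual = [
        (a, b) for a, b in report.retained_pairs() if not ({a, b} & covered)
    ]
    clusters.sort(key=lambda c: sorted(c))
    return ClusterSet(clusters, residual)


def stratified_analysis(
    cohort: Cohort, config: AnalysisConfig
) -> dict[object, tuple[StabilityReport, ClusterSet]]:
    """Run the full filter + cluster pipeline within each group stratum.

    Each stratum (e.g. CVS = 1 and CVS = 0) is screened with its own
    training/validation/combined correlations over the same transformed
    variables.

    Raises
    ------
    ValueError
        A stratum x set cell with fewer than 3 patients.
    """
    out: dict[object, tuple[StabilityReport, ClusterSet]] = {}
    for value, sub in cohort.strata().items():
        mats = correlation_matrices(sub, kind=config.correlation_kind)
        report = filter_pairs(mats, config)
        clusters = find_clusters(report, config.min_cluster_size,
                                 config.cluster_method)
        out[value] = (report, clusters)
    return out


def masked_heatmap_frame(report: StabilityReport, which: str = "r_combined"
                         ) -> pd.DataFrame:
    """Square correlation frame with non-retained cells masked (NaN).

    Mirrors the published heatmaps, which blank every pair failing the
    consistency or relevance filter.  Exported as CSV so downstream checks
    never read pixels.
    """
    names = sorted(set(report.table["var_i"]) | set(report.table["var_j"]))
    frame = pd.DataFrame(np.nan, index=names, columns=names)
    for _, row in report.table.iterrows():
        if row["retained"]:
            frame.loc[row["var_i"], row["var_j"]] = row[which]
            frame.loc[row["var_j"], row["var_i"]] = row[which]
    np.fill_diagonal(frame.values, 1.0)
    return frame
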