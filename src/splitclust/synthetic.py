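"""Synthetic aSAH cohort generator.

Generates patient tables with the statistical structure the stability
analysis assumes, so every downstream stage is testable without patient
data.  Sampling follows a Gaussian copula per group stratum: a latent
multivariate normal carries block correlation structure (group-specific,
e.g. an mtDNA-fragment block present only in the CVS stratum), and each
latent coordinate is pushed through a monotone map to its target marginal:

* biomarkers: lognormal, moment-matched to a target mean and SD (serum
  panels are non-negative and heavily right-skewed, SD typically exceeding
  the mean);
* age: normal (affine map of the latent);
* Hunt and Hess: latent-normal thresholded into its ordinal levels, so the
  score can carry planted correlation with cytokines.

Monotone marginal maps preserve the latent rank correlations exactly and
the Pearson correlations approximately once the skew is transformed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BIOMARKERS,
    TRAINING,
    VALIDATION,
    Cohort,
    VariableSchema,
    default_schema,
)

__all__ = [
    "CorrelationBlock",
    "SyntheticConfig",
    "generate_cohort",
    "inject_missing",
    "COHORT_MARGINALS",
]

#: target (mean, SD) per biomarker, matched to the emulated cohort summary
COHORT_MARGINALS: dict[str, tuple[float, float]] = {
    "HMGB1": (14.2, 21.6),
    "Cyt-B": (12.8, 21.8),
    "D-loop": (10.5, 22.5),
    "Cox-1": (10.4, 22.6),
    "IL-6": (11.7, 22.1),
    "IL-17": (12.8, 22.0),
    "IL-23": (44.5, 51.2),
    "IL-10": (95.3, 168.0),
    "CCL5": (17_300.0, 18_600.0),
    "Leukocytes": (19.0, 20.5),
}

#: demographic / score distributions of the emulated cohort
AGE_MEAN, AGE_SD = 56.7, 12.2
SEX_P = 25 / 66
FISHER_P = (1 / 66, 2 / 66, 54 / 66, 9 / 66)
HUNTHESS_P = (5 / 66, 23 / 66, 18 / 66, 12 / 66, 8 / 66)
GOS_P = (4 / 66, 8 / 66, 18 / 66, 4 / 66, 32 / 66)
MRS_P = (2 / 66, 24 / 66, 7 / 66, 6 / 66, 12 / 66, 11 / 66, 4 / 66)


@dataclass(frozen=True)
class CorrelationBlock:
    """Equicorrelated latent block planted in one stratum.

    ``stratum`` is ``"cvs"``, ``"no_cvs"`` or ``"both"``.
    """

    variables: tuple[str, ...]
    r: float
    stratum: str = "cvs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if not -1 < self.r < 1:
            raise ValueError("block correlation must lie in (-1, 1)")
        if len(self.variables) < 2:
            raise ValueError("a block needs at least two variables")
        if self.stratum not in ("cvs", "no_cvs", "both"):
            raise ValueError("stratum must be cvs, no_cvs or both")
        # equicorrelation matrix is PD iff r > -1/(k-1)
        k = len(self.variables)
        if self.r <= -1 / (k - 1):
            raise ValueError(
                f"equicorrelation r={self.r} is not positive definite for k={k}"
            )


def _default_blocks() -> tuple[CorrelationBlock, ...]:
    # group-specific structure: mtDNA-fragment block and a cytokine/age
    # block present only in the CVS stratum
    return (
        CorrelationBlock(("Cyt-B", "Cox-1", "D-loop"), 0.75, "cvs"),
        CorrelationBlock(("IL-6", "IL-10", "age"), 0.4, "cvs"),
    )


@dataclass
class SyntheticConfig:
    """Cohort-generator settings; defaults emulate the published cohort."""

    n_cvs: int = 36
    n_nocvs: int = 30
    blocks: tuple[CorrelationBlock, ...] = field(default_factory=_default_blocks)
    marginal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(COHORT_MARGINALS)
    )
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    sex_p: float = SEX_P
    score_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "Fisher": FISHER_P,
            "HuntHess": HUNTHESS_P,
            "GOS": GOS_P,
            "mRS": MRS_P,
        }
    )
    split_ratio: float = 2 / 3
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cvs + self.n_nocvs < 10:
            raise ValueError("cohort too small: n_cvs + n_nocvs must be >= 10")
        for name, (mu, sd) in self.marginal_params.items():
            if sd <= 0:
                raise ValueError(f"marginal SD for {name!r} must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        self.blocks = tuple(self.blocks)


# ---------------------------------------------------------------------------
# sampling machinery
# ---------------------------------------------------------------------------

#: latent variables: biomarkers + age + HuntHess threshold latent
_LATENTS = list(BIOMARKERS) + ["age", "HuntHess"]


def _latent_correlation(blocks: Sequence[CorrelationBlock], stratum: str) -> np.ndarray:
    """Compose the latent correlation matrix for one stratum."""
    p = len(_LATENTS)
    idx = {v: i for i, v in enumerate(_LATENTS)}
    corr = np.eye(p)
    for b in blocks:
        if b.stratum not in (stratum, "both"):
            continue
        unknown = set(b.variables) - set(idx)
        if unknown:
            raise ValueError(f"block names not among latent variables: {unknown}")
        ii = [idx[v] for v in b.variables]
        for a in ii:
            for c in ii:
                if a != c:
                    corr[a, c] = b.r
    # overlapping blocks could break positive definiteness; check eagerly
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"latent correlation matrix for stratum {stratum!r} is not "
            f"positive definite (min eigenvalue {eigmin:.3g})"
        )
    return corr


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to (mean, sd): exp(mu + sigma*Z)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _ordinal_thresholds(probs: Sequence[float]) -> np.ndarray:
    from scipy.stats import norm

    cum = np.cumsum(probs)[:-1] / np.sum(probs)
    return norm.ppf(cum)


def _sample_stratum(
    n: int,
    cvs: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    stratum = "cvs" if cvs else "no_cvs"
    corr = _latent_correlation(config.blocks, stratum)
    z = rng.multivariate_normal(np.zeros(len(_LATENTS)), corr, size=n,
                                method="cholesky")
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(_LATENTS):
        if name == "age":
            cols["age"] = config.age_mean + config.age_sd * z[:, j]
        elif name == "HuntHess":
            levels = np.asarray([1, 2, 3, 4, 5])
            thr = _ordinal_thresholds(config.score_probs["HuntHess"])
            cols["HuntHess"] = levels[np.searchsorted(thr, z[:, j])]
        else:
            mu, sigma = _lognormal_params(*config.marginal_params[name])
            cols[name] = np.exp(mu + sigma * z[:, j])
    cols["sex"] = (rng.random(n) < config.sex_p).astype(int)
    for score in ("Fisher", "GOS", "mRS"):
        probs = np.asarray(config.score_probs[score], dtype=float)
        first = 0 if score == "mRS" else 1
        cols[score] = rng.choice(
            np.arange(first, first + len(probs)), size=n, p=probs / probs.sum()
        )
    cols["CVS"] = np.full(n, cvs, dtype=int)
    n_train = int(np.floor(config.split_ratio * n + 0.5))
    assignment = np.array([TRAINING] * n_train + [VALIDATION] * (n - n_train))
    cols["set"] = rng.permutation(assignment)
    return pd.DataFrame(cols)


def generate_cohort(
    config: SyntheticConfig | None = None,
    schema: VariableSchema | None = None,
) -> Cohort:
    """Sample a synthetic cohort; deterministic under ``config.rng_seed``.

    Each group stratum (CVS / no CVS) is drawn from its own latent
    covariance so that correlation structure can be planted group-
    specifically, mirroring the stratified analysis.  Patients are assigned
    to training/validation at the configured ratio within each stratum.
    """
    config = config or SyntheticConfig()
    schema = schema or default_schema()
    rng = np.random.default_rng(config.rng_seed)
    frames = [
        _sample_stratum(config.n_cvs, 1, config, rng),
        _sample_stratum(config.n_nocvs, 0, config, rng),
    ]
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, schema.id_column, [f"P{i:04d}" for i in range(1, len(df) + 1)])
    cohort = Cohort(df[[schema.id_column] + schema.names], schema)
    if config.missing_rate > 0:
        cohort = inject_missing(cohort, config.missing_rate, config.rng_seed + 1)
    return cohort


def inject_missing(cohort: Cohort, rate: float, rng_seed: int) -> Cohort:
    """Set each biomarker cell missing independently with probability *rate*.

    Emulates the panel dropout that complete-case exclusion removes.
    Reproducible under ``rng_seed``; ``rate`` 0 returns an equal cohort.
    """
    if not 0 <= rate < 1:
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    df = cohort.data.copy()
    markers = cohort.schema.biomarkers
    mask = rng.random((len(df), len(markers))) < rate
    block = df[markers].to_numpy(dtype=float)
    block[mask] = np.nan
    df[markers] = block
    return Cohort(df, cohort.schema, list(cohort.exclusion_log))
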