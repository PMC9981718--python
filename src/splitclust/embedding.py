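"""2D variable maps from correlation matrices (metric MDS / SMACOF).

Variables are embedded in the plane so that correlated variables land
close together.  The dissimilarity is ``d_ij = sqrt(2*(1 - r_ij))`` — the
Euclidean distance between standardized variables, so strongly negatively
correlated pairs map far apart (``1 - |r|`` is available as an option).
The layout is found by SMACOF stress majorization, whose Guttman update
guarantees a non-increasing stress sequence; the random initialization is
controlled by a seed.  Dimensionality reduction of 12 variables into 2D is
lossy by construction; the residual stress quantifies that loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EmbeddingCoords", "correlation_dissimilarity", "embed_2d"]


@dataclass
class EmbeddingCoords:
    """Planar coordinates per variable plus the residual stress."""

    coords: pd.DataFrame  # index: variable; columns: x, y
    stress: float
    rng_seed: int
    stress_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.stress) and self.stress >= 0):
            raise ValueError("stress must be finite and non-negative")

    def distance(self, a: str, b: str) -> float:
        d = self.coords.loc[a] - self.coords.loc[b]
        return float(np.hypot(d["x"], d["y"]))


def correlation_dissimilarity(r: np.ndarray, kind: str = "signed") -> np.ndarray:
    """Map a correlation matrix to a dissimilarity matrix.

    ``signed``: sqrt(2*(1-r)); ``absolute``: 1 - |r| (ignores the sign).
    """
    r = np.asarray(r, dtype=float)
    if kind == "signed":
        return np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))
    if kind == "absolute":
        return 1.0 - np.abs(r)
    raise ValueError("dissimilarity kind must be 'signed' or 'absolute'")


def _stress(d: np.ndarray, x: np.ndarray) -> float:
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(x), k=1)
    return float(((d[iu] - dist[iu]) ** 2).sum())


def embed_2d(
    r_matrix: np.ndarray,
    rng_seed: int = 0,
    variables: list[str] | None = None,
    dissimilarity: str = "signed",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> EmbeddingCoords:
    """SMACOF embedding of a correlation matrix into the plane.

    Deterministic under ``rng_seed``; the recorded stress history is
    non-increasing from the random initial configuration to convergence.

    Raises
    ------
    ValueError
        Non-symmetric input or a diagonal that is not 1.
    """
    r = np.asarray(r_matrix, dtype=float)
    p = len(r)
    if r.shape != (p, p) or not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(r), 1.0, atol=1e-10):
        raise ValueError("correlation matrix diagonal must be 1")
    if variables is None:
        variables = [f"v{i}" for i in range(p)]
    d = correlation_dissimilarity(r, dissimilarity)

    rng = np.random.default_rng(rng_seed)
    x = rng.normal(scale=d.max() or 1.0, size=(p, 2))
    history = [_stress(d, x)]
    for _ in range(max_iter):
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 1e-12, d / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / p  # Guttman transform (unit weights)
        history.append(_stress(d, x))
        if history[-2] - history[-1] <= tol * max(history[-2], 1e-300):
            break
    coords = pd.DataFrame(x, index=list(variables), columns=["x", "y"])
    return EmbeddingCoords(coords, history[-1], rng_seed, history)
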