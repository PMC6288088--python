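"""Metric multidimensional scaling of sample dissimilarities by SMACOF.

SMACOF minimises the raw stress sigma(X) = sum_{a<b} (d_ab - |x_a - x_b|)^2
by iterated majorization (the Guttman transform), which guarantees a
monotonically non-increasing stress sequence within each run.  Multiple
random initialisations are used and the embedding with the smallest final
stress is reported; configurations are only identified up to rotation and
reflection, so downstream comparisons should use inter-point distances, not
raw coordinates.  TINA similarities are converted to dissimilarities by
d = 1 - s (default) or d = sqrt(1 - s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import pdist, squareform

from .tina import SampleSimilarityMatrix

__all__ = [
    "MdsConfig",
    "Embedding",
    "to_dissimilarity",
    "smacof_mds",
    "is_linearly_separable",
]


@dataclass
class MdsConfig:
    n_components: int = 2
    n_init: int = 200
    max_iter: int = 20_000
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class Embedding:
    coords: np.ndarray            # n x n_components, best initialisation
    stress: float                 # raw stress of the best run
    stress_per_init: list[float]
    normalized_stress: float      # stress / sum d^2, for interpretability
    trace: list[float] = field(default_factory=list)  # stress sequence, best run


def to_dissimilarity(
    sim: SampleSimilarityMatrix | np.ndarray, transform: str = "one_minus"
) -> np.ndarray:
    """Similarity -> dissimilarity: d = 1 - s (default) or sqrt(1 - s)."""
    s = sim.tina if isinstance(sim, SampleSimilarityMatrix) else np.asarray(sim, dtype=float)
    if (s > 1 + 1e-9).any():
        raise ValueError("similarities above 1 cannot be converted")
    if transform not in ("one_minus", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    d = np.clip(1.0 - s, 0.0, None)
    if transform == "sqrt":
        d = np.sqrt(d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _smacof_single(d: np.ndarray, X: np.ndarray, max_iter: int, eps: float):
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    trace = []
    prev = None
    for _ in range(max_iter):
        D = squareform(pdist(X))
        stress = float(((d[iu] - D[iu]) ** 2).sum())
        trace.append(stress)
        if prev is not None and prev - stress < eps:
            break
        prev = stress
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(D > 0, d / D, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
    D = squareform(pdist(X))
    stress = float(((d[iu] - D[iu]) ** 2).sum())
    if not trace or stress < trace[-1]:
        trace.append(stress)
    return X, stress, trace


def smacof_mds(d: np.ndarray, config: MdsConfig | None = None) -> Embedding:
    """Best-of-``n_init`` SMACOF embedding of a dissimilarity matrix."""
    if config is None:
        config = MdsConfig()
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("dissimilarity diagonal must be zero")
    if (d < 0).any():
        raise ValueError("dissimilarities must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(3,)))
    best = None
    stresses: list[float] = []
    for _ in range(config.n_init):
        X0 = rng.standard_normal((n, config.n_components))
        X, stress, trace = _smacof_single(d, X0, config.max_iter, config.eps)
        stresses.append(stress)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best
    iu = np.triu_indices(n, 1)
    denom = float((d[iu] ** 2).sum())
    return Embedding(
        coords=X,
        stress=stress,
        stress_per_init=stresses,
        normalized_stress=stress / denom if denom > 0 else 0.0,
        trace=trace,
    )


def is_linearly_separable(coords: np.ndarray, labels) -> bool:
    """Exact two-class linear separability via an LP feasibility problem.

    Classes are separable iff there exist (w, b) with y_i (w.x_i + b) >= 1
    for all i (any strictly separating hyperplane can be rescaled to satisfy
    the margin-1 form).  Deterministic, no iterative classifier involved.
    """
    X = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = np.where(labels == classes[0], 1.0, -1.0)
    n, k = X.shape
    # variables: w (k), b; constraints -y_i (w.x_i + b) <= -1
    A_ub = -(y[:, None] * np.hstack([X, np.ones((n, 1))]))
    b_ub = -np.ones(n)
    res = linprog(
        c=np.zeros(k + 1),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * (k + 1),
        method="highs",
    )
    return bool(res.success)
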