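"""Basis (SparCC-style) correlation inference for compositional count data.

Read counts only constrain relative abundances, and closure to fractions
induces spurious negative correlations between components regardless of the
true association of the underlying absolute ("basis") abundances.  The
estimator implemented here works on the log-ratio variation matrix

    t_ij = Var_s[ ln(f_is / f_js) ] = w_i^2 + w_j^2 - 2 r_ij w_i w_j

where w_i^2 are the basis log-abundance variances and r_ij the basis
correlations.  Under the sparsity assumption (most r_ij ~ 0) the per-taxon
row sums of t give a linear system for the basis variances; solving it and
back-substituting yields r_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j),
clipped to [-1, 1].

Sampling uncertainty in the observed counts is propagated by modelling each
sample's posterior fractions as Dirichlet(counts + alpha) with a uniform
prior (alpha = 1), drawing ``n_draws`` posterior fraction matrices (100 by
default), running the estimator — including the iterative
covariance-exclusion refinement from :mod:`coocnet.refine` — on each draw,
and aggregating the per-draw correlation matrices element-wise (mean by
default, median optionally).

Significance is assessed by permutation: each permutation independently
shuffles every taxon's counts across samples, destroying all cross-taxon
structure while preserving per-taxon count distributions, and the two-sided
pseudo-p-value carries an add-one correction so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import FractionMatrix, TaxaCountTable

__all__ = [
    "PosteriorConfig",
    "BasisModel",
    "CorrelationResult",
    "dirichlet_draw",
    "variation_matrix",
    "basis_correlations",
    "sparcc_estimate",
    "permutation_pvalues",
    "naive_pearson",
]

_OMEGA_FLOOR = 1e-10


@dataclass
class PosteriorConfig:
    """Dirichlet posterior resampling settings."""

    n_draws: int = 100
    prior_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.prior_alpha <= 0:
            raise ValueError("prior_alpha must be > 0")


@dataclass
class BasisModel:
    """Fitted basis variances and correlations for one fraction matrix."""

    omega2: np.ndarray       # per-taxon basis variances
    rho: np.ndarray          # basis correlations, unit diagonal, in [-1, 1]
    cov: np.ndarray          # basis covariances rho_ij * w_i * w_j
    floored: np.ndarray      # taxa whose omega^2 solution was negative (floored)
    excluded: frozenset = frozenset()


@dataclass
class CorrelationResult:
    """Aggregated output of a multi-draw estimation run."""

    rho_mean: np.ndarray
    pvals: np.ndarray | None
    n_draws: int
    n_perm: int
    excluded_pairs: frozenset
    traces: list = field(default_factory=list)
    taxon_ids: list[str] | None = None


def dirichlet_draw(
    table: TaxaCountTable, config: PosteriorConfig, draw_index: int
) -> FractionMatrix:
    """One posterior fraction matrix: column j ~ Dirichlet(counts[:, j] + alpha).

    Reproducible from (config.seed, draw_index); different draw indices give
    independent streams.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(int(draw_index),))
    )
    g = rng.gamma(table.counts + config.prior_alpha)
    fr = g / g.sum(axis=0)
    return FractionMatrix(list(table.taxon_ids), list(table.sample_ids), fr)


def variation_matrix(fractions: FractionMatrix | np.ndarray) -> np.ndarray:
    """Pairwise log-ratio variances t_ij = Var[ln(f_i/f_j)] (n-1 denominator).

    Requires at least two samples and strictly positive fractions — counts
    should enter through the Dirichlet posterior path, which guarantees
    positivity.
    """
    f = fractions.fractions if isinstance(fractions, FractionMatrix) else np.asarray(fractions)
    if f.shape[1] < 2:
        raise ValueError("variation matrix needs at least two samples")
    if (f <= 0).any():
        raise ValueError(
            "zero or negative fraction encountered; draw posterior fractions "
            "via dirichlet_draw to guarantee positivity"
        )
    logf = np.log(f)
    c = np.cov(logf)  # rows are taxa; ddof=1
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def _active_mask(K: int, excluded) -> np.ndarray:
    mask = ~np.eye(K, dtype=bool)
    for i, j in excluded:
        mask[i, j] = mask[j, i] = False
    return mask


def basis_correlations(t: np.ndarray, excluded=()) -> BasisModel:
    """Solve for basis variances and correlations under the sparsity approximation.

    For each taxon i with m_i active partners, the row-sum identity
    sum_j t_ij = m_i w_i^2 + sum_{j in partners} w_j^2 (active pairs only)
    gives a K x K linear system solved by least squares; negative variance
    solutions are floored at 1e-10 and flagged rather than erroring so a
    degenerate draw cannot abort a multi-draw run.  Excluded pairs are
    omitted from the system but their correlation is still reported from the
    final variances.
    """
    t = np.asarray(t, dtype=float)
    K = t.shape[0]
    if K < 4:
        raise ValueError(f"need at least 4 taxa to identify basis variances, got {K}")
    if not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("variation matrix must be symmetric")
    mask = _active_mask(K, excluded)
    m = mask.sum(axis=1)
    if (m == 0).any():
        bad = np.flatnonzero(m == 0).tolist()
        raise ValueError(f"taxa with no active pairs (singular system): {bad}")
    A = mask.astype(float)
    A[np.diag_indices(K)] = m
    b = (t * mask).sum(axis=1)
    try:
        omega2 = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        omega2, *_ = np.linalg.lstsq(A, b, rcond=None)
    floored = omega2 < _OMEGA_FLOOR
    omega2 = np.clip(omega2, _OMEGA_FLOOR, None)
    w = np.sqrt(omega2)
    denom = 2.0 * np.outer(w, w)
    rho = (omega2[:, None] + omega2[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    cov = rho * np.outer(w, w)
    return BasisModel(
        omega2=omega2,
        rho=rho,
        cov=cov,
        floored=floored,
        excluded=frozenset(tuple(sorted(p)) for p in excluded),
    )


def sparcc_estimate(
    table: TaxaCountTable,
    posterior: PosteriorConfig | None = None,
    refinement=None,
    aggregate: str = "mean",
) -> CorrelationResult:
    """Full estimation: Dirichlet draws -> variation matrix -> refinement -> basis fit.

    With ``n_draws=1`` this reduces to a single basic + refined run.  The
    aggregated matrix is symmetric with unit diagonal; the excluded-pair
    record is the union over draws, and each draw's refinement trace is kept.
    """
    from .refine import RefinementConfig, iterative_refinement  # deferred: avoids cycle

    if posterior is None:
        posterior = PosteriorConfig()
    if refinement is None:
        refinement = RefinementConfig()
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")

    rho_stack = np.empty((posterior.n_draws, table.n_taxa, table.n_taxa))
    excluded_union: set = set()
    traces = []
    for d in range(posterior.n_draws):
        fr = dirichlet_draw(table, posterior, d)
        t = variation_matrix(fr)
        model, excluded, trace = iterative_refinement(t, refinement)
        rho_stack[d] = model.rho
        excluded_union.update(excluded)
        traces.append(trace)
    rho = rho_stack.mean(axis=0) if aggregate == "mean" else np.median(rho_stack, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationResult(
        rho_mean=rho,
        pvals=None,
        n_draws=posterior.n_draws,
        n_perm=0,
        excluded_pairs=frozenset(excluded_union),
        traces=traces,
        taxon_ids=list(table.taxon_ids),
    )


def permutation_pvalues(
    table: TaxaCountTable,
    rho_obs: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    *,
    prior_alpha: float = 1.0,
    full_pipeline: bool = False,
    posterior: PosteriorConfig | None = None,
    refinement=None,
) -> np.ndarray:
    """Two-sided permutation pseudo-p-values with add-one correction.

    Each permutation shuffles every taxon's counts across samples
    independently, then re-estimates the correlation matrix from a single
    posterior draw without refinement (set ``full_pipeline=True`` to rerun
    the complete multi-draw refined pipeline per permutation instead).
    p_ij = (1 + #{perm : |rho_perm| >= |rho_obs|}) / (1 + n_perm), so every
    p lies in (0, 1] and the smallest attainable value is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rho_obs = np.asarray(rho_obs)
    K = table.n_taxa
    if rho_obs.shape != (K, K):
        raise ValueError("rho_obs does not match the table's taxa")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    abs_obs = np.abs(rho_obs)
    exceed = np.zeros((K, K), dtype=np.int64)
    for p in range(n_perm):
        counts = rng.permuted(table.counts, axis=1)
        perm_table = TaxaCountTable(list(table.taxon_ids), list(table.sample_ids), counts)
        if full_pipeline:
            res = sparcc_estimate(
                perm_table,
                posterior=posterior,
                refinement=refinement,
            )
            rho_p = res.rho_mean
        else:
            g = rng.gamma(counts + prior_alpha)
            fr = g / g.sum(axis=0)
            t = variation_matrix(fr)
            rho_p = basis_correlations(t).rho
        exceed += np.abs(rho_p) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 1.0)
    return pvals


def naive_pearson(fractions: FractionMatrix | np.ndarray) -> np.ndarray:
    """Plain Pearson correlation between taxa computed directly on fractions.

    This is the estimator the basis-correlation machinery exists to replace:
    on closed compositions it is biased negative even for independent taxa.
    Kept as an explicit contrast/diagnostic.
    """
    f = fractions.fractions if isinstance(fractions, FractionMatrix) else np.asarray(fractions)
    return np.corrcoef(f)
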