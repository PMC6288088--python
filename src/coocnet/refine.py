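"""Iterative exclusion of extreme-covariance pairs from the variation matrix.

The basis-correlation solve assumes the average pairwise covariance is
small.  Strongly associated pairs violate that assumption and contaminate
the variance estimates, so they are removed from the least-squares system
iteratively: at each step the model is refit, pairs are ranked by their
signed basis covariance c_ij = rho_ij * w_i * w_j, and a small batch —
0.025% of the currently active pairs (minimum one) from the top of the
positive tail and the same from the negative tail — is excluded.  Excluded
pairs drop out of the fitting system only; their correlation is still
reported from the final variances.

Stopping follows a sliding-window rule on the total covariance
C_k = sum of |c_ij| over active pairs: the procedure repeats while C has
decreased *significantly* over the last ``window`` (default 10) iterations.
Because every exclusion mechanically removes that pair's |c| from C, a raw
relative-decrease threshold cannot distinguish genuine refinement from
bookkeeping; the default rule therefore compares the windowed relative
decrease of C against the windowed fraction of active pairs removed (the
decrease expected if excluded pairs carried merely average weight) and stops
once the former no longer exceeds ``excess_factor`` times the latter — i.e.
once the removed pairs stop being covariance outliers.  A literal
fixed-threshold variant (``stop_rule="fixed"`` with ``rel_tol``) is kept for
comparison.  The loop additionally terminates at ``max_iter`` or when the
active-pair count would fall below the solvability floor of 3(K-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sparcc import BasisModel, basis_correlations

__all__ = [
    "RefinementConfig",
    "RefinementTrace",
    "pair_covariances",
    "batch_size",
    "total_covariance",
    "iterative_refinement",
]


@dataclass
class RefinementConfig:
    batch_fraction: float = 0.00025   # 0.025% of active pairs, per tail
    window: int = 10
    rel_tol: float = 1e-3             # used by stop_rule="fixed"
    max_iter: int = 500
    enabled: bool = True
    stop_rule: str = "excess"         # "excess" (default) or "fixed"
    excess_factor: float = 3.0
    ranking: str = "signed"           # "signed" or "absolute"

    def __post_init__(self) -> None:
        if not (0.0 < self.batch_fraction < 1.0):
            raise ValueError("batch_fraction must be in (0, 1)")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.stop_rule not in ("excess", "fixed"):
            raise ValueError("stop_rule must be 'excess' or 'fixed'")
        if self.ranking not in ("signed", "absolute"):
            raise ValueError("ranking must be 'signed' or 'absolute'")
        if self.excess_factor <= 0:
            raise ValueError("excess_factor must be > 0")


@dataclass
class RefinementTrace:
    """Per-iteration record of the refinement loop."""

    total_covariance: list[float] = field(default_factory=list)
    n_excluded_cumulative: list[int] = field(default_factory=list)
    n_active: list[int] = field(default_factory=list)
    stopped_reason: str = "not_run"

    def to_jsonable(self) -> dict:
        return {
            "total_covariance": self.total_covariance,
            "n_excluded_cumulative": self.n_excluded_cumulative,
            "n_active": self.n_active,
            "stopped_reason": self.stopped_reason,
        }


def pair_covariances(model: BasisModel, active) -> list[tuple[tuple[int, int], float]]:
    """Active pairs with their signed basis covariance, sorted descending.

    Ties are broken by the lexicographic (i, j) index pair so the ordering —
    and hence every downstream exclusion — is deterministic.
    """
    active = list(active)
    if not active:
        raise ValueError("empty active pair set")
    items = [((int(i), int(j)), float(model.cov[i, j])) for i, j in active]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items


def batch_size(n_active_pairs: int, batch_fraction: float) -> int:
    """ceil(n_active_pairs * batch_fraction), never below one pair."""
    if n_active_pairs < 1:
        raise ValueError("n_active_pairs must be >= 1")
    return max(1, int(np.ceil(n_active_pairs * batch_fraction)))


def total_covariance(model: BasisModel, active) -> float:
    """Sum of |c_ij| over the active pairs — the stopping statistic."""
    return float(sum(abs(model.cov[i, j]) for i, j in active))


def _select_batch(items, nb: int, ranking: str):
    """Pairs to exclude this iteration, from the covariance-sorted list."""
    if ranking == "signed":
        top = [p for p, _ in items[:nb]]
        bottom = [p for p, _ in items[-nb:]]
        return list(dict.fromkeys(top + bottom))
    by_abs = sorted(items, key=lambda kv: (-abs(kv[1]), kv[0]))
    return [p for p, _ in by_abs[: 2 * nb]]


def iterative_refinement(
    t: np.ndarray, config: RefinementConfig | None = None
) -> tuple[BasisModel, frozenset, RefinementTrace]:
    """Run the exclusion loop on a variation matrix.

    Returns the final fitted model, the excluded pair set, and the trace.
    With ``config.enabled=False`` this is a single basic fit with an empty
    exclusion set.
    """
    if config is None:
        config = RefinementConfig()
    t = np.asarray(t, dtype=float)
    if not np.allclose(t, t.T, atol=1e-8):
        raise ValueError("variation matrix must be symmetric")
    K = t.shape[0]
    all_pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]

    if not config.enabled:
        model = basis_correlations(t)
        trace = RefinementTrace(
            total_covariance=[total_covariance(model, all_pairs)],
            n_excluded_cumulative=[0],
            n_active=[len(all_pairs)],
            stopped_reason="disabled",
        )
        return model, frozenset(), trace

    floor = 3 * (K - 1)
    excluded: set[tuple[int, int]] = set()
    trace = RefinementTrace()
    model = basis_correlations(t)
    reason = "max_iter"
    for it in range(config.max_iter):
        active = [p for p in all_pairs if p not in excluded]
        c_total = total_covariance(model, active)
        trace.total_covariance.append(c_total)
        trace.n_excluded_cumulative.append(len(excluded))
        trace.n_active.append(len(active))

        k = len(trace.total_covariance) - 1
        if k >= config.window:
            c0 = trace.total_covariance[k - config.window]
            rel = (c0 - c_total) / c0 if c0 > 0 else 0.0
            if config.stop_rule == "fixed":
                threshold = config.rel_tol
            else:
                n0 = trace.n_active[k - config.window]
                mech = (n0 - len(active)) / n0 if n0 > 0 else 0.0
                threshold = config.excess_factor * mech
            if rel < threshold:
                reason = "window_converged"
                break
        if len(active) <= floor:
            reason = "exhausted"
            break

        nb = batch_size(len(active), config.batch_fraction)
        items = pair_covariances(model, active)
        for pair in _select_batch(items, nb, config.ranking):
            excluded.add(pair)
        model = basis_correlations(t, excluded)

    trace.stopped_reason = reason
    return model, frozenset(excluded), trace
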