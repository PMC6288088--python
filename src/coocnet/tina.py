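"""Weighted taxa-interaction-adjusted (TINA) similarity between samples.

Classical abundance-based sample similarities treat taxa as mutually
independent; TINA instead weights shared abundance through a taxon-taxon
association matrix, so two samples dominated by *different but strongly
associated* taxa still score as similar.  The association matrix is built
from the basis correlation matrix by correlating taxa through their profiles
of pairwise associations to all other taxa and mapping the resulting Pearson
correlation onto [0, 1] via s = (1 + r)/2.  The weighted index between
samples a and b with fraction vectors p_a, p_b is

    TINA(a, b) = (p_a' S p_b) / sqrt( (p_a' S p_a) (p_b' S p_b) ),

a cosine-like similarity in the S-weighted inner product: it equals one for
identical compositions, reduces exactly to cosine similarity when S is the
identity, and depends on fractions only (sample depth cancels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tables import TaxaCountTable, relative_abundances

__all__ = [
    "TaxaSimilarityMatrix",
    "SampleSimilarityMatrix",
    "association_similarity",
    "tina_weighted",
    "tina_matrix",
]


@dataclass
class TaxaSimilarityMatrix:
    """Taxon association similarity s_ij in [0, 1], symmetric, unit diagonal."""

    s: np.ndarray
    taxon_ids: list[str] | None = None
    constant_taxa: tuple[int, ...] = ()   # taxa with zero-variance profiles (flagged)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.allclose(self.s, self.s.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if (self.s < -1e-9).any() or (self.s > 1 + 1e-9).any():
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(self.s), 1.0, atol=1e-9):
            raise ValueError("similarity diagonal must be 1")


@dataclass
class SampleSimilarityMatrix:
    sample_ids: list[str]
    tina: np.ndarray

    def __post_init__(self) -> None:
        self.tina = np.asarray(self.tina, dtype=float)
        if not np.allclose(self.tina, self.tina.T, atol=1e-9):
            raise ValueError("TINA matrix must be symmetric")


def association_similarity(
    rho: np.ndarray,
    taxon_ids: list[str] | None = None,
    include_self: bool = True,
) -> TaxaSimilarityMatrix:
    """Pearson-profile similarity of taxa through their association rows.

    r*_ij is the Pearson correlation between row i and row j of the
    correlation matrix (each taxon's profile of associations to all taxa);
    s_ij = (1 + r*_ij)/2 and the diagonal is forced to one.  A taxon whose
    profile has zero variance carries no association information: its
    off-diagonal similarities are set to the uninformative value 0.5 and the
    taxon index is flagged.  ``include_self=False`` drops entries i and j
    from both profiles before correlating (the two readings of "pairwise
    associations to all other taxa").
    """
    rho = np.asarray(rho, dtype=float)
    K = rho.shape[0]
    if rho.shape != (K, K):
        raise ValueError("rho must be square")
    if not np.allclose(rho, rho.T, atol=1e-8):
        raise ValueError("rho must be symmetric")

    if include_self:
        x = rho - rho.mean(axis=1, keepdims=True)
        norms = np.sqrt((x * x).sum(axis=1))
        constant = norms < 1e-12
        safe = np.where(constant, 1.0, norms)
        r = (x @ x.T) / np.outer(safe, safe)
    else:
        r = np.eye(K)
        constant_set = set()
        idx = np.arange(K)
        for i in range(K):
            for j in range(i + 1, K):
                keep = (idx != i) & (idx != j)
                a = rho[i, keep]
                b = rho[j, keep]
                sa, sb = a.std(), b.std()
                if sa < 1e-12 or sb < 1e-12:
                    if sa < 1e-12:
                        constant_set.add(i)
                    if sb < 1e-12:
                        constant_set.add(j)
                    continue
                r[i, j] = r[j, i] = float(np.corrcoef(a, b)[0, 1])
        constant = np.zeros(K, dtype=bool)
        constant[sorted(constant_set)] = True

    r = np.clip(r, -1.0, 1.0)
    s = (1.0 + r) / 2.0
    s[constant, :] = 0.5
    s[:, constant] = 0.5
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return TaxaSimilarityMatrix(
        s=s,
        taxon_ids=list(taxon_ids) if taxon_ids is not None else None,
        constant_taxa=tuple(int(i) for i in np.flatnonzero(constant)),
    )


def tina_weighted(p_a: np.ndarray, p_b: np.ndarray, s: TaxaSimilarityMatrix | np.ndarray) -> float:
    """Weighted TINA index between two fraction vectors over the taxa of ``s``."""
    S = s.s if isinstance(s, TaxaSimilarityMatrix) else np.asarray(s, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != (S.shape[0],) or p_b.shape != (S.shape[0],):
        raise ValueError("fraction vectors must align with the similarity matrix")
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must sum to 1 (got {p.sum():.6g})")
    num = float(p_a @ S @ p_b)
    den_a = float(p_a @ S @ p_a)
    den_b = float(p_b @ S @ p_b)
    if den_a <= 0 or den_b <= 0:
        raise ValueError("zero TINA denominator (all-zero similarity block)")
    if np.array_equal(p_a, p_b):
        return 1.0  # self-similarity is exactly one by definition
    return num / np.sqrt(den_a * den_b)


def tina_matrix(
    table: TaxaCountTable, s: TaxaSimilarityMatrix | np.ndarray
) -> SampleSimilarityMatrix:
    """Pairwise weighted TINA over the table's relative-abundance columns."""
    S = s.s if isinstance(s, TaxaSimilarityMatrix) else np.asarray(s, dtype=float)
    if isinstance(s, TaxaSimilarityMatrix) and s.taxon_ids is not None:
        if list(s.taxon_ids) != list(table.taxon_ids):
            offending = sorted(
                set(s.taxon_ids).symmetric_difference(table.taxon_ids)
            ) or ["<same ids, different order>"]
            raise ValueError(f"taxa misaligned between table and similarity: {offending}")
    if S.shape[0] != table.n_taxa:
        raise ValueError(
            f"similarity has {S.shape[0]} taxa but table has {table.n_taxa}"
        )
    P = relative_abundances(table).fractions  # (K, n)
    W = P.T @ S @ P
    d = np.sqrt(np.diag(W))
    if (d <= 0).any():
        bad = [table.sample_ids[j] for j in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero TINA self-weight for sample(s): {bad}")
    M = W / np.outer(d, d)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return SampleSimilarityMatrix(sample_ids=list(table.sample_ids), tina=M)
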