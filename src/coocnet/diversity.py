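"""Per-sample nonparametric diversity statistics.

Three indices are computed per sample from its genus-level count vector:

* Chao1 richness: S_obs + f1^2 / (2 f2), falling back to the bias-corrected
  form S_obs + f1 (f1 - 1) / (2 (f2 + 1)) when there are no doubletons,
  where f1 and f2 are the numbers of singleton and doubleton taxa.
* Nonparametric Shannon diversity: the Chao-Shen coverage-adjusted
  Horvitz-Thompson estimator.  With sample coverage C = 1 - f1/n and
  coverage-adjusted proportions p_i = C * x_i / n, the estimator is
  H = -sum_i p_i ln(p_i) / (1 - (1 - p_i)^n), in nats.  The plug-in
  -sum p ln p is exposed alongside for comparison.
* Effective number of OTUs: the order-1 Hill number exp(H) — the number of
  equally common taxa giving the same Shannon entropy.  The exponential
  identity only holds with H in natural-log units, which is what this module
  uses throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tables import TaxaCountTable

__all__ = [
    "chao1",
    "shannon_np",
    "shannon_plugin",
    "effective_otus",
    "diversity_table",
]


def _clean_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if not np.issubdtype(c.dtype, np.integer):
        ci = c.astype(np.int64)
        if not np.array_equal(ci, c):
            raise ValueError("counts must be integers")
        c = ci
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    return c


def chao1(counts) -> float:
    """Chao1 richness estimate; always >= the observed taxon count."""
    c = _clean_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_np(counts) -> float:
    """Chao-Shen coverage-adjusted Shannon entropy (nats)."""
    c = _clean_counts(counts)
    n = int(c.sum())
    f1 = int((c == 1).sum())
    if f1 == n:
        raise ValueError(
            "estimated coverage is zero (every read a singleton); "
            "the coverage-adjusted estimator is undefined"
        )
    coverage = 1.0 - f1 / n
    p = c[c > 0] / n
    pa = coverage * p
    return float(-np.sum(pa * np.log(pa) / (1.0 - (1.0 - pa) ** n)))


def shannon_plugin(counts) -> float:
    """Plug-in (maximum-likelihood) Shannon entropy (nats)."""
    c = _clean_counts(counts)
    p = c[c > 0] / c.sum()
    return float(-np.sum(p * np.log(p)))


def effective_otus(shannon: float) -> float:
    """Hill number of order 1: exp(Shannon entropy in nats)."""
    if shannon < 0:
        raise ValueError(f"Shannon entropy must be non-negative, got {shannon}")
    return float(np.exp(shannon))


def diversity_table(table: TaxaCountTable) -> pd.DataFrame:
    """Per-sample diversity summary mirroring a sequencing-library table.

    Columns: sample_id, n_reads, s_obs, f1, f2, chao1, shannon_np,
    effective_otus.  Computed on the raw (unfiltered) table, since abundance
    filtering is a pre-processing step for correlation and similarity
    analyses only.
    """
    rows = []
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        h = shannon_np(c)
        rows.append(
            {
                "sample_id": sid,
                "n_reads": int(c.sum()),
                "s_obs": int((c > 0).sum()),
                "f1": int((c == 1).sum()),
                "f2": int((c == 2).sum()),
                "chao1": chao1(c),
                "shannon_np": h,
                "effective_otus": effective_otus(h),
            }
        )
    return pd.DataFrame(rows)
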