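"""Count tables, metadata and taxonomy I/O, plus abundance filtering.

The universal input of the pipeline is a genus-level taxa x sample table of
non-negative integer read counts (TSV, taxa as rows).  Relative abundances
are per-sample fractions; the abundance filter keeps taxa whose mean (or,
optionally, maximum) relative abundance across samples is strictly greater
than a threshold, 0.1% by default.  The filter is applied before all
correlation and similarity stages; diversity indices are computed on the
unfiltered table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_GROUPS = ("ciliate", "gut")

METADATA_COLUMNS = ("sample_id", "group", "species_label", "country")


@dataclass
class TaxaCountTable:
    """Integer read counts, taxa x samples, with stable row/column identifiers.

    Invariants: unique ids, all counts >= 0, every sample column sum > 0.
    Row and column order is preserved from the source everywhere; no silent
    re-sorting, so matrices derived from the same table stay alignable.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dups = sorted({t for t in self.taxon_ids if self.taxon_ids.count(t) > 1})
            raise ValueError(f"duplicate taxon ids: {dups}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dups = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dups}")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            bad = [self.sample_ids[j] for j in np.flatnonzero(sums == 0)]
            raise ValueError(f"zero-depth sample column(s): {bad}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TaxaCountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_taxa(self, keep: np.ndarray) -> "TaxaCountTable":
        """New table restricted to taxa where ``keep`` (bool mask) is True."""
        keep = np.asarray(keep, dtype=bool)
        ids = [t for t, k in zip(self.taxon_ids, keep) if k]
        return TaxaCountTable(ids, list(self.sample_ids), self.counts[keep])


@dataclass
class FractionMatrix:
    """Per-sample relative abundances; each column sums to one."""

    taxon_ids: list[str]
    sample_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < 0).any():
            raise ValueError("fractions must be non-negative")
        colsums = self.fractions.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1 within 1e-9")


def read_count_table(path: str | Path) -> TaxaCountTable:
    """Read a tab-separated count table (taxa rows, sample columns).

    The header row carries sample ids, the first column taxon ids.  Duplicate
    ids, negative or non-integer counts and zero-sum sample columns are
    rejected with an error naming the offending cell or sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate taxon ids in {path}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                x = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count {cell!r} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                ) from None
            if x != int(x):
                raise ValueError(
                    f"non-integer count {cell!r} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            if x < 0:
                raise ValueError(
                    f"negative count {cell!r} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            values[i, j] = int(x)
    return TaxaCountTable(list(df.index), list(df.columns), values)


def write_count_table(table: TaxaCountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, group, species_label, country)."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    bad = sorted(set(md["group"]) - set(VALID_GROUPS))
    if bad:
        raise ValueError(f"unknown group label(s) {bad}; expected {VALID_GROUPS}")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return md


def align_metadata(md: pd.DataFrame, table: TaxaCountTable) -> pd.DataFrame:
    """Metadata reindexed to the table's sample order; every sample must resolve."""
    missing = [s for s in table.sample_ids if s not in set(md["sample_id"])]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    return md.set_index("sample_id").loc[table.sample_ids].reset_index()


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read the taxon_id -> phylum map (TSV, two or more columns)."""
    tx = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in tx.columns or "phylum" not in tx.columns:
        raise ValueError("taxonomy file needs columns taxon_id and phylum")
    return dict(zip(tx["taxon_id"], tx["phylum"]))


def phylum_of(taxonomy: dict[str, str], taxon_id: str) -> str:
    """Total lookup: unknown taxa map to the explicit label 'Unclassified'."""
    return taxonomy.get(taxon_id, "Unclassified")


def relative_abundances(table: TaxaCountTable) -> FractionMatrix:
    """Column-normalised fractions: entry (i, j) = counts[i, j] / depth(j)."""
    depths = table.counts.sum(axis=0)
    if (depths == 0).any():
        bad = [table.sample_ids[j] for j in np.flatnonzero(depths == 0)]
        raise ValueError(f"zero-depth sample column(s): {bad}")
    fr = table.counts / depths[None, :]
    return FractionMatrix(list(table.taxon_ids), list(table.sample_ids), fr)


def filter_by_abundance(
    table: TaxaCountTable,
    threshold: float = 0.001,
    mode: str = "mean",
) -> TaxaCountTable:
    """Keep taxa whose relative abundance is strictly greater than ``threshold``.

    ``mode="mean"`` (default) compares the mean relative abundance across all
    samples — one global filter producing one global taxon list; ``mode="max"``
    compares the per-sample maximum instead.  The boundary is exclusive: a
    taxon sitting exactly at the threshold is removed.  The sample set is
    never changed, and filtering an already-filtered table is the identity.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if mode not in ("mean", "max"):
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    fr = relative_abundances(table).fractions
    stat = fr.mean(axis=1) if mode == "mean" else fr.max(axis=1)
    keep = stat > threshold
    if not keep.any():
        raise ValueError("abundance filter removed every taxon")
    return table.subset_taxa(keep)
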