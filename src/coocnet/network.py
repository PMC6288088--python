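"""Thresholded co-occurrence network construction and export.

Edges are the taxon pairs whose correlation passes |rho| > r_threshold
(strictly) *and* p < p_threshold (strictly); every taxon is kept as a node
even when isolated, carrying its mean relative abundance across the full
dataset, its phylum, and the ratio of its mean relative abundance in
ciliate samples to gut-content samples (with a symmetric pseudocount so
group-absent taxa stay finite; log2 of the ratio is stored alongside for
colour mapping).  No multiple-testing correction is applied by default —
edge selection deliberately mirrors a raw per-pair p < 0.05 rule — but a
Benjamini-Hochberg switch is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io_tables import TaxaCountTable, phylum_of, relative_abundances

__all__ = ["NetworkConfig", "abundance_ratio", "build_network", "export_network"]


@dataclass
class NetworkConfig:
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    ratio_pseudocount: float = 1e-6
    fdr_bh: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in [0, 1)")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.ratio_pseudocount <= 0:
            raise ValueError("ratio_pseudocount must be > 0")


def _group_masks(table: TaxaCountTable, metadata: pd.DataFrame):
    md = metadata.set_index("sample_id").loc[table.sample_ids]
    groups = md["group"].to_numpy()
    cil = groups == "ciliate"
    gut = groups == "gut"
    if not cil.any() or not gut.any():
        raise ValueError("both ciliate and gut groups must be non-empty")
    return cil, gut


def abundance_ratio(
    table: TaxaCountTable, metadata: pd.DataFrame, pseudocount: float = 1e-6
) -> np.ndarray:
    """Per-taxon (mean ciliate abundance + eps) / (mean gut abundance + eps)."""
    cil, gut = _group_masks(table, metadata)
    fr = relative_abundances(table).fractions
    mean_cil = fr[:, cil].mean(axis=1)
    mean_gut = fr[:, gut].mean(axis=1)
    return (mean_cil + pseudocount) / (mean_gut + pseudocount)


def build_network(
    rho: np.ndarray,
    pvals: np.ndarray,
    table: TaxaCountTable,
    metadata: pd.DataFrame,
    taxonomy: dict[str, str],
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Co-occurrence graph with node abundance/phylum/group-ratio attributes."""
    if config is None:
        config = NetworkConfig()
    rho = np.asarray(rho, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    K = table.n_taxa
    if rho.shape != (K, K) or pvals.shape != (K, K):
        raise ValueError(
            f"matrix shapes {rho.shape}/{pvals.shape} misaligned with the "
            f"table's {K} taxa ids"
        )

    fr = relative_abundances(table).fractions
    mean_abundance = fr.mean(axis=1)
    ratio = abundance_ratio(table, metadata, config.ratio_pseudocount)

    g = nx.Graph()
    g.graph["r_threshold"] = config.r_threshold
    g.graph["p_threshold"] = config.p_threshold
    for i, tid in enumerate(table.taxon_ids):
        g.add_node(
            tid,
            abundance=float(mean_abundance[i]),
            phylum=phylum_of(taxonomy, tid),
            group_ratio=float(ratio[i]),
            log2_group_ratio=float(np.log2(ratio[i])),
        )

    iu = np.triu_indices(K, 1)
    p_used = pvals.copy()
    if config.fdr_bh:
        adj = false_discovery_control(pvals[iu], method="bh")
        p_used[iu] = adj
        p_used[(iu[1], iu[0])] = adj
    for i, j in zip(*iu):
        r = rho[i, j]
        p = p_used[i, j]
        if abs(r) > config.r_threshold and p < config.p_threshold:
            g.add_edge(
                table.taxon_ids[i],
                table.taxon_ids[j],
                rho=float(r),
                p=float(p),
                sign="positive" if r > 0 else "negative",
            )
    return g


def export_network(
    net: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path | None = None
) -> None:
    """Write GraphML (node + edge attributes) and optionally a flat edge-list TSV."""
    nx.write_graphml(net, str(graphml_path))
    if edgelist_path is not None:
        rows = [
            {"taxon_a": a, "taxon_b": b, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for a, b, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"]).to_csv(
            edgelist_path, sep="\t", index=False
        )
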