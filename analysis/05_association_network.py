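"""Thresholded co-occurrence network of the simulated community.

Keeps pairs with |rho| > 0.5 and p < 0.05 as edges, attaches node abundance,
phylum and ciliate/gut abundance-ratio attributes, exports GraphML and an
edge list, and checks the signature pattern: negative edges should bridge
taxa whose group affinities fall on opposite sides of one.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from coocnet.io_tables import (
    filter_by_abundance,
    read_count_table,
    read_metadata,
    read_taxonomy,
)
from coocnet.network import NetworkConfig, build_network, export_network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--r-threshold", type=float, default=0.5)
    ap.add_argument("--p-threshold", type=float, default=0.05)
    args = ap.parse_args()

    data = args.outdir / "data"
    table = filter_by_abundance(read_count_table(data / "counts.tsv"))
    metadata = read_metadata(data / "metadata.tsv")
    taxonomy = read_taxonomy(data / "taxonomy.tsv")
    rho = pd.read_csv(args.outdir / "sparcc_rho.tsv", sep="\t", index_col=0).to_numpy()
    pvals = pd.read_csv(args.outdir / "sparcc_pvalues.tsv", sep="\t", index_col=0).to_numpy()

    net = build_network(
        rho, pvals, table, metadata, taxonomy,
        NetworkConfig(r_threshold=args.r_threshold, p_threshold=args.p_threshold),
    )
    export_network(net, args.outdir / "network.graphml",
                   args.outdir / "network_edges.tsv")

    pos = [(a, b) for a, b, d in net.edges(data=True) if d["sign"] == "positive"]
    neg = [(a, b) for a, b, d in net.edges(data=True) if d["sign"] == "negative"]
    print(f"network: {net.number_of_nodes()} nodes, "
          f"{len(pos)} positive + {len(neg)} negative edges "
          f"(|rho| > {args.r_threshold}, p < {args.p_threshold})")
    ratio = {n: d["group_ratio"] for n, d in net.nodes(data=True)}
    if neg:
        opposite = np.mean([(ratio[a] - 1) * (ratio[b] - 1) < 0 for a, b in neg])
        print(f"negative edges bridging opposite group affinities: {opposite:.0%}")
    if pos:
        same = np.mean([(ratio[a] - 1) * (ratio[b] - 1) > 0 for a, b in pos])
        print(f"positive edges within one affinity side: {same:.0%}")
    print(f"wrote network.graphml and network_edges.tsv to {args.outdir}")


if __name__ == "__main__":
    main()
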