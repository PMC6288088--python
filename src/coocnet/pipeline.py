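"""End-to-end orchestration: filter -> diversity -> correlations -> TINA -> MDS -> network.

A single :class:`RunConfig` (optionally loaded from YAML) drives the whole
pipeline; all randomness is derived from one global seed through named
per-stage substreams, every stage writes its artifact under ``outdir``, and
a JSON manifest records parameters, per-stage seeds, row/edge counts and
SHA-256 checksums of every artifact so a rerun with the same config can be
verified bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table
from .io_tables import (
    TaxaCountTable,
    align_metadata,
    filter_by_abundance,
    read_count_table,
    read_metadata,
    read_taxonomy,
)
from .network import NetworkConfig, build_network, export_network
from .ordination import MdsConfig, smacof_mds, to_dissimilarity
from .refine import RefinementConfig
from .sparcc import PosteriorConfig, permutation_pvalues, sparcc_estimate
from .tina import association_similarity, tina_matrix

__all__ = ["RunConfig", "run_pipeline"]

# stable stage ordering; also the substream indices for per-stage seeds
_STAGES = ("filter", "diversity", "sparcc", "permutation", "tina", "mds", "network")


@dataclass
class RunConfig:
    table_path: str
    metadata_path: str
    taxonomy_path: str | None
    outdir: str
    filter_threshold: float = 0.001
    filter_mode: str = "mean"
    posterior: PosteriorConfig = field(default_factory=PosteriorConfig)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    mds: MdsConfig = field(default_factory=MdsConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_perm: int = 100
    seed: int = 0
    tina_include_self: bool = True
    dissimilarity_transform: str = "one_minus"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, sub in (
            ("posterior", PosteriorConfig),
            ("refinement", RefinementConfig),
            ("mds", MdsConfig),
            ("network", NetworkConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _stage_seed(global_seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(100 + idx,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix(m: np.ndarray, ids: list[str], path: Path) -> None:
    pd.DataFrame(m, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="id", float_format="%.10g"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest.

    Any stage error aborts the run with the stage name attached; stages
    completed so far are still listed in the raised error's manifest context.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "coocnet_version": __version__,
        "config": config.to_jsonable(),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGES},
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, path: Path, **counts) -> None:
        manifest["artifacts"][path.name] = _sha256(path)
        manifest["stages"].setdefault(stage, {}).update(counts)

    stage = "load"
    try:
        table = read_count_table(config.table_path)
        metadata = align_metadata(read_metadata(config.metadata_path), table)
        taxonomy = (
            read_taxonomy(config.taxonomy_path) if config.taxonomy_path else {}
        )

        stage = "filter"
        filtered = filter_by_abundance(table, config.filter_threshold, config.filter_mode)
        p = outdir / "filtered_table.tsv"
        filtered.to_dataframe().to_csv(p, sep="\t", index_label="taxon_id")
        record(stage, p, taxa_before=table.n_taxa, taxa_after=filtered.n_taxa)

        stage = "diversity"  # computed on the unfiltered table
        div = diversity_table(table)
        p = outdir / "diversity.tsv"
        div.to_csv(p, sep="\t", index=False, float_format="%.6f")
        record(stage, p, samples=len(div))

        stage = "sparcc"
        posterior = PosteriorConfig(
            n_draws=config.posterior.n_draws,
            prior_alpha=config.posterior.prior_alpha,
            seed=_stage_seed(config.seed, "sparcc"),
        )
        result = sparcc_estimate(filtered, posterior, config.refinement)
        p = outdir / "sparcc_rho.tsv"
        _write_matrix(result.rho_mean, filtered.taxon_ids, p)
        record(stage, p, n_draws=result.n_draws,
               excluded_pairs=len(result.excluded_pairs))
        p = outdir / "sparcc_runlog.json"
        runlog = {
            "posterior": asdict(posterior),
            "refinement": asdict(config.refinement),
            "excluded_pairs": sorted(
                [list(pair) for pair in result.excluded_pairs]
            ),
            "traces": [t.to_jsonable() for t in result.traces],
        }
        p.write_text(json.dumps(runlog, sort_keys=True))
        record(stage, p)

        stage = "permutation"
        pvals = permutation_pvalues(
            filtered,
            result.rho_mean,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "permutation"),
            prior_alpha=config.posterior.prior_alpha,
        )
        p = outdir / "sparcc_pvalues.tsv"
        _write_matrix(pvals, filtered.taxon_ids, p)
        record(stage, p, n_perm=config.n_perm)

        stage = "tina"
        sim = association_similarity(
            result.rho_mean, filtered.taxon_ids, include_self=config.tina_include_self
        )
        sample_sim = tina_matrix(filtered, sim)
        p = outdir / "tina_similarity.tsv"
        pd.DataFrame(
            sample_sim.tina, index=sample_sim.sample_ids, columns=sample_sim.sample_ids
        ).to_csv(p, sep="\t", index_label="sample_id", float_format="%.10g")
        record(stage, p, constant_taxa=len(sim.constant_taxa))

        stage = "mds"
        d = to_dissimilarity(sample_sim, config.dissimilarity_transform)
        mds_cfg = MdsConfig(
            n_components=config.mds.n_components,
            n_init=config.mds.n_init,
            max_iter=config.mds.max_iter,
            eps=config.mds.eps,
            seed=_stage_seed(config.seed, "mds"),
        )
        emb = smacof_mds(d, mds_cfg)
        p = outdir / "mds_coords.tsv"
        coords = pd.DataFrame(
            emb.coords,
            index=sample_sim.sample_ids,
            columns=[f"dim{i + 1}" for i in range(emb.coords.shape[1])],
        )
        coords.insert(0, "group", metadata.set_index("sample_id").loc[
            sample_sim.sample_ids, "group"].to_numpy())
        coords.to_csv(p, sep="\t", index_label="sample_id", float_format="%.10g")
        record(stage, p, stress=emb.stress, normalized_stress=emb.normalized_stress)

        stage = "network"
        net = build_network(
            result.rho_mean, pvals, filtered, metadata, taxonomy, config.network
        )
        p_gml = outdir / "network.graphml"
        p_edges = outdir / "network_edges.tsv"
        export_network(net, p_gml, p_edges)
        record(stage, p_gml, nodes=net.number_of_nodes(), edges=net.number_of_edges())
        record(stage, p_edges)
    except Exception as exc:  # noqa: BLE001 — annotate with the failing stage
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
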