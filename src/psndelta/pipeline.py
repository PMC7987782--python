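"""End-to-end wildtype/mutant comparison: one report per structure pair.

``compare_chains`` orchestrates the full analysis on in-memory chains;
``compare_pair`` wraps it with file reading, ``batch_compare`` runs a
manifest of pairs and produces a scatter-ready summary table (pair id, n,
RMSD, NDS components, edge/hub partition counts) with mean/SD rows.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import ChainModel, read_structure, quality_filter, compute_exposure
from .psn_builder import (
    NormalizationTable,
    build_psn,
    DEFAULT_CUTOFF,
    DEFAULT_HUB_THRESHOLD,
    DEFAULT_MIN_SEQ_SEPARATION,
)
from .alignment import align_chains, ca_rmsd
from .network_compare import (
    restrict_common,
    partition_edges,
    partition_hubs,
    retained_edge_weight_changes,
    site_deltas,
)
from .nds import nds_score

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the comparison pipeline, with their defaults."""

    cutoff: float = DEFAULT_CUTOFF
    min_seq_separation: int = DEFAULT_MIN_SEQ_SEPARATION
    hub_threshold: int = DEFAULT_HUB_THRESHOLD
    alignment_mode: str = "sequence"
    laplacian_variant: str = "normalized"
    eds_denominator: str = "per_edge"
    ewcs_squared_mean: bool = True
    probe_radius: float = 1.4
    rsa_threshold: float = 0.10
    sasa_points: int = 960
    max_resolution: float = 3.0
    max_r_diff: float = 0.05
    strict_quality: bool = False
    compute_sasa: bool = False
    norm_table_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def normalization_table(self) -> NormalizationTable:
        if self.norm_table_path:
            return NormalizationTable.from_tsv(self.norm_table_path)
        from .synthetic_data import default_normalization_table

        return default_normalization_table()


@dataclass
class ComparisonReport:
    """Everything computed for one wildtype/mutant pair, JSON-serializable."""

    wt_id: str
    mut_id: str
    n_common: int
    coverage_wt: float
    coverage_mut: float
    ca_rmsd: float
    nds: float
    eds: float
    crs: float
    ewcs: float
    edges_retained: int
    edges_lost: int
    edges_gained: int
    hubs_retained: int
    hubs_lost: int
    hubs_gained: int
    edge_lists: dict = field(default_factory=dict)
    hub_lists: dict = field(default_factory=dict)
    site_delta_table: pd.DataFrame | None = None
    weight_change_table: pd.DataFrame | None = None
    quality: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "inputs": {"wildtype": self.wt_id, "mutant": self.mut_id},
            "mapping": {
                "n": self.n_common,
                "coverage_wt": self.coverage_wt,
                "coverage_mut": self.coverage_mut,
            },
            "ca_rmsd": self.ca_rmsd,
            "nds": {
                "nds": self.nds, "eds": self.eds, "crs": self.crs, "ewcs": self.ewcs,
            },
            "edges": {
                "retained": self.edges_retained,
                "lost": self.edges_lost,
                "gained": self.edges_gained,
                "lists": self.edge_lists,
            },
            "hubs": {
                "retained": self.hubs_retained,
                "lost": self.hubs_lost,
                "gained": self.hubs_gained,
                "lists": self.hub_lists,
            },
            "quality": self.quality,
            "provenance": self.provenance,
        }
        if self.site_delta_table is not None:
            d["site_deltas"] = json.loads(self.site_delta_table.to_json(orient="records"))
        if self.weight_change_table is not None:
            d["retained_edge_weight_changes"] = json.loads(
                self.weight_change_table.to_json(orient="records")
            )
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compare_chains(
    wt: ChainModel,
    mut: ChainModel,
    norm: NormalizationTable | None = None,
    config: PipelineConfig | None = None,
    sites: dict[str, str] | None = None,
) -> ComparisonReport:
    """Full comparison of two in-memory chains.

    Stages: quality check (warn, or abort under ``strict_quality``) →
    residue mapping → PSN construction → restriction to common nodes →
    edge/hub partitions and per-site deltas → NDS → Cα RMSD.
    """
    config = config or PipelineConfig()
    norm = norm or config.normalization_table()

    quality = {}
    for name, chain in (("wildtype", wt), ("mutant", mut)):
        ok = quality_filter(chain, config.max_resolution, config.max_r_diff)
        quality[name] = {
            "passes_filter": ok,
            "resolution": chain.resolution,
            "r_free": chain.r_free,
            "r_work": chain.r_work,
        }
        if not ok:
            msg = f"{name} chain {chain.pdb_id}:{chain.chain_id} fails the quality filter"
            if config.strict_quality:
                raise ValueError(msg)
            logger.warning(msg)

    mapping = align_chains(wt, mut, mode=config.alignment_mode)
    psn_wt = build_psn(wt, norm, config.cutoff, config.hub_threshold, config.min_seq_separation)
    psn_mut = build_psn(mut, norm, config.cutoff, config.hub_threshold, config.min_seq_separation)
    common_wt, common_mut = restrict_common(psn_wt, psn_mut, mapping)

    edges = partition_edges(common_wt, common_mut)
    hubs = partition_hubs(common_wt, common_mut)
    weight_changes = retained_edge_weight_changes(common_wt, common_mut, edges)

    exposure_wt = exposure_mut = None
    if config.compute_sasa:
        exposure_wt = compute_exposure(
            wt, config.probe_radius, config.rsa_threshold, config.sasa_points
        )
        exposure_mut = compute_exposure(
            mut, config.probe_radius, config.rsa_threshold, config.sasa_points
        )
    deltas = site_deltas(common_wt, common_mut, exposure_wt, exposure_mut, sites)

    nds_res = nds_score(
        common_wt,
        common_mut,
        variant=config.laplacian_variant,
        eds_denominator=config.eds_denominator,
        ewcs_squared_mean=config.ewcs_squared_mean,
    )
    rmsd = ca_rmsd(wt, mut, mapping)

    def edge_names(pairs):
        return sorted(
            f"{common_wt.node_ids[i]}--{common_wt.node_ids[j]}" for i, j in pairs
        )

    def hub_names(nodes):
        return sorted(common_wt.node_ids[i] for i in nodes)

    from . import __version__

    return ComparisonReport(
        wt_id=f"{wt.pdb_id}:{wt.chain_id}",
        mut_id=f"{mut.pdb_id}:{mut.chain_id}",
        n_common=mapping.n,
        coverage_wt=mapping.coverage_wt,
        coverage_mut=mapping.coverage_mut,
        ca_rmsd=rmsd,
        nds=nds_res.nds,
        eds=nds_res.eds,
        crs=nds_res.crs,
        ewcs=nds_res.ewcs,
        edges_retained=edges.n_retained,
        edges_lost=edges.n_lost,
        edges_gained=edges.n_gained,
        hubs_retained=hubs.n_retained,
        hubs_lost=hubs.n_lost,
        hubs_gained=hubs.n_gained,
        edge_lists={
            "retained": edge_names(edges.retained),
            "lost": edge_names(edges.lost),
            "gained": edge_names(edges.gained),
        },
        hub_lists={
            "retained": hub_names(hubs.retained),
            "lost": hub_names(hubs.lost),
            "gained": hub_names(hubs.gained),
        },
        site_delta_table=deltas,
        weight_change_table=weight_changes,
        quality=quality,
        provenance={
            "parameters": config.to_dict(),
            "normalization_table": norm.provenance,
            "software_version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )


def _select_chain(chains: list[ChainModel], chain_id: str | None, path) -> ChainModel:
    if chain_id is None:
        return chains[0]
    for c in chains:
        if c.chain_id == chain_id:
            return c
    raise ValueError(
        f"chain {chain_id!r} not found in {path}; "
        f"available: {[c.chain_id for c in chains]}"
    )


def compare_pair(
    wt_path: str | Path,
    mut_path: str | Path,
    wt_chain: str | None = None,
    mut_chain: str | None = None,
    config: PipelineConfig | None = None,
    sites: dict[str, str] | None = None,
) -> ComparisonReport:
    """Compare two structure files (first chain of each unless ids are given)."""
    config = config or PipelineConfig()
    wt = _select_chain(read_structure(wt_path), wt_chain, wt_path)
    mut = _select_chain(read_structure(mut_path), mut_chain, mut_path)
    return compare_chains(wt, mut, config=config, sites=sites)


def batch_compare(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    keep_going: bool = True,
) -> tuple[list[ComparisonReport], pd.DataFrame]:
    """Run a manifest of pairs; return per-pair reports and a summary table.

    The manifest is a TSV (or DataFrame) with columns
    ``pair_id, wt_path, wt_chain, mut_path, mut_chain`` (chain columns
    optional).  The summary carries one row per successful pair plus
    ``mean``/``sd`` rows over the numeric columns; failures are logged and,
    with ``keep_going``, do not abort the batch.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    if manifest.empty:
        raise ValueError("empty manifest")
    config = config or PipelineConfig()
    norm = config.normalization_table()

    reports: list[ComparisonReport] = []
    rows = []
    for _, row in manifest.iterrows():
        pair_id = row.get("pair_id", f"{row['wt_path']}|{row['mut_path']}")
        try:
            wt = _select_chain(
                read_structure(row["wt_path"]), row.get("wt_chain"), row["wt_path"]
            )
            mut = _select_chain(
                read_structure(row["mut_path"]), row.get("mut_chain"), row["mut_path"]
            )
            rep = compare_chains(wt, mut, norm=norm, config=config)
        except Exception as exc:
            logger.error("pair %s failed: %s", pair_id, exc)
            if not keep_going:
                raise
            continue
        reports.append(rep)
        rows.append(
            {
                "pair_id": pair_id, "n": rep.n_common, "rmsd": rep.ca_rmsd,
                "nds": rep.nds, "eds": rep.eds, "crs": rep.crs, "ewcs": rep.ewcs,
                "edges_lost": rep.edges_lost, "edges_gained": rep.edges_gained,
                "hubs_lost": rep.hubs_lost, "hubs_gained": rep.hubs_gained,
            }
        )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        numeric = summary.select_dtypes(include=[np.number]).columns
        stats = pd.DataFrame(
            [
                {"pair_id": "mean", **summary[numeric].mean().to_dict()},
                {"pair_id": "sd", **summary[numeric].std(ddof=1).to_dict()},
            ]
        )
        summary = pd.concat([summary, stats], ignore_index=True)
    return reports, summary
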