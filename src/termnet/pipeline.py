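"""End-to-end orchestration of the analysis stages with provenance.

Stage order mirrors the analysis flow: network ingest and confidence table →
transport/usage profiles → similarity/co-occurrence correlation → segment
partition → influence matrix → influence network → centrality report →
segment byproduct profiles → robustness resampling → degradation network.
Every run writes a provenance record (config, seed, package versions) next to
its outputs, and each stage's output is a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .cooccurrence import (
    cooccurrence_score,
    group_correlation,
    metabolic_similarity,
    write_matrix,
)
from .degradation import (
    build_degradation_network,
    degradation_network_to_graphml,
    degradation_network_to_sif,
    load_enzyme_table,
    select_degraders,
)
from .errors import DomainError
from .influence import (
    InfluenceModel,
    build_influence_network,
    influence_matrix,
    influence_network_to_graphml,
    influence_network_to_sif,
)
from .network_analysis import (
    RemovalMode,
    centrality_report,
    robustness_sample,
    segment_byproduct_profile,
)
from .network_model import load_network, metabolite_usage, transport_profile
from .segmentation import AbundanceTable, partition_segments

log = logging.getLogger("termnet.pipeline")


@dataclass
class PipelineConfig:
    """Paths and knobs for a full pipeline run (YAML-serializable)."""

    activity_table: str
    compound_table: str
    abundance_table: str
    enzyme_table: str | None = None
    groups_table: str | None = None
    output_dir: str = "termnet_out"
    alpha: float = 0.05
    min_abundance: float = 0.02
    influence_normalization: str = "per_import_set"
    influence_abundance_mode: str = "segment"
    top_k_per_segment: int | None = None
    abundance_cutoff: float | None = None
    magnitude_threshold: float = 0.0
    centrality_cutoff: float | str = "auto"
    centrality_directed: bool = True
    removal_fraction: float = 0.25
    removal_mode: str = "species_and_metabolites"
    robustness_seeds: tuple[int, ...] = (0, 1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        if "robustness_seeds" in raw:
            raw["robustness_seeds"] = tuple(raw["robustness_seeds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["robustness_seeds"] = list(self.robustness_seeds)
        return d


def _stage(name: str, t0: float) -> None:
    log.info("stage=%s elapsed=%.2fs", name, time.time() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing TSV/SIF/GraphML/JSON outputs to
    ``config.output_dir``; returns the in-memory result bundle."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    provenance = {
        "config": config.to_dict(),
        "versions": {
            "termnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")

    # 1. network + confidence
    net = load_network(config.activity_table, config.compound_table)
    net.confidence_table().to_csv(out / "confidence.tsv", sep="\t", index=False)
    net.to_sif(out / "crossfeeding.sif")
    net.to_graphml(out / "crossfeeding.graphml")
    summary = {
        "n_species": net.n_species,
        "n_compounds": net.n_compounds,
        "n_metabolites": net.n_metabolites,
        "n_transport_events": net.n_transport_events,
        "n_degradation_events": net.n_degradation_events,
    }
    _stage("network", t0)

    # 2. transport & usage profiles
    profile = transport_profile(net)
    profile.per_species.to_csv(out / "transport_profile.tsv", sep="\t", index_label="species")
    usage = metabolite_usage(net)
    usage.to_csv(out / "metabolite_usage.tsv", sep="\t", index_label="compound")
    summary.update(
        mean_imports=profile.mean_imports,
        mean_exports=profile.mean_exports,
        median_imports=profile.median_imports,
        median_exports=profile.median_exports,
    )
    _stage("profile", t0)

    # 3. similarity / co-occurrence
    ab = AbundanceTable.from_tsv(config.abundance_table, min_abundance=config.min_abundance)
    sim = metabolic_similarity(net)
    cooc = cooccurrence_score(ab)
    write_matrix(sim, out / "metabolic_similarity.tsv")
    write_matrix(cooc, out / "cooccurrence.tsv")
    _stage("cooccurrence", t0)

    # 4. segment partition
    partition = partition_segments(ab, alpha=config.alpha)
    partition.to_frame().to_csv(out / "segment_tests.tsv", sep="\t", index=False)
    pd.Series(partition.assignment, name="segment").to_csv(
        out / "segments.tsv", sep="\t", index_label="compartment"
    )
    _stage("segmentation", t0)

    # 5-6. influence matrix + network
    model = InfluenceModel(
        normalization=config.influence_normalization,
        abundance_mode=config.influence_abundance_mode,
    )
    mat = influence_matrix(
        net, ab, partition, model,
        top_k_per_segment=config.top_k_per_segment,
        min_abundance=config.abundance_cutoff,
    )
    mat.to_tsv(out / "influence_matrix.tsv")
    g = build_influence_network(mat, config.magnitude_threshold)
    influence_network_to_sif(g, out / "influence_network.sif")
    influence_network_to_graphml(g, out / "influence_network.graphml")
    summary["influence_nodes"] = g.number_of_nodes()
    summary["influence_edges"] = g.number_of_edges()
    summary["segment_membership"] = mat.segment_counts()
    _stage("influence", t0)

    # 7. centrality + influencers
    report = centrality_report(
        g, net, cutoff=config.centrality_cutoff, directed=config.centrality_directed
    )
    report.to_tsv(out / "centrality_report.tsv")
    summary["influencer_fraction_pct"] = report.influencer_fraction
    summary["influencer_cutoff"] = report.cutoff
    summary["influencer_class_fractions_pct"] = report.class_fractions
    _stage("centrality", t0)

    # 8. segment byproduct profiles
    profiles = segment_byproduct_profile(g, net)
    for seg, df in profiles.items():
        df.to_csv(out / f"byproducts_{seg}.tsv", sep="\t", index_label="compound")
    _stage("byproducts", t0)

    # 9. robustness
    rob_rows = []
    for rseed in config.robustness_seeds:
        res = robustness_sample(
            net, ab, partition, model,
            top_k_per_segment=config.top_k_per_segment,
            min_abundance=config.abundance_cutoff,
            magnitude_threshold=config.magnitude_threshold,
            cutoff=config.centrality_cutoff,
            removal_fraction=config.removal_fraction,
            mode=RemovalMode(config.removal_mode),
            seed=rseed,
        )
        rob_rows.append(
            {
                "seed": res.seed,
                "removal_fraction": res.removal_fraction,
                "mode": res.mode.value,
                "retention_surviving_pct": res.retention_surviving_pct,
                "retention_all_pct": res.retention_all_pct,
            }
        )
    rob_df = pd.DataFrame(rob_rows)
    rob_df.to_csv(out / "robustness.tsv", sep="\t", index=False)
    (out / "robustness.json").write_text(json.dumps(rob_rows, indent=1) + "\n")
    if rob_rows:
        summary["mean_retention_surviving_pct"] = float(
            rob_df["retention_surviving_pct"].mean()
        )
    _stage("robustness", t0)

    # 10. degradation network
    degradation = None
    if config.enzyme_table:
        enzymes = load_enzyme_table(config.enzyme_table)
        degraders = select_degraders(report, net, substrates=None)
        if degraders and any(r.species in set(degraders) for r in enzymes):
            degradation = build_degradation_network(degraders, enzymes, net)
            degradation_network_to_sif(degradation, out / "degradation_network.sif")
            degradation_network_to_graphml(degradation, out / "degradation_network.graphml")
            summary["degradation_nodes"] = degradation.number_of_nodes()
            summary["n_influential_degraders"] = len(degraders)
        else:
            log.warning("no influential degrader covered by the enzyme table; skipping")
    _stage("degradation", t0)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str) + "\n")
    return {
        "network": net,
        "abundance": ab,
        "summary": summary,
        "partition": partition,
        "influence_matrix": mat,
        "influence_network": g,
        "centrality_report": report,
        "byproduct_profiles": profiles,
        "robustness": rob_rows,
        "degradation_network": degradation,
    }
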