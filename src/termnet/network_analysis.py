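"""Topology of the influence network: centrality, influencers, robustness.

A node's *out-degree* measures its direct metabolic reach.  Community-wide
(indirect) control is measured by betweenness centrality

    C_b(p) = [ sum_{x != p != y} sigma_xy(p) / sigma_xy ] * 2 / ((P - 1)(P - 2))

over shortest paths of the directed, unweighted influence network, where
sigma_xy counts shortest x->y paths, sigma_xy(p) those passing through p, and
P is the node count of the connected component ("attached string") p belongs
to — read as the weakly connected component.  The 2/((P-1)(P-2)) constant is
the undirected-graph normalization applied verbatim to the directed network;
a ``directed`` normalization flag halves the result (1/((P-1)(P-2))) for the
directed pair count.

Species whose C_b exceeds a cutoff (by default the network mean) are the
*influencers*; they are classified by metabolic function into macromolecule
degraders, fermenters (exporting classic fermentation byproducts), both, or
other.  Robustness of the influencer set is assessed by randomly removing a
fraction of species (and optionally metabolites), rerunning the influence and
centrality stages, and measuring how many original influencers retain the
label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._names import normalize_name
from .errors import DomainError
from .influence import (
    InfluenceMatrix,
    InfluenceModel,
    build_influence_network,
    influence_matrix,
)
from .network_model import Activity, CrossFeedingNetwork
from .segmentation import AbundanceTable, SegmentPartition

#: classic fermentation end products (normalized compound names)
DEFAULT_FERMENTATION_PRODUCTS = frozenset(
    {"acetate", "ethanol", "butanol", "lactate", "h2", "co2"}
)


class FunctionalClass(str, enum.Enum):
    DEGRADER = "degrader"
    FERMENTER = "fermenter"
    BOTH = "both"
    OTHER = "other"


# ---------------------------------------------------------------------------------
# betweenness (printed-equation normalization)


def betweenness_centrality(
    g: nx.DiGraph,
    directed: bool = True,
    normalization: str = "printed",
) -> dict[str, float]:
    """Per-node betweenness with per-component normalization.

    Raw pair-dependency sums come from Brandes' algorithm (all shortest paths
    counted); each node's sum is scaled by 2/((P-1)(P-2)) with P the size of
    its weakly connected component (``printed``), or halved under
    ``directed`` normalization.  Components with P < 3 contribute 0.  With
    ``directed=False`` the graph is collapsed to undirected before the path
    computation.
    """
    if normalization not in ("printed", "directed"):
        raise DomainError(f"unknown normalization {normalization!r}")
    if g.number_of_nodes() == 0:
        return {}
    h = g if directed else g.to_undirected(as_view=False)
    raw = nx.betweenness_centrality(h, normalized=False)
    comp_of: dict[str, int] = {}
    sizes: dict[int, int] = {}
    for i, comp in enumerate(nx.weakly_connected_components(g)):
        sizes[i] = len(comp)
        for v in comp:
            comp_of[v] = i
    out: dict[str, float] = {}
    for v in g.nodes:
        p_count = sizes[comp_of[v]]
        if p_count < 3:
            out[v] = 0.0
            continue
        scale = 2.0 / ((p_count - 1) * (p_count - 2))
        if normalization == "directed":
            scale /= 2.0
        out[v] = raw[v] * scale
    return out


# ---------------------------------------------------------------------------------
# influencer identification and classification


def identify_influencers(
    centrality: Mapping[str, float], cutoff: float | str = "auto"
) -> tuple[set[str], float, float]:
    """Nodes strictly above the C_b cutoff.

    ``cutoff="auto"`` uses the mean C_b over all nodes.  Returns the
    influencer set, the influencer fraction in percent, and the cutoff used.
    """
    if not centrality:
        return set(), 0.0, 0.0
    if cutoff == "auto":
        cut = float(np.mean(list(centrality.values())))
    else:
        cut = float(cutoff)
    influencers = {v for v, c in centrality.items() if c > cut}
    fraction = 100.0 * len(influencers) / len(centrality)
    return influencers, fraction, cut


def classify_species(
    species: str,
    net: CrossFeedingNetwork,
    fermentation_products: frozenset[str] = DEFAULT_FERMENTATION_PRODUCTS,
) -> FunctionalClass:
    degrades = bool(net.degraded(species))
    ferments = bool(net.explicit_exports(species) & fermentation_products)
    if degrades and ferments:
        return FunctionalClass.BOTH
    if degrades:
        return FunctionalClass.DEGRADER
    if ferments:
        return FunctionalClass.FERMENTER
    return FunctionalClass.OTHER


def classify_influencers(
    influencers: Iterable[str],
    net: CrossFeedingNetwork,
    fermentation_products: frozenset[str] = DEFAULT_FERMENTATION_PRODUCTS,
) -> tuple[dict[str, FunctionalClass], dict[str, float]]:
    """Functional class per influencer and class fractions in percent.

    DEGRADER: macromolecule degradation only; FERMENTER: exports a
    fermentation byproduct without degrading; BOTH: both capabilities.
    """
    members = [normalize_name(s) for s in influencers]
    unknown = [s for s in members if s not in net.species]
    if unknown:
        raise DomainError(f"influencers not in network: {sorted(unknown)}")
    classes = {s: classify_species(s, net, fermentation_products) for s in members}
    n = len(members)
    fractions = {
        fc.value: (100.0 * sum(1 for c in classes.values() if c is fc) / n) if n else 0.0
        for fc in FunctionalClass
    }
    return classes, fractions


# ---------------------------------------------------------------------------------
# centrality report


@dataclass
class CentralityReport:
    """Per-node topology and function summary of the influence network."""

    table: pd.DataFrame  # index node; out_degree, betweenness, influencer, ...
    cutoff: float
    influencer_fraction: float
    class_fractions: dict[str, float]

    @property
    def influencers(self) -> set[str]:
        return set(self.table.index[self.table["influencer"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="species")


def centrality_report(
    g: nx.DiGraph,
    net: CrossFeedingNetwork,
    cutoff: float | str = "auto",
    directed: bool = True,
    normalization: str = "printed",
    fermentation_products: frozenset[str] = DEFAULT_FERMENTATION_PRODUCTS,
) -> CentralityReport:
    """Out-degree, C_b, influencer flag, functional class and signed influence
    fractions for every node of the influence network.

    ``positive_influence_pct`` of a node is the percentage of the other nodes
    receiving a positive edge from it (likewise negative).
    """
    if g.number_of_nodes() < 3:
        raise DomainError("centrality report requires >= 3 nodes")
    cb = betweenness_centrality(g, directed=directed, normalization=normalization)
    influencers, infl_fraction, cut = identify_influencers(cb, cutoff)
    n = g.number_of_nodes()
    rows = {}
    for v in sorted(g.nodes):
        pos = sum(1 for _, _, d in g.out_edges(v, data=True) if d["sign"] > 0)
        neg = sum(1 for _, _, d in g.out_edges(v, data=True) if d["sign"] < 0)
        fc = (
            classify_species(v, net, fermentation_products)
            if v in net.species
            else FunctionalClass.OTHER
        )
        rows[v] = {
            "out_degree": g.out_degree(v),
            "betweenness": cb[v],
            "influencer": v in influencers,
            "functional_class": fc.value,
            "positive_influence_pct": 100.0 * pos / (n - 1),
            "negative_influence_pct": 100.0 * neg / (n - 1),
            "segment": g.nodes[v].get("segment", ""),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    _, fractions = (
        classify_influencers(influencers, net, fermentation_products)
        if influencers
        else ({}, {fc.value: 0.0 for fc in FunctionalClass})
    )
    return CentralityReport(table, cut, infl_fraction, fractions)


# ---------------------------------------------------------------------------------
# segment byproduct profiles


def segment_byproduct_profile(
    g: nx.DiGraph,
    net: CrossFeedingNetwork,
    top_n: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-segment producer/consumer percentages of each metabolite.

    For every gut segment (taken from node attributes), each metabolite's
    ``producer_pct`` is the percentage of the segment's species that
    effectively export it and ``consumer_pct`` the percentage importing it.
    The returned tables are sorted by producer percentage; the top ``top_n``
    rows are the segment's most commonly exported byproducts.
    """
    segments: dict[str, list[str]] = {}
    for v, d in g.nodes(data=True):
        segments.setdefault(d.get("segment", ""), []).append(v)
    out: dict[str, pd.DataFrame] = {}
    for seg, members in sorted(segments.items()):
        n = len(members)
        exports = {s: net.effective_exports(s) for s in members}
        imports = {s: net.imports(s) for s in members}
        touched = set().union(*exports.values(), *imports.values()) if members else set()
        rows = {}
        for m in sorted(touched):
            rows[m] = {
                "producer_pct": 100.0 * sum(1 for s in members if m in exports[s]) / n,
                "consumer_pct": 100.0 * sum(1 for s in members if m in imports[s]) / n,
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        if not df.empty:
            df = df.sort_values("producer_pct", ascending=False, kind="stable")
        df.attrs["top_exported"] = list(df.index[:top_n])
        out[seg] = df
    return out


# ---------------------------------------------------------------------------------
# robustness resampling


class RemovalMode(str, enum.Enum):
    SPECIES_AND_METABOLITES = "species_and_metabolites"
    SPECIES_ONLY = "species_only"


@dataclass
class RobustnessResult:
    """Influencer retention after random removal of input data.

    ``retention_surviving_pct`` uses as denominator the original influencers
    that survived removal (the headline statistic); ``retention_all_pct``
    divides by all original influencers.
    """

    seed: int
    removal_fraction: float
    mode: RemovalMode
    original_influencers: set[str]
    reduced_influencers: set[str]
    retention_surviving_pct: float
    retention_all_pct: float


def _run_influencer_stage(
    net: CrossFeedingNetwork,
    ab: AbundanceTable,
    partition: SegmentPartition,
    model: InfluenceModel,
    top_k_per_segment: int | None,
    min_abundance: float | None,
    magnitude_threshold: float,
    cutoff: float | str,
) -> set[str]:
    mat = influence_matrix(
        net, ab, partition, model,
        top_k_per_segment=top_k_per_segment, min_abundance=min_abundance,
    )
    g = build_influence_network(mat, magnitude_threshold)
    cb = betweenness_centrality(g)
    influencers, _, _ = identify_influencers(cb, cutoff)
    return influencers


def robustness_sample(
    net: CrossFeedingNetwork,
    ab: AbundanceTable,
    partition: SegmentPartition,
    model: InfluenceModel | None = None,
    top_k_per_segment: int | None = None,
    min_abundance: float | None = None,
    magnitude_threshold: float = 0.0,
    cutoff: float | str = "auto",
    removal_fraction: float = 0.25,
    mode: RemovalMode | str = RemovalMode.SPECIES_AND_METABOLITES,
    seed: int = 0,
) -> RobustnessResult:
    """Remove a random fraction of the input data and re-identify influencers.

    The stated fraction of species (and, under SPECIES_AND_METABOLITES, of
    small metabolites) is removed uniformly at random with the given seed; the
    influence matrix, network, centrality and influencer stages are rerun on
    the reduced data, and retention of the original influencer set is
    reported as a percentage.  Deterministic for a fixed seed.
    """
    if not 0 <= removal_fraction < 1:
        raise DomainError("removal_fraction must be in [0, 1)")
    mode = RemovalMode(mode)
    model = model or InfluenceModel()

    original = _run_influencer_stage(
        net, ab, partition, model, top_k_per_segment, min_abundance,
        magnitude_threshold, cutoff,
    )

    rng = np.random.default_rng(seed)
    species = sorted(net.species)
    n_drop = int(np.floor(removal_fraction * len(species)))
    if len(species) - n_drop < 3:
        raise DomainError("removal would leave fewer than 3 species")
    dropped_sp = set(rng.choice(species, size=n_drop, replace=False)) if n_drop else set()
    keep_species = [s for s in species if s not in dropped_sp]

    keep_compounds = None
    if mode is RemovalMode.SPECIES_AND_METABOLITES:
        from .network_model import CompoundClass

        mets = sorted(
            k for k, c in net.compounds.items()
            if c.klass is CompoundClass.SMALL_METABOLITE
        )
        m_drop = int(np.floor(removal_fraction * len(mets)))
        dropped_m = set(rng.choice(mets, size=m_drop, replace=False)) if m_drop else set()
        keep_compounds = [k for k in net.compounds if k not in dropped_m]

    reduced_net = net.subset(keep_species=keep_species, keep_compounds=keep_compounds)
    reduced_ab = ab.subset_species([s for s in ab.species if s not in dropped_sp])

    reduced = _run_influencer_stage(
        reduced_net, reduced_ab, partition, model, top_k_per_segment, min_abundance,
        magnitude_threshold, cutoff,
    )

    surviving = original - dropped_sp
    kept = original & reduced
    retention_surv = 100.0 * len(kept) / len(surviving) if surviving else 100.0
    retention_all = 100.0 * len(kept) / len(original) if original else 100.0
    return RobustnessResult(
        seed=seed,
        removal_fraction=removal_fraction,
        mode=mode,
        original_influencers=original,
        reduced_influencers=reduced,
        retention_surviving_pct=retention_surv,
        retention_all_pct=retention_all,
    )
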