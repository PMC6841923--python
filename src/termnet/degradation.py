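"""Lignocellulose degradation network: degraders, GH enzymes, sugars, fermenters.

The most influential macromolecule degraders secrete extracellular glycoside
hydrolases (endoglucanases, cellobiohydrolases, endo-1,4-β-xylanases,
β-glucosidases, β-xylosidases, ...) that hydrolyze cellulose, hemicellulose,
pectin and starch into simple sugars; fermentative species take the sugars up
and excrete byproducts (acetate, H2, CO2, ...).  The assembled network is a
typed, layered digraph

    degrader --secretes--> enzyme --hydrolyzes--> macromolecule
        --yields--> sugar --consumed_by--> fermenter --excretes--> byproduct

projected from the cross-feeding network plus a curated enzyme table
(CAZy/dbCAN2-derived).  dbCAN2 Hotpep rows are subjected to the provenance
filters frequency > 2.6 and hits > 6 at load time.  Edges carry confidence:
the evidence score of the underlying metabolic activity where one exists,
else 50 (mid-scale) for enzyme-derived links.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._names import normalize_name
from .errors import DomainError, ParseError
from .network_analysis import (
    CentralityReport,
    DEFAULT_FERMENTATION_PRODUCTS,
    FunctionalClass,
)
from .network_model import CrossFeedingNetwork

HOTPEP_MIN_FREQUENCY = 2.6
HOTPEP_MIN_HITS = 6

#: macromolecule classes that count as lignocellulosic substrates
LIGNOCELLULOSE_SUBSTRATES = frozenset(
    {"cellulose", "hemicellulose", "pectin", "starch", "xylan", "lignin"}
)


class EnzymeSource(str, enum.Enum):
    CAZY = "cazy"
    DBCAN2_HOTPEP = "dbcan2_hotpep"
    CURATED = "curated"


@dataclass(frozen=True)
class EnzymeAnnotation:
    """One species -> extracellular GH enzyme record with its substrate."""

    species: str
    enzyme: str
    gh_family: str
    substrate: str
    source: EnzymeSource = EnzymeSource.CURATED
    hotpep_frequency: float | None = None
    hotpep_hits: int | None = None

    def passes_filters(self) -> bool:
        if self.source is not EnzymeSource.DBCAN2_HOTPEP:
            return True
        return (
            self.hotpep_frequency is not None
            and self.hotpep_hits is not None
            and self.hotpep_frequency > HOTPEP_MIN_FREQUENCY
            and self.hotpep_hits > HOTPEP_MIN_HITS
        )


def filter_enzyme_table(rows: Iterable[EnzymeAnnotation]) -> list[EnzymeAnnotation]:
    """Keep rows passing the Hotpep provenance thresholds (idempotent)."""
    return [r for r in rows if r.passes_filters()]


def load_enzyme_table(path: str | Path) -> list[EnzymeAnnotation]:
    """Read the enzyme TSV: columns
    ``species, enzyme, ghfamily, substrate, source[, frequency, hits]``;
    Hotpep rows failing the frequency/hits filters are dropped."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"species", "enzyme", "ghfamily", "substrate", "source"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"enzyme table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    rows = []
    for i, row in df.iterrows():
        try:
            source = EnzymeSource(str(row["source"]).strip().lower())
        except ValueError:
            raise ParseError(
                f"row {i + 2} of {path}: unknown enzyme source {row['source']!r}"
            ) from None
        freq = (
            float(row["frequency"])
            if "frequency" in df.columns and pd.notna(row.get("frequency"))
            else None
        )
        hits = (
            int(float(row["hits"]))
            if "hits" in df.columns and pd.notna(row.get("hits"))
            else None
        )
        rows.append(
            EnzymeAnnotation(
                normalize_name(row["species"]),
                str(row["enzyme"]).strip(),
                str(row["ghfamily"]).strip(),
                normalize_name(row["substrate"]),
                source,
                freq,
                hits,
            )
        )
    return filter_enzyme_table(rows)


def write_enzyme_table(rows: Sequence[EnzymeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species": r.species,
                "enzyme": r.enzyme,
                "ghfamily": r.gh_family,
                "substrate": r.substrate,
                "source": r.source.value,
                "frequency": r.hotpep_frequency,
                "hits": r.hotpep_hits,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------------


def select_degraders(
    report: CentralityReport,
    net: CrossFeedingNetwork,
    substrates: frozenset[str] | None = LIGNOCELLULOSE_SUBSTRATES,
) -> list[str]:
    """Influencers degrading a lignocellulosic macromolecule, ranked by C_b.

    ``substrates=None`` accepts any degraded macromolecule.
    """
    degraders = []
    for s in report.influencers:
        degraded = net.degraded(s)
        if not degraded:
            continue
        if substrates is not None and not (degraded & substrates):
            continue
        degraders.append(s)
    return sorted(
        degraders, key=lambda s: (-report.table.loc[s, "betweenness"], s)
    )


def build_degradation_network(
    degraders: Sequence[str],
    enzymes: Sequence[EnzymeAnnotation],
    net: CrossFeedingNetwork,
    fermenters: Iterable[str] | None = None,
    fermentation_products: frozenset[str] = DEFAULT_FERMENTATION_PRODUCTS,
) -> nx.DiGraph:
    """Assemble the typed degrader→enzyme→macromolecule→sugar→fermenter graph.

    ``fermenters`` defaults to every network species exporting a fermentation
    byproduct (degraders excluded).  Degraders absent from the enzyme table
    keep their node, with a warning, but contribute no secretes/hydrolyzes
    edges; consumes/excretes edges are projected from import/export
    activities of the cross-feeding network, so referential integrity with it
    is guaranteed by construction.
    """
    if not degraders:
        raise DomainError("build_degradation_network requires >= 1 degrader")
    degraders = [normalize_name(d) for d in degraders]
    enz_by_species: dict[str, list[EnzymeAnnotation]] = {}
    for r in filter_enzyme_table(enzymes):
        enz_by_species.setdefault(r.species, []).append(r)
    if not any(d in enz_by_species for d in degraders):
        raise DomainError("enzyme table covers none of the given degraders")

    if fermenters is None:
        fermenters = sorted(
            s
            for s in net.species
            if net.explicit_exports(s) & fermentation_products and s not in degraders
        )
    else:
        fermenters = sorted(normalize_name(f) for f in fermenters)

    g = nx.DiGraph()
    mid_confidence = 50.0  # enzyme-derived edges have no curated activity behind them

    def conf(species: str, compound: str) -> float:
        c = net.activity_confidence(species, compound)
        return mid_confidence if c is None else c

    released: set[str] = set()
    for d in degraders:
        g.add_node(d, type="degrader")
        rows = enz_by_species.get(d)
        if rows is None:
            warnings.warn(f"degrader {d!r} absent from enzyme table; node kept bare")
            rows = []
        for r in rows:
            enz = r.enzyme
            g.add_node(enz, type="enzyme", gh_family=r.gh_family)
            g.add_edge(d, enz, type="secretes", confidence=mid_confidence)
            sub = r.substrate
            comp = net.compounds.get(sub)
            g.add_node(sub, type="macromolecule")
            g.add_edge(enz, sub, type="hydrolyzes", confidence=mid_confidence)
            if comp is not None:
                for prod in sorted(comp.degradation_products):
                    pkey = normalize_name(prod)
                    g.add_node(pkey, type="small_metabolite")
                    g.add_edge(sub, pkey, type="yields", confidence=conf(d, sub))
                    released.add(pkey)

    for f in fermenters:
        eaten = net.imports(f) & released
        if not eaten:
            continue
        g.add_node(f, type="fermenter")
        for m in sorted(eaten):
            g.add_edge(m, f, type="consumed_by", confidence=conf(f, m))
        for b in sorted(net.explicit_exports(f) & fermentation_products):
            g.add_node(b, type="small_metabolite")
            g.add_edge(f, b, type="excretes", confidence=conf(f, b))
    return g


def degradation_network_to_sif(g: nx.DiGraph, path: str | Path) -> None:
    lines = sorted(f"{u}\t{d['type']}\t{v}" for u, v, d in g.edges(data=True))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def degradation_network_to_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
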