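"""Pairwise inter-species metabolic influence scores and the influence network.

The influence of species p on species q is an elasticity-style quantity: the
relative change of q's growth induced by a relative change in p's abundance,
summed over the metabolites q consumes.  Exact partial derivatives are not
recoverable from presence/absence data, so the score is discretized as

    I_pq = (n_p / mu_q) * sum_{m in Imp(q)} w_m * s_m(p, q)

with n_p, mu_q the relative abundances of p and q, w_m = 1/|Imp(q)| (each of
q's imports matters equally), and a sign rule per metabolite m imported by q:

    s_m = +1  if p effectively exports m             (cross-feeding: p feeds q)
    s_m = -1  if p imports m and cannot supply it    (competition for m)
    s_m =  0  otherwise

A species that both consumes and supplies m counts as a provider (+1):
degrader-fermenters are net sources of their degradation products.  Pure
cross-feeding between equally abundant species scores exactly +1, pure
competition exactly -1, metabolically disjoint pairs exactly 0.  The score is
directional and generally asymmetric (I_pq != I_qp).

Thresholding |I_pq| yields the signed, directed influence network whose nodes
are the most abundant species of each gut segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._names import normalize_name
from .errors import DomainError
from .network_model import CrossFeedingNetwork
from .segmentation import AbundanceTable, SegmentPartition


@dataclass
class InfluenceModel:
    """Tunable pieces of the influence-score discretization.

    ``metabolite_weights`` overrides the per-metabolite sensitivity (default
    uniform); ``normalization`` divides the sum by |Imp(q)| (default) or not
    at all; ``abundance_mode`` picks segment-local or global abundances for
    n_p and mu_q; ``confidence_weighting`` multiplies each term by the edge
    confidence / 100.
    """

    metabolite_weights: Mapping[str, float] | None = None
    normalization: str = "per_import_set"  # or "none"
    abundance_mode: str = "segment"  # or "global"
    confidence_weighting: bool = False

    def __post_init__(self) -> None:
        if self.normalization not in ("per_import_set", "none"):
            raise DomainError(f"unknown normalization {self.normalization!r}")
        if self.abundance_mode not in ("segment", "global"):
            raise DomainError(f"unknown abundance_mode {self.abundance_mode!r}")
        if self.metabolite_weights is not None:
            bad = {m: w for m, w in self.metabolite_weights.items() if w < 0}
            if bad:
                raise DomainError(f"negative metabolite weights: {bad}")


def _signed_sum(
    p: str, q: str, net: CrossFeedingNetwork, model: InfluenceModel
) -> float:
    imports_q = net.imports(q)
    if not imports_q:
        return 0.0
    eff_p = net.effective_exports(p)
    imp_p = net.imports(p)
    weights = model.metabolite_weights or {}
    total = 0.0
    for m in imports_q:
        if m in eff_p:
            s = 1.0
        elif m in imp_p:
            s = -1.0
        else:
            continue
        w = float(weights.get(m, 1.0))
        if model.confidence_weighting:
            c = net.activity_confidence(q, m)
            w *= (c / 100.0) if c is not None else 0.5
        total += w * s
    if model.normalization == "per_import_set":
        total /= len(imports_q)
    return total


def influence_score(
    p: str,
    q: str,
    net: CrossFeedingNetwork,
    ab: AbundanceTable | None = None,
    model: InfluenceModel | None = None,
    n_p: float | None = None,
    mu_q: float | None = None,
) -> float:
    """Net metabolic influence of species p on species q.

    Abundances are taken from ``ab`` (overall aggregate) unless ``n_p`` and
    ``mu_q`` are passed explicitly (as segment-local abundances, say).  A q
    with an empty import set scores 0 with a warning; a missing abundance is a
    domain error.
    """
    model = model or InfluenceModel()
    pk, qk = normalize_name(p), normalize_name(q)
    if pk == qk:
        raise DomainError("influence_score requires two distinct species")
    for s in (pk, qk):
        if s not in net.species:
            raise DomainError(f"species {s!r} not in the cross-feeding network")
    if not net.imports(qk):
        warnings.warn(f"species {qk!r} imports nothing; influence on it is 0")
        return 0.0
    if n_p is None or mu_q is None:
        if ab is None:
            raise DomainError("provide an abundance table or explicit n_p/mu_q")
        agg = ab.aggregate("mean")
        try:
            n_p = float(agg.loc[pk]) if n_p is None else n_p
            mu_q = float(agg.loc[qk]) if mu_q is None else mu_q
        except KeyError as exc:
            raise DomainError(f"species missing from abundance table: {exc}") from exc
    if mu_q <= 0:
        return 0.0  # degenerate pair: q effectively absent
    return (n_p / mu_q) * _signed_sum(pk, qk, net, model)


@dataclass
class InfluenceMatrix:
    """Dense ordered-pair influence scores over the selected abundant species.

    ``segments`` maps each selected species to the gut segment where it is
    most abundant; the diagonal of ``values`` is NaN (self-influence is
    undefined).
    """

    values: pd.DataFrame
    segments: dict[str, str]

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def segment_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for seg in self.segments.values():
            out[seg] = out.get(seg, 0) + 1
        return dict(sorted(out.items()))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="species")


def _select_abundant(
    ab: AbundanceTable,
    partition: SegmentPartition,
    candidates: set[str],
    top_k_per_segment: int | None,
    min_abundance: float | None,
) -> dict[str, str]:
    """Pick the most abundant species per segment; a species picked in several
    segments is assigned to the one where its within-segment abundance share
    is highest (invariant to segment-level scale differences)."""
    chosen: dict[str, tuple[str, float]] = {}
    for seg, comps in sorted(partition.segments.items()):
        seg_ab = ab.segment_abundance(comps)
        total = float(seg_ab.sum())
        share = seg_ab / total if total > 0 else seg_ab
        seg_ab = seg_ab[[s for s in seg_ab.index if s in candidates]]
        if min_abundance is not None:
            seg_ab = seg_ab[seg_ab >= min_abundance]
        seg_ab = seg_ab.sort_values(ascending=False, kind="stable")
        if top_k_per_segment is not None:
            if top_k_per_segment > len(seg_ab):
                warnings.warn(
                    f"segment {seg}: requested top {top_k_per_segment} species "
                    f"but only {len(seg_ab)} available; truncating"
                )
            seg_ab = seg_ab.iloc[:top_k_per_segment]
        for s in seg_ab.index:
            v = float(share.loc[s])
            if s not in chosen or v > chosen[s][1]:
                chosen[s] = (seg, v)
    return {s: seg for s, (seg, _) in sorted(chosen.items())}


def influence_matrix(
    net: CrossFeedingNetwork,
    ab: AbundanceTable,
    partition: SegmentPartition,
    model: InfluenceModel | None = None,
    top_k_per_segment: int | None = None,
    min_abundance: float | None = None,
) -> InfluenceMatrix:
    """All ordered-pair influence scores among the abundant species.

    Selection per segment is by mean abundance over the segment's
    compartments, keeping the top k and/or those above ``min_abundance``.
    Same-segment pairs use segment-local abundances (under the model's
    ``segment`` mode); cross-segment pairs fall back to global mean
    abundances.
    """
    missing = [c for c in ab.compartments if c not in partition.assignment]
    if missing:
        raise DomainError(f"partition does not cover compartments {missing}")
    model = model or InfluenceModel()
    candidates = net.species & set(ab.species)
    assignment = _select_abundant(ab, partition, candidates, top_k_per_segment, min_abundance)
    species = list(assignment)
    n = len(species)

    seg_ab = {
        seg: ab.segment_abundance(comps)
        for seg, comps in partition.segments.items()
    }
    global_ab = ab.aggregate("mean")

    def abund(s: str, seg: str, use_segment: bool) -> float:
        if use_segment and model.abundance_mode == "segment":
            return float(seg_ab[seg].loc[s])
        return float(global_ab.loc[s])

    values = np.full((n, n), np.nan)
    for i, p in enumerate(species):
        for j, q in enumerate(species):
            if i == j:
                continue
            same = assignment[p] == assignment[q]
            n_p = abund(p, assignment[p], same)
            mu_q = abund(q, assignment[q], same)
            if mu_q <= 0:
                values[i, j] = 0.0
                continue
            values[i, j] = (n_p / mu_q) * _signed_sum(p, q, net, model)
    df = pd.DataFrame(values, index=species, columns=species)
    return InfluenceMatrix(df, assignment)


def build_influence_network(
    mat: InfluenceMatrix, magnitude_threshold: float = 0.0
) -> nx.DiGraph:
    """Signed directed graph keeping edges with |I_pq| > threshold.

    Isolated nodes are retained with their segment label; edges carry
    ``weight`` (I_pq), ``sign`` (+1/-1) and ``interaction`` ("pos"/"neg").
    """
    if magnitude_threshold < 0:
        raise DomainError("magnitude_threshold must be >= 0")
    g = nx.DiGraph()
    for s in mat.species:
        g.add_node(s, segment=mat.segments[s])
    vals = mat.values
    for p in mat.species:
        for q in mat.species:
            if p == q:
                continue
            v = float(vals.loc[p, q])
            if np.isnan(v) or abs(v) <= magnitude_threshold or v == 0.0:
                continue
            sign = 1 if v > 0 else -1
            g.add_edge(p, q, weight=v, sign=sign, interaction="pos" if sign > 0 else "neg")
    return g


def influence_network_to_sif(g: nx.DiGraph, path: str | Path) -> None:
    lines = sorted(
        f"{p}\t{d['interaction']}\t{q}" for p, q, d in g.edges(data=True)
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def influence_network_to_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
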