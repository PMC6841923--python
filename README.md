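# termnet

Species-wide metabolic cross-feeding and inter-species influence analysis for
compartmentalized gut microbiota, modeled on the lignocellulose-digesting gut
community of wood-feeding higher termites.

## Who this is for

Microbial ecologists and systems biologists who have, for a host-associated
community:

* a **curated metabolic-activity table** — which species imports, exports or
  extracellularly degrades which compound, with literature counts and a KEGG
  corroboration flag per row;
* a **species × gut-compartment relative-abundance table** (e.g. derived from
  shotgun metagenomes of crop, midgut and hindgut sections);
* a **species → glycoside-hydrolase (GH) enzyme table** (CAZy/dbCAN2-derived)
  for the macromolecule degraders;

and who want to turn presence/absence metabolic knowledge plus abundances into
a quantitative picture of who feeds whom, who competes with whom, which
species hold the community together, and how lignocellulose is taken apart.

## The model

**Cross-feeding network.** A bipartite graph links species to compounds by
import / export / both / degrades edges. Degradation products of every
macromolecule a species depolymerizes count toward its *effective export set*
(breakdown products enter the shared pool). Each edge carries a confidence
score in [0, 100]:

```
confidence = (n / N) · 70 + K · 30
```

with `n` the supporting publications, `N` the maximum publication count over
all edges, and `K` a 0/1 KEGG flag.

**Segments.** Adjacent gut compartments whose abundance distributions are
indistinguishable under the Kruskal–Wallis rank test,

```
H = 12 / (N(N+1)) · Σᵢ Rᵢ²/nᵢ − 3(N+1) ,
```

are merged left-to-right along the gut axis into segments S1, S2, … (p > α
reads as "same distribution"; α = 0.05).

**Influence scores.** The influence of species *p* on species *q* is an
elasticity-style quantity discretized from presence/absence data:

```
I_pq = (n_p / μ_q) · Σ_{m ∈ Imp(q)} w_m · s_m(p, q),    w_m = 1/|Imp(q)|
```

with `n_p`, `μ_q` relative abundances and `s_m = +1` if *p* effectively
exports *m* (cross-feeding), `−1` if *p* imports *m* without supplying it
(competition), else 0. Pure cross-feeding between equally abundant species
scores exactly +1, pure competition −1, metabolically disjoint pairs 0.
Thresholding |I_pq| over the most abundant species per segment yields the
signed, directed **influence network**.

**Influencers.** Community-wide control is measured by betweenness centrality
over shortest paths,

```
C_b(p) = [ Σ_{x≠p≠y} σ_xy(p)/σ_xy ] · 2 / ((P−1)(P−2)) ,
```

with `P` the node count of *p*'s connected component. Nodes above a cutoff
(default: the network mean) are the influencers; they are classified as
macromolecule degraders, fermenters, both, or other, and their stability is
probed by rerunning the whole pipeline after randomly removing 25 % of
species and metabolites.

**Degradation network.** The influential degraders, their extracellular GH
enzymes (endoglucanases, β-xylosidases, cellobiohydrolases, …), the
macromolecules hydrolyzed, the sugars released, and the fermenters consuming
them are assembled into a typed, layered digraph with confidence-weighted
edges.

A fully seeded synthetic-community generator plants cross-feeder, competitor,
degrader-hub and specialist guilds over disjoint metabolite pools, together
with segment-structured abundances, so every stage is testable against known
ground truth without external data.

## Worked example

Generate a 30-species synthetic community and run every stage:

```
termnet simulate --seed 42 --out demo --config spec.yaml   # n_species: 30 ...
termnet run-all pipeline.yaml
```

with `pipeline.yaml` pointing at the three generated tables. The run prints:

```json
{
 "n_species": 30,
 "n_compounds": 110,
 "n_transport_events": 131,
 "n_degradation_events": 8,
 "mean_imports": 3.3,
 "mean_exports": 1.9,
 "influence_nodes": 30,
 "influence_edges": 335,
 "segment_membership": {"S1": 11, "S2": 7, "S3": 12},
 "influencer_fraction_pct": 30.0,
 "influencer_class_fractions_pct": {"degrader": 44.4, "fermenter": 22.2,
                                    "both": 0.0, "other": 33.3},
 "mean_retention_surviving_pct": 66.7,
 "degradation_nodes": 44,
 "n_influential_degraders": 4
}
```

Reading it: the six compartments collapsed into three segments (the planted
3/2/1 plan); all 30 species entered the influence network, whose 335 signed
edges yield 9 influencers (30 % of nodes, C_b above the network mean), mostly
macromolecule degraders; two-thirds of surviving influencers keep their
status under 25 % data removal; and the 4 influential degraders anchor a
44-node degrader→enzyme→macromolecule→sugar→fermenter degradation network.
Alongside the printed summary the run writes, per stage: the confidence
table, transport and usage profiles, similarity/co-occurrence matrices, the
segment test trail, the I_pq matrix, SIF/GraphML graph exports (Cytoscape-
ready), the centrality report, per-segment byproduct profiles, robustness
records, and a provenance JSON.

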