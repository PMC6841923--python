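# Methods

## Scope and data model

The package analyzes a host-associated microbial community described by three
tables: curated per-species metabolic activities (import / export / both /
degrades, with per-row literature counts and a KEGG flag), relative abundances
across gut compartments, and GH-enzyme annotations for degraders. Raw-read
processing (taxonomic classification, CAZy domain calling) is upstream and out
of scope; the tables are the interface.

Compound and species names are normalized case-insensitively with whitespace
collapsed; stereo prefixes (`D-`/`L-`) are preserved. Strain-level rows
sharing a species name merge into one species with the union of activities;
byte-identical repeats collapse silently, while identical
(species, compound, activity) triples with *different* evidence raise a
validation error rather than guessing which count is right.

The one modeling rule with real teeth is the **degradation-product rule**:
the breakdown products of every macromolecule a species degrades are added to
that species' effective export set. This is what gives degraders their large
positive influence and is applied consistently in transport profiling,
usage fractions, influence scoring and the degradation network.

## Confidence score

`confidence = (n/N)·70 + K·30`, with `N` the global maximum publication count
over the whole table (not per compound — the definition refers to the single
best-annotated edge). The score is monotone in both inputs and bounded in
[0, 100]. When an edge-confidence weighting of the influence score is enabled
(off by default), each metabolite term is multiplied by `confidence/100`.

## Compartment segmentation

The Kruskal–Wallis statistic is computed in its plain rank-sum form on
mid-ranks; this is the default because it is the form whose printed values the
segment classification was built on, and a tie-corrected variant (divide by
`1 − Σ(t³−t)/(N³−N)`) is available behind a flag. The p-value uses the
chi-square approximation with k−1 degrees of freedom. A published p-value for
the two-compartment hindgut test (0.1748 for H = 1.748, df = 1) equals H/10
and disagrees with the chi-square tail (0.186); we compute the proper tail.

Partitioning is a greedy left-to-right merge along the anatomical compartment
order: the current segment plus the next compartment is tested jointly, and
`p > α` ("no detectable distributional difference") merges the block. Every
decision is recorded with its H and p. Observations entering a test are the
per-species abundances of species at or above the inclusion threshold
(default 0.02 %) in at least one compartment of the candidate block, zeros
retained. No compartment's separateness is hard-coded; the terminal
compartment earns its own segment by the same rule. No multiple-testing
correction is applied — the procedure is deliberately the printed one.

## Metabolic similarity and co-occurrence

Similarity defaults to Jaccard overlap of import sets (competition is about
shared inputs); a flag includes effective exports. Co-occurrence defaults to
Spearman correlation of the two species' abundance vectors across the (six)
compartments — with so few samples only ranks are defensible — with a
presence/absence Jaccard alternative. Zero-variance species have undefined
rank correlations: they are flagged, set to NaN and excluded from downstream
correlations. The guild-level statistic collects all unordered cross-guild
pairs (shared members excluded — guilds are treated as disjoint), and
correlates pair similarity with pair co-occurrence; the two-sided p-value
uses the large-sample t approximation at ≥ 30 pairs and a seeded 10⁴-resample
permutation test below that.

## Influence discretization

The elasticity definition of influence involves partial derivatives of
growth with respect to abundances, which presence/absence data cannot supply.
The operational model is a signed, abundance-scaled, import-normalized sum
(README, "The model"), chosen to satisfy the qualitative contract: pure
cross-feeding positive (+1 at equal abundances), pure competition negative
(−1), disjoint metabolisms zero, magnitude growing with the supplier's
abundance and shrinking with the receiver's. Two deliberate resolutions:

* a species that both consumes and supplies a metabolite counts as a
  *provider* (+1) for importers of that metabolite — degrader-fermenters are
  net sources of their own breakdown products;
* the competition term counts only metabolites the influencer imports but
  cannot itself supply.

The discretization is linear (not scale-free) in `n_p`; doubling the
supplier's abundance doubles the score. The model object is pluggable
(per-metabolite weights, normalization off, global vs segment abundances,
confidence weighting) so alternative operationalizations can be swapped in
without touching downstream stages.

Node selection takes the top-k most abundant species per segment (and/or an
abundance floor); a species abundant in several segments is assigned to the
segment where its within-segment abundance *share* is highest, which is
invariant to segment-level scale differences. Same-segment pairs use
segment-mean abundances; cross-segment pairs fall back to global means, since
the influence network draws edges across segments. Edges are kept when
|I_pq| exceeds a magnitude threshold (strict); isolated nodes keep their
segment label.

## Centrality, influencers, robustness

Betweenness uses Brandes' algorithm on the directed, unweighted graph (all
shortest paths counted; unreachable pairs contribute 0), then normalizes each
node's raw dependency sum by `2/((P−1)(P−2))` with `P` the size of the node's
weakly connected component — the undirected-graph constant applied verbatim
to a directed network, because that is the printed convention the 0.0074-scale
cutoff lives on. A `directed` normalization flag halves it; an undirected
mode collapses the graph first. Components with fewer than three nodes score
zero. Production values are checked exactly against an exhaustive
simple-path-enumeration oracle on small digraphs.

The influencer cutoff defaults to the mean C_b over all nodes (strictly
above). Functional classes: DEGRADER (degrades, no fermentation exports),
FERMENTER (explicitly exports any of acetate, ethanol, butanol, lactate, H2,
CO2 — configurable; degradation products do not count, otherwise every sugar
releaser would ferment), BOTH, OTHER. A node's positive/negative influence
fraction is the share of the other nodes receiving a positive/negative edge
from it.

Robustness removes ⌊f·n⌋ species (and, in the default mode, the same fraction
of small metabolites) uniformly at random under one seed, reruns influence →
network → centrality → influencers, and reports retention two ways, because
the denominator is genuinely ambiguous: among original influencers that
survived removal (headline number) and among all original influencers. The
whole path is bit-reproducible per seed; `f = 0` is accepted as the identity
limit and returns 100 %.

## Degradation network

Influencers with degradation activity on lignocellulosic macromolecules
(cellulose, hemicellulose, pectin, starch, xylan, lignin by default;
configurable, or any macromolecule) are ranked by C_b and joined with the
enzyme table into the layered digraph
degrader→enzyme→macromolecule→sugar→fermenter→byproduct. dbCAN2/Hotpep rows
must pass frequency > 2.6 and hits > 6 at load time (provenance filter,
idempotent). Consumes/excretes edges are projected from the cross-feeding
network's own import/export activities, so referential integrity holds by
construction. Edge confidence is the underlying activity's score where one
exists, else 50 (mid-scale) for enzyme-derived links, for which no curated
evidence count exists.

## Synthetic communities

The generator plants four guilds over **disjoint metabolite pools** —
byproducts, sugars (macromolecule degradation products), per-pair niches, and
private metabolites — so that every ordered species pair is, by construction,
purely cross-feeding, purely competing, or metabolically disjoint, and the
label is recorded as ground truth at generation time. Degraders consume a
couple of byproducts (giving them incoming influence edges and hence paths to
mediate); hubs degrade every macromolecule and so feed every fermenter;
specialist pairs share a three-metabolite niche and export nothing.
Per-edge evidence (geometric publication counts, Bernoulli KEGG flags)
exercises the confidence score.

Abundances are log-normal: species baseline (σ = 1), a per-segment location
shift of 3 log units per segment step with per-species loadings in
[0.5, 1.5], an extra 3-log-unit bloom in a random home segment for half the
species, small within-segment noise (σ = 0.25), and a +2 boost for hubs so
they survive top-k selection. Compartments of one segment share baselines
(strong positive within-segment correlation) and an identical marginal
distribution; adjacent segments are stochastically ordered — the structure
the rank-based partitioning detects. Columns are on a percent-like scale but
deliberately not renormalized to sum 100: a detected-species table covers
only part of a community, and closing the composition would cancel the common
part of the planted shift.

What the generator does **not** emulate: closed compositional abundance data
(renormalization effects), the breadth of real curated transport profiles
(planted-pool disjointness caps imports at roughly 6 per species versus ~10
in a literature-curated table), taxonomic realism, mixed feed-and-compete
pairs (excluded precisely so the planted sign is unambiguous), and
abundance–metabolism coupling (guild membership and abundance are
independent, so abundance–transport R² is near zero by design). Passing
recovery tests therefore show that the pipeline's inferences are correct
when its assumptions hold, not that the assumptions hold in any particular
real gut.

## Problem sizes and numerics

Default analysis sizes: the study-scale community is 205 species / 265
compounds / 10 macromolecules over six compartments (3/2/1 segment plan);
recovery Monte Carlos use 40-species communities for segmentation and
30-species single-hub communities for centrality, 50–100 seeds each; the sign
contract is checked on 100-species communities over 20 seeds. Determinism:
all randomness descends from a single integer seed per object (generator,
permutation test, robustness draw); outputs are byte-identical across runs.
Ties get mid-ranks everywhere; influence edges at exactly the threshold are
dropped; a receiver with zero abundance yields score 0 (degenerate pair)
rather than an infinity.

## Known limitations

* The influence discretization is one defensible reading of an elasticity
  that presence/absence data underdetermines; exact numeric agreement with
  any particular published influence matrix depends on matching that
  construction, which is why the model object is pluggable.
* The similarity and co-occurrence indices are likewise stated conventions
  (Jaccard-on-imports, Spearman-across-compartments); published correlation
  coefficients can only be matched against the original curated tables.
* Betweenness normalization follows the printed undirected constant on a
  directed graph; both alternatives are available but change the cutoff
  scale.
* With six compartments, rank correlations take few distinct values; guild
  correlations on real-sized guilds should prefer the permutation p-value
  (automatic below 30 pairs).
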