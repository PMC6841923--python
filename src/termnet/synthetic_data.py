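"""Synthetic gut communities with planted cross-feeding structure.

Every pipeline stage needs inputs whose ground truth is known: a curated-style
activity table, a compartment abundance table and an enzyme table.  The
generator plants four guilds over disjoint metabolite pools so that every
ordered species pair has an unambiguous planted relation:

* **degraders** depolymerize macromolecules; their degradation products (the
  sugar pool) feed the fermenters, while they themselves consume a couple of
  fermentation byproducts (incoming edges, hence shortest paths to mediate).
  Planted *hubs* are degraders that degrade every macromolecule and so feed
  every fermenter.
* **fermenters** import sugars and excrete classic fermentation byproducts;
  fermenters sharing sugars compete.
* **consumers** import byproducts (fed by fermenters, competing with each
  other) and export a private metabolite nobody uses.
* **specialist pairs** share a private two-metabolite niche and nothing else:
  pure competition.

Because the pools are disjoint, each labeled pair is purely cross-feeding
(exports of p intersect imports of q), purely competing (shared imports, no
feeding), or metabolically disjoint; the labels are recorded as ground truth
at generation time.

Abundances are log-normal: a species baseline (scale ``base_sigma``), plus a
per-segment location shift of ``segment_shift`` log units per segment step,
carried with heterogeneous per-species loadings, plus small within-segment
compartment noise.  Compartments of one segment share the species baselines
(strong within-segment correlation) and an identical marginal distribution;
adjacent segments are stochastically ordered — exactly the structure the
rank-based partitioning is meant to detect.  Columns are on a percent-like
scale but deliberately not renormalized to sum 100: a detected-species table
covers only part of a community, and closing the composition would cancel the
common part of the planted shift.  All randomness flows from the single spec
seed and outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .degradation import EnzymeAnnotation, EnzymeSource, write_enzyme_table
from .errors import DomainError
from .network_model import (
    Activity,
    Compound,
    CompoundClass,
    CrossFeedingNetwork,
    MetabolicActivity,
)
from .segmentation import AbundanceTable, DEFAULT_COMPARTMENTS, DEFAULT_MIN_ABUNDANCE

_BYPRODUCTS = ("acetate", "ethanol", "lactate", "butanol", "h2", "co2",
               "propionate", "succinate", "formate", "methane", "ammonia",
               "butyrate", "valerate", "glycerol", "methanol", "ethanolamine")
_SUGARS = ("glucose", "xylose", "cellobiose", "arabinose", "mannose", "maltose",
           "fructose", "ribose")
_MACROS = ("cellulose", "hemicellulose", "pectin", "starch", "xylan", "lignin",
           "chitin", "pullulan", "arabinan", "galactan")

_GH_CATALOG: dict[str, list[tuple[str, str]]] = {
    "cellulose": [("endoglucanase", "GH5"), ("cellobiohydrolase", "GH48"),
                  ("exoglucanase", "GH6"), ("β-glucosidase", "GH3")],
    "hemicellulose": [("endo-1,4-β-xylanase", "GH10"), ("β-xylosidase", "GH43"),
                      ("β-mannanase", "GH26")],
    "xylan": [("endo-1,4-β-xylanase", "GH11"), ("β-xylosidase", "GH43")],
    "pectin": [("polygalacturonase", "GH28")],
    "starch": [("α-amylase", "GH13"), ("pullulanase", "GH13")],
}


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community, sized by default to the termite
    study (205 species, 265 metabolites incl. 10 macromolecules, 6 gut
    compartments grouped 3/2/1)."""

    n_species: int = 205
    n_metabolites: int = 265
    n_macromolecules: int = 10
    degrader_fraction: float = 0.15
    fermenter_fraction: float = 0.35
    specialist_fraction: float = 0.20  # paired; remainder are byproduct consumers
    n_hubs: int = 1
    cross_feeding_density: float = 0.25  # per-sugar import probability of a fermenter
    competition_density: float = 0.5  # per-byproduct import probability of a consumer
    n_compartments: int = 6
    segment_plan: tuple[int, ...] = (3, 2, 1)  # compartments per planted segment
    base_sigma: float = 1.0  # species baseline log-abundance scale
    segment_shift: float = 3.0  # log-unit location shift between adjacent segments
    response_heterogeneity: float = 0.5  # spread of per-species shift loadings
    bloom_fraction: float = 0.5  # species with a preferred home segment
    bloom_shift: float = 3.0  # log-unit bloom in the home segment
    within_noise: float = 0.25  # within-segment compartment log noise
    hub_abundance_boost: float = 2.0  # log units added to hub baselines
    min_abundance: float = DEFAULT_MIN_ABUNDANCE
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 4:
            raise DomainError("need at least 4 species")
        if self.n_macromolecules < 1 or self.n_metabolites <= self.n_macromolecules:
            raise DomainError("need at least one macromolecule and one small metabolite")
        fracs = (self.degrader_fraction, self.fermenter_fraction, self.specialist_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise DomainError("guild fractions must be non-negative and sum to <= 1")
        if not 0 < self.cross_feeding_density <= 1:
            raise DomainError("cross_feeding_density must be in (0, 1]")
        if not 0 < self.competition_density <= 1:
            raise DomainError("competition_density must be in (0, 1]")
        if sum(self.segment_plan) != self.n_compartments:
            raise DomainError("segment_plan must sum to n_compartments")
        if self.n_hubs > max(1, int(round(self.degrader_fraction * self.n_species))):
            raise DomainError("more hubs than degraders")


@dataclass
class SyntheticCommunity:
    """Generated inputs plus the planted ground truth."""

    spec: CommunitySpec
    network: CrossFeedingNetwork
    abundance: AbundanceTable
    enzymes: list[EnzymeAnnotation]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        acts = sorted(
            self.network.activities,
            key=lambda a: (a.species, a.compound, a.activity.value),
        )
        pd.DataFrame(
            [
                {
                    "species": a.species,
                    "compound": a.compound,
                    "activity": a.activity.value,
                    "n_publications": a.n_publications,
                    "kegg_flag": a.kegg_flag,
                }
                for a in acts
            ]
        ).to_csv(outdir / "activities.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "compound": c.name,
                    "class": c.klass.value,
                    "degradation_products": ";".join(sorted(c.degradation_products)),
                }
                for c in sorted(self.network.compounds.values(), key=lambda c: c.name)
            ]
        ).to_csv(outdir / "compounds.tsv", sep="\t", index=False)
        self.abundance.to_tsv(outdir / "abundance.tsv")
        write_enzyme_table(self.enzymes, outdir / "enzymes.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True) + "\n"
        )


def _names(prefix: str, n: int, seeded: tuple[str, ...]) -> list[str]:
    out = list(seeded[:n])
    out += [f"{prefix}_{i}" for i in range(len(out), n)]
    return out


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate the three input tables and ground-truth labels from a spec.

    Raises :class:`DomainError` when the metabolite budget cannot host the
    disjoint guild pools the planted structure requires.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_deg = max(1, int(round(spec.degrader_fraction * spec.n_species)))
    n_ferm = max(1, int(round(spec.fermenter_fraction * spec.n_species)))
    n_spec_pairs = int(round(spec.specialist_fraction * spec.n_species)) // 2
    n_cons = spec.n_species - n_deg - n_ferm - 2 * n_spec_pairs
    if n_cons < 0:
        raise DomainError("guild fractions leave no room for byproduct consumers")

    n_small = spec.n_metabolites - spec.n_macromolecules
    n_by = min(len(_BYPRODUCTS), max(4, n_small // 12))
    n_sugar = max(spec.n_macromolecules * 2, n_small // 8)
    n_private = n_cons + 3 * n_spec_pairs
    if n_by + n_sugar + n_private > n_small:
        raise DomainError(
            f"metabolite budget too small for planted pools: need "
            f"{n_by + n_sugar + n_private} small metabolites, have {n_small}"
        )

    byproducts = list(_BYPRODUCTS[:n_by])
    sugars = _names("sugar", n_sugar, _SUGARS)
    n_rest = n_small - n_by - n_sugar
    private = [f"met_{i}" for i in range(n_rest)]
    private_iter = iter(private)
    macros = _names("macro", spec.n_macromolecules, _MACROS)

    # macromolecule products partition the sugar pool (>= 2 each), so a hub
    # degrading everything effectively exports every sugar
    order = list(rng.permutation(n_sugar))
    splits = np.array_split(order, spec.n_macromolecules)
    macro_products = {
        m: sorted(sugars[i] for i in chunk) for m, chunk in zip(macros, splits)
    }
    for m in macros:
        while len(macro_products[m]) < 2:
            extra = sugars[int(rng.integers(n_sugar))]
            if extra not in macro_products[m]:
                macro_products[m].append(extra)
                macro_products[m].sort()

    species = [f"sp_{i:03d}" for i in range(spec.n_species)]
    hubs = species[:spec.n_hubs]
    degraders = species[:n_deg]
    fermenters = species[n_deg : n_deg + n_ferm]
    consumers = species[n_deg + n_ferm : n_deg + n_ferm + n_cons]
    specialists = species[n_deg + n_ferm + n_cons :]

    imports: dict[str, set[str]] = {s: set() for s in species}
    exports: dict[str, set[str]] = {s: set() for s in species}
    degrades: dict[str, set[str]] = {s: set() for s in species}
    guild: dict[str, str] = {}

    for d in degraders:
        guild[d] = "hub" if d in hubs else "degrader"
        if d in hubs:
            degrades[d] = set(macros)
        else:
            k = int(rng.integers(1, 3))
            degrades[d] = set(rng.choice(macros, size=min(k, len(macros)), replace=False))
        # degraders feed on fermentation byproducts, which gives them incoming
        # influence edges (they are fed by fermenters) and mediating paths
        imports[d] = set(
            rng.choice(byproducts, size=min(2, len(byproducts)), replace=False)
        )

    for f in fermenters:
        guild[f] = "fermenter"
        mask = rng.random(n_sugar) < spec.cross_feeding_density
        chosen = {sugars[i] for i in range(n_sugar) if mask[i]}
        if len(chosen) < 2:
            chosen |= set(rng.choice(sugars, size=2, replace=False))
        imports[f] = chosen
        k = int(rng.integers(1, 4))
        exports[f] = set(rng.choice(byproducts, size=min(k, len(byproducts)), replace=False))

    for g in consumers:
        guild[g] = "consumer"
        mask = rng.random(len(byproducts)) < spec.competition_density
        chosen = {byproducts[i] for i in range(len(byproducts)) if mask[i]}
        if not chosen:
            chosen = {byproducts[int(rng.integers(len(byproducts)))]}
        imports[g] = chosen
        exports[g] = {next(private_iter)}

    for i in range(0, len(specialists) - 1, 2):
        p, q = specialists[i], specialists[i + 1]
        niche = {next(private_iter), next(private_iter), next(private_iter)}
        for s in (p, q):
            guild[s] = "specialist"
            imports[s] = set(niche)
    if len(specialists) % 2:  # odd leftover becomes a lone consumer
        s = specialists[-1]
        guild[s] = "consumer"
        imports[s] = {byproducts[int(rng.integers(len(byproducts)))]}
        exports[s] = {next(private_iter)}
        consumers = consumers + [s]
        specialists = specialists[:-1]

    # --- planted relations over the disjoint pools -------------------------------
    eff_exports = {
        s: exports[s] | set().union(*(macro_products[m] for m in degrades[s]))
        if degrades[s]
        else set(exports[s])
        for s in species
    }
    relations: dict[str, list[list[str]]] = {"feed": [], "compete": [], "none": []}
    for p in species:
        for q in species:
            if p == q:
                continue
            if eff_exports[p] & imports[q]:
                relations["feed"].append([p, q])
            elif imports[p] & imports[q]:
                relations["compete"].append([p, q])
            else:
                relations["none"].append([p, q])

    # --- activity rows with evidence ----------------------------------------------
    activities: list[MetabolicActivity] = []
    for s in species:
        both = imports[s] & exports[s]
        for m in sorted(imports[s] - both):
            activities.append(_evidenced(s, m, Activity.IMPORT, rng))
        for m in sorted(exports[s] - both):
            activities.append(_evidenced(s, m, Activity.EXPORT, rng))
        for m in sorted(both):
            activities.append(_evidenced(s, m, Activity.BOTH, rng))
        for m in sorted(degrades[s]):
            activities.append(_evidenced(s, m, Activity.DEGRADES, rng))

    compounds = [Compound(n, CompoundClass.SMALL_METABOLITE) for n in
                 byproducts + sugars + private]
    compounds += [
        Compound(m, CompoundClass.MACROMOLECULE, frozenset(macro_products[m]))
        for m in macros
    ]
    groups = {s: guild[s] for s in species}
    network = CrossFeedingNetwork(compounds, activities, groups)

    # --- abundances ----------------------------------------------------------------
    if spec.n_compartments == 6:
        comps = list(DEFAULT_COMPARTMENTS)
    else:
        comps = [f"comp_{i}" for i in range(spec.n_compartments)]
    seg_of_comp: list[int] = []
    for si, size in enumerate(spec.segment_plan):
        seg_of_comp += [si] * size

    z = rng.normal(0.0, spec.base_sigma, size=spec.n_species)
    for i, s in enumerate(species):
        if s in hubs:
            z[i] += spec.hub_abundance_boost
    # per-segment location shift with heterogeneous per-species loadings:
    # segments are stochastically ordered in the marginal the rank test sees,
    # while compartments of one segment share the species baselines (strong
    # within-segment correlation) and differ only by small noise; on top of
    # that, half the species bloom in a random home segment, so each segment
    # has its own dominant taxa
    h = spec.response_heterogeneity
    loadings = rng.uniform(1.0 - h, 1.0 + h, size=spec.n_species)
    blooming = rng.random(spec.n_species) < spec.bloom_fraction
    home = rng.integers(0, len(spec.segment_plan), size=spec.n_species)
    log_ab = np.empty((spec.n_species, spec.n_compartments))
    for j, seg in enumerate(seg_of_comp):
        bloom = np.where(blooming & (home == seg), spec.bloom_shift, 0.0)
        log_ab[:, j] = (
            z
            + spec.segment_shift * seg * loadings
            + bloom
            + rng.normal(0.0, spec.within_noise, size=spec.n_species)
        )
    raw = np.exp(log_ab)
    # percent-like scale: columns are NOT renormalized to sum exactly 100 --
    # a detected-species table covers only part of the community, and exact
    # column normalization would cancel the common part of the planted
    # segment-level shift
    rel = raw / spec.n_species
    abundance = AbundanceTable(
        pd.DataFrame(rel, index=species, columns=comps),
        min_abundance=spec.min_abundance,
    )

    # --- enzyme annotations for the degraders --------------------------------------
    enzymes: list[EnzymeAnnotation] = []
    for d in degraders:
        for m in sorted(degrades[d]):
            catalog = _GH_CATALOG.get(m, [("glycoside hydrolase", "GH0")])
            k = int(rng.integers(1, min(2, len(catalog)) + 1))
            idx = rng.choice(len(catalog), size=k, replace=False)
            for i in sorted(idx):
                enzyme, fam = catalog[i]
                src = EnzymeSource(
                    ["cazy", "dbcan2_hotpep", "curated"][int(rng.integers(3))]
                )
                freq = hits = None
                if src is EnzymeSource.DBCAN2_HOTPEP:
                    freq = float(np.round(rng.uniform(2.7, 12.0), 2))
                    hits = int(rng.integers(7, 40))
                enzymes.append(EnzymeAnnotation(d, enzyme, fam, m, src, freq, hits))

    truth = {
        "guilds": guild,
        "hubs": list(hubs),
        "segment_plan": list(spec.segment_plan),
        "shift_loadings": {s: float(l) for s, l in zip(species, loadings)},
        "home_segment": {
            s: int(g) for s, g, b in zip(species, home, blooming) if b
        },
        "relations": relations,
        "macromolecule_products": macro_products,
    }
    return SyntheticCommunity(spec, network, abundance, enzymes, truth)


def _evidenced(
    species: str, compound: str, activity: Activity, rng: np.random.Generator
) -> MetabolicActivity:
    n_pub = int(rng.geometric(0.3))
    kegg = int(rng.random() < 0.7)
    return MetabolicActivity(species, compound, activity, n_pub, kegg)
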