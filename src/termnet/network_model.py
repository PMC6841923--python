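"""Species-wide metabolic cross-feeding network: data model, ingest, profiling.

The central object is :class:`CrossFeedingNetwork`, a bipartite graph between
microbial species and compounds.  Compounds are either small metabolites or
macromolecules (cellulose, hemicellulose, pectin, starch, ...).  A species is
linked to a compound by one of four literature-curated activities: it imports
it, exports it, does both, or — for macromolecules only — degrades it
extracellularly.  Degradation releases the macromolecule's breakdown products
into the shared microenvironment, so the degradation products of every
macromolecule a species degrades count toward that species' *effective export
set*.  That rule is what gives macromolecule degraders their outsized role in
the community feed.

Each activity row carries a confidence score in [0, 100] combining literature
support (weight 70) with corroboration in the KEGG database (weight 30):

    confidence = (n / N) * 70 + K * 30

where ``n`` is the number of publications supporting the row, ``N`` the
maximum publication count over all rows of the table, and ``K`` a 0/1 KEGG
availability flag.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._names import normalize_name
from .errors import DomainError, ParseError, ValidationError


class Activity(str, enum.Enum):
    """Curated metabolic activity linking a species to a compound."""

    IMPORT = "import"
    EXPORT = "export"
    BOTH = "both"
    DEGRADES = "degrades"


class CompoundClass(str, enum.Enum):
    SMALL_METABOLITE = "small_metabolite"
    MACROMOLECULE = "macromolecule"


@dataclass(frozen=True)
class Compound:
    """A small metabolite or a degradable macromolecule.

    ``degradation_products`` is empty unless the compound is a macromolecule;
    product names refer to small metabolites.
    """

    name: str
    klass: CompoundClass
    degradation_products: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.degradation_products and self.klass is not CompoundClass.MACROMOLECULE:
            raise ValidationError(
                f"compound {self.name!r} has degradation products but is not a macromolecule"
            )


@dataclass(frozen=True)
class MetabolicActivity:
    """One curated (species, compound, activity) edge with its evidence."""

    species: str
    compound: str
    activity: Activity
    n_publications: int = 0
    kegg_flag: int = 0

    def __post_init__(self) -> None:
        if self.n_publications < 0:
            raise ValidationError(
                f"negative publication count for ({self.species}, {self.compound})"
            )
        if self.kegg_flag not in (0, 1):
            raise ValidationError(
                f"kegg_flag must be 0 or 1, got {self.kegg_flag!r} "
                f"for ({self.species}, {self.compound})"
            )


def confidence_score(n: int, n_max: int, kegg_flag: int) -> float:
    """Evidence score in [0, 100] for one edge.

    Parameters
    ----------
    n : publications supporting the edge (0 <= n <= n_max).
    n_max : maximum publication count over all edges of the table (>= 1).
    kegg_flag : 1 if the activity is corroborated by KEGG, else 0.
    """
    if n_max < 1:
        raise DomainError(f"n_max must be >= 1, got {n_max}")
    if not 0 <= n <= n_max:
        raise DomainError(f"n must satisfy 0 <= n <= n_max={n_max}, got {n}")
    if kegg_flag not in (0, 1):
        raise DomainError(f"kegg_flag must be 0 or 1, got {kegg_flag!r}")
    return (n / n_max) * 70.0 + kegg_flag * 30.0


class CrossFeedingNetwork:
    """Validated bipartite species–compound network with typed activities.

    Construction validates referential integrity (every activity references a
    known compound), the degradation contract (DEGRADES rows point at
    macromolecules with at least one degradation product) and duplicate
    handling: byte-identical repeated rows are merged, identical triples with
    conflicting evidence raise.
    """

    def __init__(
        self,
        compounds: Iterable[Compound],
        activities: Iterable[MetabolicActivity],
        groups: Mapping[str, str] | None = None,
    ) -> None:
        self.compounds: dict[str, Compound] = {}
        for c in compounds:
            key = normalize_name(c.name)
            if key in self.compounds and self.compounds[key] != c:
                raise ValidationError(f"conflicting definitions for compound {c.name!r}")
            self.compounds[key] = c

        seen: dict[tuple[str, str, Activity], MetabolicActivity] = {}
        conflicts: list[str] = []
        for a in activities:
            skey = normalize_name(a.species)
            ckey = normalize_name(a.compound)
            a = MetabolicActivity(skey, ckey, a.activity, a.n_publications, a.kegg_flag)
            triple = (skey, ckey, a.activity)
            if triple in seen:
                if seen[triple] != a:
                    conflicts.append(f"{skey} / {ckey} / {a.activity.value}")
                continue  # idempotent merge of identical rows
            seen[triple] = a
        if conflicts:
            raise ValidationError(
                "duplicate conflicting rows (same species/compound/activity, "
                "different evidence): " + "; ".join(sorted(set(conflicts)))
            )
        self.activities: list[MetabolicActivity] = list(seen.values())

        for a in self.activities:
            comp = self.compounds.get(a.compound)
            if comp is None:
                raise ValidationError(
                    f"activity references unknown compound {a.compound!r} "
                    f"(species {a.species!r})"
                )
            if a.activity is Activity.DEGRADES:
                if comp.klass is not CompoundClass.MACROMOLECULE:
                    raise ValidationError(
                        f"{a.species!r} degrades {a.compound!r}, which is not a macromolecule"
                    )
                if not comp.degradation_products:
                    raise ValidationError(
                        f"macromolecule {a.compound!r} is degraded but has no degradation products"
                    )
        for comp in self.compounds.values():
            for prod in comp.degradation_products:
                pkey = normalize_name(prod)
                target = self.compounds.get(pkey)
                if target is None:
                    raise ValidationError(
                        f"degradation product {prod!r} of {comp.name!r} is not a known compound"
                    )
                if target.klass is not CompoundClass.SMALL_METABOLITE:
                    raise ValidationError(
                        f"degradation product {prod!r} of {comp.name!r} is not a small metabolite"
                    )

        self.species: set[str] = {a.species for a in self.activities}
        self.groups: dict[str, str] = {
            normalize_name(k): v for k, v in (groups or {}).items()
        }
        self.n_max: int = max((a.n_publications for a in self.activities), default=0)

        self._imports: dict[str, set[str]] = {}
        self._explicit_exports: dict[str, set[str]] = {}
        self._degraded: dict[str, set[str]] = {}
        for a in self.activities:
            if a.activity in (Activity.IMPORT, Activity.BOTH):
                self._imports.setdefault(a.species, set()).add(a.compound)
            if a.activity in (Activity.EXPORT, Activity.BOTH):
                self._explicit_exports.setdefault(a.species, set()).add(a.compound)
            if a.activity is Activity.DEGRADES:
                self._degraded.setdefault(a.species, set()).add(a.compound)

    # -- per-species compound sets -------------------------------------------------

    def imports(self, species: str) -> set[str]:
        return set(self._imports.get(normalize_name(species), set()))

    def explicit_exports(self, species: str) -> set[str]:
        return set(self._explicit_exports.get(normalize_name(species), set()))

    def degraded(self, species: str) -> set[str]:
        return set(self._degraded.get(normalize_name(species), set()))

    def effective_exports(self, species: str) -> set[str]:
        """Explicit exports plus the degradation products of every macromolecule
        the species degrades."""
        key = normalize_name(species)
        out = set(self._explicit_exports.get(key, set()))
        for macro in self._degraded.get(key, set()):
            out |= {normalize_name(p) for p in self.compounds[macro].degradation_products}
        return out

    # -- evidence ------------------------------------------------------------------

    def confidence(self, activity: MetabolicActivity) -> float:
        n_max = max(self.n_max, 1)
        return confidence_score(activity.n_publications, n_max, activity.kegg_flag)

    def confidence_table(self) -> pd.DataFrame:
        rows = [
            {
                "species": a.species,
                "compound": a.compound,
                "activity": a.activity.value,
                "n_publications": a.n_publications,
                "kegg_flag": a.kegg_flag,
                "confidence": self.confidence(a),
            }
            for a in self.activities
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "species",
                "compound",
                "activity",
                "n_publications",
                "kegg_flag",
                "confidence",
            ],
        )

    def activity_confidence(self, species: str, compound: str) -> float | None:
        """Confidence of the highest-evidence activity linking species and
        compound, or None if no such activity exists."""
        skey, ckey = normalize_name(species), normalize_name(compound)
        best: float | None = None
        for a in self.activities:
            if a.species == skey and a.compound == ckey:
                c = self.confidence(a)
                best = c if best is None else max(best, c)
        return best

    # -- tallies -------------------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_metabolites(self) -> int:
        return sum(
            1 for c in self.compounds.values() if c.klass is CompoundClass.SMALL_METABOLITE
        )

    @property
    def n_transport_events(self) -> int:
        """Number of import/export/both rows (degradation rows excluded)."""
        return sum(1 for a in self.activities if a.activity is not Activity.DEGRADES)

    @property
    def n_degradation_events(self) -> int:
        return sum(1 for a in self.activities if a.activity is Activity.DEGRADES)

    # -- restriction (robustness resampling) ----------------------------------------

    def subset(
        self,
        keep_species: Iterable[str] | None = None,
        keep_compounds: Iterable[str] | None = None,
    ) -> "CrossFeedingNetwork":
        """Network restricted to the given species and/or compounds.

        Dropping a small metabolite also removes it from every macromolecule's
        degradation-product list; a macromolecule left without products loses
        its DEGRADES rows (they would violate the degradation contract).
        """
        skeep = (
            None if keep_species is None else {normalize_name(s) for s in keep_species}
        )
        ckeep = (
            None
            if keep_compounds is None
            else {normalize_name(c) for c in keep_compounds}
        )

        compounds: list[Compound] = []
        kept_keys: set[str] = set()
        for key, comp in self.compounds.items():
            if ckeep is not None and key not in ckeep:
                continue
            kept_keys.add(key)
        for key in kept_keys:
            comp = self.compounds[key]
            products = frozenset(
                p for p in comp.degradation_products if normalize_name(p) in kept_keys
            )
            compounds.append(Compound(comp.name, comp.klass, products))
        empty_macros = {
            normalize_name(c.name)
            for c in compounds
            if c.klass is CompoundClass.MACROMOLECULE and not c.degradation_products
        }

        activities = [
            a
            for a in self.activities
            if (skeep is None or a.species in skeep)
            and a.compound in kept_keys
            and not (a.activity is Activity.DEGRADES and a.compound in empty_macros)
        ]
        groups = {s: g for s, g in self.groups.items() if skeep is None or s in skeep}
        return CrossFeedingNetwork(compounds, activities, groups)

    # -- exports ---------------------------------------------------------------------

    def to_sif(self, path: str | Path) -> None:
        """Cytoscape SIF export: ``species<TAB>activity<TAB>compound``."""
        verbs = {
            Activity.IMPORT: "imports",
            Activity.EXPORT: "exports",
            Activity.BOTH: "imports-exports",
            Activity.DEGRADES: "degrades",
        }
        lines = sorted(
            f"{a.species}\t{verbs[a.activity]}\t{a.compound}" for a in self.activities
        )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for key, comp in self.compounds.items():
            g.add_node(key, kind="compound", klass=comp.klass.value)
        for s in self.species:
            g.add_node(s, kind="species", group=self.groups.get(s, ""))
        for a in self.activities:
            g.add_edge(
                a.species,
                a.compound,
                activity=a.activity.value,
                confidence=self.confidence(a),
            )
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


# ---------------------------------------------------------------------------------
# ingest


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


def load_compound_table(path: str | Path) -> list[Compound]:
    """Read the compound table: columns ``compound, class, degradation_products``
    (semicolon-separated product list)."""
    df = _read_table(path)
    required = {"compound", "class"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"compound table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    compounds = []
    for i, row in df.iterrows():
        raw_klass = str(row["class"]).strip().lower()
        try:
            klass = CompoundClass(raw_klass)
        except ValueError:
            aliases = {"small": CompoundClass.SMALL_METABOLITE,
                       "metabolite": CompoundClass.SMALL_METABOLITE,
                       "macro": CompoundClass.MACROMOLECULE}
            if raw_klass not in aliases:
                raise ParseError(
                    f"row {i + 2} of {path}: unknown compound class {row['class']!r}"
                ) from None
            klass = aliases[raw_klass]
        products: frozenset[str] = frozenset()
        if "degradation_products" in df.columns and pd.notna(row.get("degradation_products")):
            raw = str(row["degradation_products"]).strip()
            if raw:
                products = frozenset(
                    normalize_name(p) for p in raw.split(";") if p.strip()
                )
        compounds.append(Compound(str(row["compound"]).strip(), klass, products))
    return compounds


def load_activity_table(path: str | Path) -> list[MetabolicActivity]:
    """Read the activity table: columns
    ``species, compound, activity[, n_publications, kegg_flag]``."""
    df = _read_table(path)
    required = {"species", "compound", "activity"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"activity table {path} must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    acts = []
    for i, row in df.iterrows():
        raw = str(row["activity"]).strip().lower()
        try:
            activity = Activity(raw)
        except ValueError:
            raise ParseError(
                f"row {i + 2} of {path}: unknown activity keyword {row['activity']!r} "
                "(expected import|export|both|degrades)"
            ) from None
        n_pub = 0
        if "n_publications" in df.columns and pd.notna(row.get("n_publications")):
            n_pub = int(float(row["n_publications"]))
        kegg = 0
        if "kegg_flag" in df.columns and pd.notna(row.get("kegg_flag")):
            kegg = int(float(row["kegg_flag"]))
        acts.append(
            MetabolicActivity(
                str(row["species"]).strip(), str(row["compound"]).strip(), activity, n_pub, kegg
            )
        )
    return acts


def load_network(
    activity_table: str | Path,
    compound_table: str | Path,
    groups: Mapping[str, str] | None = None,
) -> CrossFeedingNetwork:
    """Build a validated :class:`CrossFeedingNetwork` from the two delimited tables.

    Strain-level rows sharing a species name are merged into one species with
    the union of activities (identical repeated rows collapse; conflicting
    evidence for the same triple raises :class:`ValidationError`).
    """
    return CrossFeedingNetwork(
        load_compound_table(compound_table), load_activity_table(activity_table), groups
    )


def load_workbook_sheets(
    workbook: str | Path,
    activity_sheet: str,
    compound_sheet: str | None = None,
) -> CrossFeedingNetwork:
    """Read the curated tables from an Excel workbook by sheet name.

    The sheets must follow the same column contracts as the delimited tables.
    When ``compound_sheet`` is None every compound is taken to be a small
    metabolite (no degradation rows permitted).
    """
    adf = pd.read_excel(workbook, sheet_name=activity_sheet, dtype=str)
    tmp_a = Path(workbook).with_suffix(".activities.tmp.tsv")
    adf.to_csv(tmp_a, sep="\t", index=False)
    try:
        acts = load_activity_table(tmp_a)
    finally:
        tmp_a.unlink(missing_ok=True)
    if compound_sheet is not None:
        cdf = pd.read_excel(workbook, sheet_name=compound_sheet, dtype=str)
        tmp_c = Path(workbook).with_suffix(".compounds.tmp.tsv")
        cdf.to_csv(tmp_c, sep="\t", index=False)
        try:
            comps = load_compound_table(tmp_c)
        finally:
            tmp_c.unlink(missing_ok=True)
    else:
        names = sorted({a.compound for a in acts})
        comps = [Compound(n, CompoundClass.SMALL_METABOLITE) for n in names]
    return CrossFeedingNetwork(comps, acts)


# ---------------------------------------------------------------------------------
# profiling


@dataclass
class TransportProfile:
    """Per-species metabolite import/export counts with summary statistics."""

    per_species: pd.DataFrame  # index species; columns n_imported, n_exported
    mean_imports: float
    mean_exports: float
    median_imports: float
    median_exports: float


def transport_profile(net: CrossFeedingNetwork) -> TransportProfile:
    """Count imported and (effectively) exported metabolites per species.

    ``n_imported`` counts IMPORT and BOTH compounds; ``n_exported`` counts the
    effective export set, i.e. EXPORT/BOTH compounds plus degradation products.
    """
    if not net.species:
        raise DomainError("transport_profile requires a nonempty network")
    rows = {
        s: {
            "n_imported": len(net.imports(s)),
            "n_exported": len(net.effective_exports(s)),
        }
        for s in sorted(net.species)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return TransportProfile(
        per_species=df,
        mean_imports=float(df["n_imported"].mean()),
        mean_exports=float(df["n_exported"].mean()),
        median_imports=float(df["n_imported"].median()),
        median_exports=float(df["n_exported"].median()),
    )


def metabolite_usage(
    net: CrossFeedingNetwork,
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-compound consumer/producer percentages over the species considered.

    ``consumer_pct`` is the percentage of species importing the compound,
    ``producer_pct`` the percentage effectively exporting it.
    """
    if restrict_to is not None:
        species = {normalize_name(s) for s in restrict_to}
        if not species:
            raise DomainError("restriction set is empty")
        unknown = species - net.species
        if unknown:
            raise DomainError(f"restriction names unknown species: {sorted(unknown)}")
    else:
        species = net.species
    n = len(species)
    if n == 0:
        raise DomainError("metabolite_usage requires at least one species")
    imports = {s: net.imports(s) for s in species}
    exports = {s: net.effective_exports(s) for s in species}
    records = {}
    for ckey, comp in net.compounds.items():
        consumers = sum(1 for s in species if ckey in imports[s])
        producers = sum(1 for s in species if ckey in exports[s])
        records[ckey] = {
            "consumer_pct": 100.0 * consumers / n,
            "producer_pct": 100.0 * producers / n,
        }
    return pd.DataFrame.from_dict(records, orient="index").sort_index()


def abundance_transport_correlation(
    net: CrossFeedingNetwork,
    abundance,
    aggregate: str = "mean",
) -> float:
    """R-squared of a linear fit of total transport count on relative abundance.

    ``abundance`` is an AbundanceTable; each species' overall abundance is its
    mean (default) or max relative abundance across compartments.
    """
    profile = transport_profile(net).per_species
    agg = abundance.aggregate(aggregate)
    common = sorted(set(profile.index) & set(agg.index))
    if len(common) < 3:
        raise DomainError(
            f"need >= 3 species shared between network and abundance table, got {len(common)}"
        )
    x = agg.loc[common].to_numpy(dtype=float)
    y = (profile.loc[common, "n_imported"] + profile.loc[common, "n_exported"]).to_numpy(
        dtype=float
    )
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("degenerate (constant) abundance or transport vector; R^2 set to 0")
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
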