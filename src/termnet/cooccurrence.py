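"""Metabolic similarity, cross-compartment co-occurrence, and their correlation.

Two species competing for the same metabolic inputs have a high *metabolic
similarity* (Jaccard overlap of their import sets).  Whether they actually
co-occur along the gut is measured by the *co-occurrence score*, the Spearman
rank correlation of their relative-abundance vectors across the gut
compartments (only six samples exist, hence ranks).  A positive rank
correlation between the two quantities over the species pairs of two guilds is
the signature of habitat filtering (the host environment retains metabolically
similar, competing taxa together) or — for producer/consumer guild pairs — of
metabolic interdependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._names import normalize_name
from .errors import DomainError
from .network_model import CrossFeedingNetwork
from .segmentation import AbundanceTable

#: below this many pairs the correlation p-value switches to a seeded
#: permutation test instead of the large-sample t approximation
PERMUTATION_CUTOFF = 30


def metabolic_similarity(
    net: CrossFeedingNetwork, include_exports: bool = False
) -> pd.DataFrame:
    """Pairwise Jaccard similarity of species' import sets (optionally
    import ∪ effective-export sets), as a symmetric DataFrame in [0, 1].

    Species with empty sets on both sides of a pair get similarity 0 by
    convention; the diagonal is 1 for species with a nonempty set.
    """
    if not net.species:
        raise DomainError("metabolic_similarity requires a nonempty network")
    species = sorted(net.species)
    sets = {}
    for s in species:
        ms = net.imports(s)
        if include_exports:
            ms = ms | net.effective_exports(s)
        sets[s] = ms
    mat = pd.DataFrame(0.0, index=species, columns=species)
    for s in species:
        if sets[s]:
            mat.loc[s, s] = 1.0
    for p, q in combinations(species, 2):
        union = sets[p] | sets[q]
        val = len(sets[p] & sets[q]) / len(union) if union else 0.0
        mat.loc[p, q] = val
        mat.loc[q, p] = val
    return mat


def zero_variance_species(ab: AbundanceTable) -> list[str]:
    """Species whose abundance is constant across compartments; their rank
    correlation with anything is undefined."""
    arr = ab.data.to_numpy(dtype=float)
    flat = [s for s, row in zip(ab.species, arr) if np.allclose(row, row[0])]
    return flat


def cooccurrence_score(ab: AbundanceTable, method: str = "spearman") -> pd.DataFrame:
    """Pairwise species co-occurrence across compartments.

    ``spearman`` (default): rank correlation of the two abundance vectors,
    in [-1, 1]; pairs involving a zero-variance species are NaN (flagged and
    excluded downstream).  ``jaccard``: presence/absence overlap using the
    table's inclusion threshold, in [0, 1].
    """
    if len(ab.compartments) < 3:
        raise DomainError("cooccurrence_score requires >= 3 compartments")
    species = ab.species
    if method == "spearman":
        flat = set(zero_variance_species(ab))
        mat = ab.data.T.corr(method="spearman")
        for s in flat:
            mat.loc[s, :] = np.nan
            mat.loc[:, s] = np.nan
        np.fill_diagonal(mat.values, [np.nan if s in flat else 1.0 for s in species])
        return mat
    if method == "jaccard":
        present = ab.data >= ab.min_abundance
        arr = present.to_numpy()
        n = len(species)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                union = (arr[i] | arr[j]).sum()
                val = (arr[i] & arr[j]).sum() / union if union else 0.0
                out[i, j] = out[j, i] = val
        return pd.DataFrame(out, index=species, columns=species)
    raise DomainError(f"unknown co-occurrence method {method!r}")


@dataclass(frozen=True)
class GroupCorrelation:
    rho: float
    p_value: float
    n_pairs: int
    method: str  # "t-approximation" or "permutation"


def group_correlation(
    sim: pd.DataFrame,
    cooc: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    min_pairs: int = 5,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GroupCorrelation:
    """Rank correlation between metabolic similarity and co-occurrence over
    all cross-guild species pairs (p in A, q in B, p != q).

    Pairs inside A ∩ B are excluded (guilds are treated as disjoint), as are
    pairs whose co-occurrence is undefined (NaN).  The two-sided p-value uses
    the large-sample t approximation, or a seeded permutation test when fewer
    than ``PERMUTATION_CUTOFF`` pairs remain.  Symmetric in A and B.
    """
    a = {normalize_name(s) for s in group_a}
    b = {normalize_name(s) for s in group_b}
    shared = a & b
    a, b = a - shared, b - shared
    known = set(sim.index) & set(cooc.index)
    a &= known
    b &= known

    pairs = sorted({tuple(sorted((p, q))) for p in a for q in b if p != q})
    sims, coocs = [], []
    for p, q in pairs:
        c = cooc.loc[p, q]
        if pd.isna(c):
            continue
        sims.append(float(sim.loc[p, q]))
        coocs.append(float(c))
    n = len(sims)
    if n < min_pairs:
        raise DomainError(
            f"need >= {min_pairs} usable cross-group pairs, got {n}"
        )

    rho, p_t = stats.spearmanr(sims, coocs)
    rho = float(rho)
    if n >= PERMUTATION_CUTOFF:
        return GroupCorrelation(rho, float(p_t), n, "t-approximation")

    rng = np.random.default_rng(seed)
    coocs_arr = np.asarray(coocs)
    sims_arr = np.asarray(sims)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(coocs_arr)
        r, _ = stats.spearmanr(sims_arr, perm)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_permutations + 1)
    return GroupCorrelation(rho, float(p_perm), n, "permutation")


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    """Square matrix as TSV with header row and column."""
    mat.to_csv(path, sep="\t", index_label="species")


def load_groups(path: str | Path) -> dict[str, str]:
    """Two-column ``species, group`` membership file."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if not {"species", "group"}.issubset(df.columns):
        raise DomainError(f"group file {path} must have columns species, group")
    return {normalize_name(r["species"]): str(r["group"]) for _, r in df.iterrows()}
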