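"""Gut-compartment abundance table and rank-based segment partitioning.

The gut of a wood-feeding higher termite is compartmentalized into crop (C),
midgut (M) and hindgut sections P1, P3, P4, P5.  Microbial relative-abundance
distributions are compared between adjacent compartments with the
Kruskal–Wallis one-way rank test,

    H = 12 / (N (N + 1)) * sum_i R_i^2 / n_i  -  3 (N + 1)

with R_i the rank sum of group i (mid-ranks for ties), n_i its size and N the
total observation count.  Compartments whose abundance distributions are
statistically indistinguishable (p > alpha under the chi-square approximation)
are merged, left to right along the gut axis, into segments S1, S2, ...  On
the termite data this recovers S1 = {C, M, P1}, S2 = {P3, P4}, S3 = {P5}.

Note the default H is the plain (uncorrected) statistic above; the
tie-corrected variant, which divides by 1 - sum(t^3 - t)/(N^3 - N), is
available behind a flag and coincides with it when no ties exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._names import normalize_name
from .errors import DomainError, ParseError

#: anatomical order of the six termite gut compartments
DEFAULT_COMPARTMENTS = ("C", "M", "P1", "P3", "P4", "P5")

#: inclusion threshold: considerable relative abundance, in percent
DEFAULT_MIN_ABUNDANCE = 0.02


@dataclass
class AbundanceTable:
    """Species x compartment relative abundances (percent), compartments in
    anatomical order, with an inclusion threshold in percent."""

    data: pd.DataFrame
    min_abundance: float = DEFAULT_MIN_ABUNDANCE

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [normalize_name(s) for s in self.data.index]
        if self.data.index.duplicated().any():
            dups = sorted(self.data.index[self.data.index.duplicated()])
            raise ParseError(f"duplicate species rows in abundance table: {dups}")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ParseError("duplicate compartment columns in abundance table")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ParseError("negative abundances in abundance table")
        self.data = self.data.astype(float)

    @property
    def compartments(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_tsv(
        cls, path: str | Path, min_abundance: float = DEFAULT_MIN_ABUNDANCE
    ) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, min_abundance=min_abundance)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="species")

    def aggregate(self, how: str = "mean") -> pd.Series:
        """Overall per-species abundance across compartments (mean or max)."""
        if how == "mean":
            return self.data.mean(axis=1)
        if how == "max":
            return self.data.max(axis=1)
        raise DomainError(f"unknown aggregate {how!r} (expected 'mean' or 'max')")

    def segment_abundance(self, compartments: Sequence[str]) -> pd.Series:
        """Per-species mean abundance over a block of compartments."""
        missing = [c for c in compartments if c not in self.data.columns]
        if missing:
            raise DomainError(f"unknown compartments {missing}")
        return self.data[list(compartments)].mean(axis=1)

    def detected_species(self, compartments: Sequence[str] | None = None) -> list[str]:
        """Species at or above the inclusion threshold in at least one of the
        given compartments (default: any compartment)."""
        cols = list(compartments) if compartments is not None else self.compartments
        mask = (self.data[cols] >= self.min_abundance).any(axis=1)
        return list(self.data.index[mask])

    def subset_species(self, keep: Iterable[str]) -> "AbundanceTable":
        keys = {normalize_name(s) for s in keep}
        return AbundanceTable(
            self.data.loc[[s for s in self.data.index if s in keys]],
            min_abundance=self.min_abundance,
        )


# ---------------------------------------------------------------------------------
# Kruskal–Wallis


@dataclass(frozen=True)
class KruskalWallisResult:
    h_stat: float
    p_value: float
    n_groups: int
    n_total: int


def kruskal_wallis(
    groups: Sequence[Sequence[float]], tie_correction: bool = False
) -> KruskalWallisResult:
    """Kruskal–Wallis one-way rank test on >= 2 groups.

    Mid-ranks are assigned over the pooled sample; the statistic is the plain
    rank-sum form (see module docstring), optionally tie-corrected.  The
    p-value uses the chi-square approximation with (#groups - 1) degrees of
    freedom.
    """
    if len(groups) < 2:
        raise DomainError("kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrays]
    if any(s == 0 for s in sizes):
        raise DomainError("kruskal_wallis: every group must be nonempty")
    n_total = int(sum(sizes))
    if n_total < 3:
        raise DomainError(f"kruskal_wallis requires N >= 3 observations, got {n_total}")

    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    offset = 0
    for size in sizes:
        r_i = float(ranks[offset : offset + size].sum())
        h += r_i**2 / size
        offset += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        denom = 1.0 - float(((counts**3 - counts).sum())) / (n_total**3 - n_total)
        if denom <= 0:  # all observations identical
            h = 0.0
        else:
            h /= denom

    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
    return KruskalWallisResult(float(h), p, len(groups), n_total)


# ---------------------------------------------------------------------------------
# segment partitioning


@dataclass(frozen=True)
class MergeRecord:
    """One greedy merge decision: the candidate compartment block tested, the
    test result, and whether the block was kept as one segment."""

    compartments: tuple[str, ...]
    h_stat: float
    p_value: float
    merged: bool


@dataclass
class SegmentPartition:
    """Mapping of compartments to contiguous segments with the test trail."""

    assignment: dict[str, str]  # compartment -> segment label (S1, S2, ...)
    records: list[MergeRecord] = field(default_factory=list)

    @property
    def segments(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for comp, seg in self.assignment.items():
            out.setdefault(seg, []).append(comp)
        return out

    def segment_sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for _, v in sorted(self.segments.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compartments": "+".join(r.compartments),
                    "h_stat": r.h_stat,
                    "p_value": r.p_value,
                    "merged": r.merged,
                }
                for r in self.records
            ]
        )


def partition_segments(
    ab: AbundanceTable,
    alpha: float = 0.05,
    tie_correction: bool = False,
) -> SegmentPartition:
    """Greedy left-to-right merge of adjacent compartments into segments.

    A candidate block (current segment plus the next compartment along the gut
    axis) is kept as one segment when the Kruskal–Wallis test on its abundance
    vectors fails to reject at ``alpha`` (p > alpha reads as "similar
    distribution").  Observations entering each test are the per-species
    abundances of species at or above the inclusion threshold in at least one
    compartment of the candidate block; zeros are retained.
    """
    comps = ab.compartments
    if not comps:
        raise DomainError("abundance table has no compartments")

    records: list[MergeRecord] = []
    blocks: list[list[str]] = [[comps[0]]]
    for comp in comps[1:]:
        candidate = blocks[-1] + [comp]
        keep = ab.detected_species(candidate)
        if len(keep) < 2:
            # too few detected species to test; keep compartments apart
            records.append(MergeRecord(tuple(candidate), float("nan"), float("nan"), False))
            blocks.append([comp])
            continue
        sub = ab.data.loc[keep, candidate]
        res = kruskal_wallis(
            [sub[c].to_numpy() for c in candidate], tie_correction=tie_correction
        )
        merged = res.p_value > alpha
        records.append(MergeRecord(tuple(candidate), res.h_stat, res.p_value, merged))
        if merged:
            blocks[-1].append(comp)
        else:
            blocks.append([comp])

    assignment = {
        comp: f"S{i + 1}" for i, block in enumerate(blocks) for comp in block
    }
    return SegmentPartition(assignment, records)
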