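"""Cross-platform and cross-replicate concordance statistics.

Per-rank abundance profiles (with rank coverage, the fraction of reads
carrying a label at that rank), the three detection groups — I: found by
both platforms, II: nanopore-only, III: short-read-only — log2 fold-change
flags for shared taxa (|log2 FC| > 1 marks a significant deviation),
Spearman rank correlation reported as rho^2, and shared/specific (Venn)
phylotype counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .classify import TaxonAssignment
from .shortread import OtuTable
from .taxonomy import RANKS, Lineage


@dataclass
class AbundanceProfile:
    """Taxon -> count / relative abundance at one rank.

    Reads without a label at the rank are excluded from the abundances but
    counted in the coverage denominator.
    """

    rank: str
    counts: dict[str, int]
    total_reads: int  # all classified reads, labelled at this rank or not

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")

    @property
    def labelled_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def rank_coverage(self) -> float:
        return self.labelled_reads / self.total_reads if self.total_reads else 0.0

    @property
    def abundances(self) -> dict[str, float]:
        lab = self.labelled_reads
        return {t: c / lab for t, c in self.counts.items()} if lab else {}

    @property
    def taxa(self) -> set[str]:
        return set(self.counts)


ProfileInput = Union[Sequence[TaxonAssignment], OtuTable]


def profile_abundance(data: ProfileInput, rank: str) -> AbundanceProfile:
    """Build a per-rank profile from long-read assignments or an OTU table.

    For an OTU table each member read carries its OTU's lineage, so counts
    are read counts on both platforms.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    pairs: list[tuple[Lineage, int]]
    if isinstance(data, OtuTable):
        pairs = [(o.lineage if o.lineage is not None else Lineage(), o.count) for o in data.otus]
    else:
        pairs = [(a.lineage, 1) for a in data]
    if not pairs:
        raise ValueError("no classified input to profile")
    counts: dict[str, int] = {}
    total = 0
    for lineage, n in pairs:
        total += n
        if lineage.label(rank):
            key = lineage.prefix_string(rank)
            counts[key] = counts.get(key, 0) + n
    return AbundanceProfile(rank, counts, total)


@dataclass
class ComparisonRecord:
    taxon: str
    rank: str
    abundance_a: float  # short-read platform
    abundance_b: float  # nanopore platform
    group: str  # "I" both, "II" nanopore only, "III" short-read only
    log2fc: Optional[float] = None  # log2(B/A), defined only for group I

    @property
    def significant_deviation(self) -> bool:
        return self.log2fc is not None and abs(self.log2fc) > 1.0


def compare_platforms(
    profile_a: AbundanceProfile, profile_b: AbundanceProfile
) -> list[ComparisonRecord]:
    """Partition the union of taxa into detection groups and flag shared
    taxa whose relative abundances deviate more than 2-fold.

    ``profile_a`` is the short-read profile, ``profile_b`` the nanopore
    profile; log2 fold-changes are log2(B/A) over relative abundances, so
    unequal sequencing depths cancel.  No pseudocounts: the fold-change is
    defined only where both abundances are positive (group I).
    """
    if profile_a.rank != profile_b.rank:
        raise ValueError(
            f"rank mismatch: {profile_a.rank!r} vs {profile_b.rank!r}"
        )
    ab_a = profile_a.abundances
    ab_b = profile_b.abundances
    records: list[ComparisonRecord] = []
    for taxon in sorted(set(ab_a) | set(ab_b)):
        a = ab_a.get(taxon, 0.0)
        b = ab_b.get(taxon, 0.0)
        if a > 0 and b > 0:
            records.append(
                ComparisonRecord(taxon, profile_a.rank, a, b, "I", math.log2(b / a))
            )
        elif b > 0:
            records.append(ComparisonRecord(taxon, profile_a.rank, a, b, "II"))
        else:
            records.append(ComparisonRecord(taxon, profile_a.rank, a, b, "III"))
    return records


def spearman_r2(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation squared, with its two-sided p-value.

    Average ranks break ties.  For n <= 9 the p-value is exact (enumeration
    of all rank permutations); for larger n the usual t approximation is
    used.  Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    n = len(x)
    if n <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.array(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho * rho, p


def rank_concordance(
    profile_a: AbundanceProfile, profile_b: AbundanceProfile
) -> tuple[float, float, int]:
    """rho^2 and p over taxa shared by both profiles (group I); returns
    (rho2, p, n_shared)."""
    shared = sorted(profile_a.taxa & profile_b.taxa)
    if len(shared) < 3:
        return float("nan"), float("nan"), len(shared)
    a = profile_a.abundances
    b = profile_b.abundances
    r2, p = spearman_r2([a[t] for t in shared], [b[t] for t in shared])
    return r2, p, len(shared)


@dataclass
class VennCounts:
    shared: int
    only_a: int
    only_b: int
    shared_read_fraction_a: float = float("nan")
    shared_read_fraction_b: float = float("nan")


def venn_counts(
    taxa_a: set[str],
    taxa_b: set[str],
    profile_a: Optional[AbundanceProfile] = None,
    profile_b: Optional[AbundanceProfile] = None,
) -> VennCounts:
    """Shared / A-only / B-only taxon counts; when profiles are supplied,
    also the fraction of each sample's labelled reads carried by shared
    taxa."""
    shared = taxa_a & taxa_b

    def frac(profile: Optional[AbundanceProfile]) -> float:
        if profile is None:
            return float("nan")
        lab = profile.labelled_reads
        if not lab:
            return float("nan")
        return sum(c for t, c in profile.counts.items() if t in shared) / lab

    return VennCounts(
        len(shared),
        len(taxa_a - taxa_b),
        len(taxa_b - taxa_a),
        frac(profile_a),
        frac(profile_b),
    )
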