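"""Best-hit phylotyping of long reads and spike-in accuracy assessment.

Reads are assigned by aligning locally against every reference under the
(1, 1, 1, 1) scheme and keeping the highest-scoring hit — taxonomy-
supervised analysis that bins reads directly without OTU clustering.  Equal
best scores are resolved by truncating the lineage to the lowest common
ancestor of the tied references.  Platform accuracy is estimated from the
spike-in control: pooled matches / (matches + mismatches + insertions +
deletions) over reads spanning at least 80% of the control reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib

from .align import AlignmentResult, ScoringScheme, align_local
from .seqio import SeqRecord
from .synth import ReferenceDB
from .taxonomy import Lineage, lowest_common_ancestor

logger = logging.getLogger(__name__)


@dataclass
class TaxonAssignment:
    read_id: str
    lineage: Lineage
    ref_id: str
    score: int
    tie_count: int = 1
    query_cover: float = 0.0


@dataclass
class AccuracyStats:
    """Pooled alignment-column tallies and the rates derived from them.

    All four rates share the denominator matches + mismatches + insertions
    + deletions, so accuracy + mismatch_rate + insertion_rate +
    deletion_rate == 1 exactly.
    """

    n_reads_used: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int

    @property
    def total_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def accuracy(self) -> float:
        return self.matches / self.total_columns

    @property
    def mismatch_rate(self) -> float:
        return self.mismatches / self.total_columns

    @property
    def insertion_rate(self) -> float:
        return self.insertions / self.total_columns

    @property
    def deletion_rate(self) -> float:
        return self.deletions / self.total_columns

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    def as_dict(self) -> dict:
        return {
            "n_reads_used": self.n_reads_used,
            "matches": self.matches,
            "mismatches": self.mismatches,
            "insertions": self.insertions,
            "deletions": self.deletions,
            "accuracy": self.accuracy,
            "mismatch_rate": self.mismatch_rate,
            "insertion_rate": self.insertion_rate,
            "deletion_rate": self.deletion_rate,
            "error_rate": self.error_rate,
        }


class EmptyResultError(RuntimeError):
    pass


def _candidate_ids(
    read: str, db: ReferenceDB, prescreen_margin: Optional[int]
) -> list[str]:
    """Edit-distance prescreen: keep references within `prescreen_margin`
    of the best infix edit distance.  A speed heuristic only — pass
    ``prescreen_margin=None`` for the exact all-against-all scan."""
    if prescreen_margin is None:
        return [r.id for r in db.records]
    dists = []
    for rec in db.records:
        d = edlib.align(read, rec.seq, mode="HW", task="distance")["editDistance"]
        dists.append((d, rec.id))
    best = min(d for d, _ in dists)
    return [rid for d, rid in dists if d <= best + prescreen_margin]


def classify_reads(
    reads: Iterable[SeqRecord],
    db: ReferenceDB,
    scheme: ScoringScheme = ScoringScheme(),
    min_query_cover: float = 0.5,
    prescreen_margin: Optional[int] = 60,
) -> tuple[list[TaxonAssignment], list[str]]:
    """Assign each read to its best-scoring reference.

    Returns (assignments, unassigned read ids).  A read is unassigned when
    its best local alignment covers less than ``min_query_cover`` of the
    read.  On score ties the lineage is the LCA of the tied references and
    ``tie_count`` records how many tied.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    assignments: list[TaxonAssignment] = []
    unassigned: list[str] = []
    taxonomy = db.taxonomy
    for read in reads:
        if not read.seq:
            logger.warning("skipping empty read %s", read.id)
            continue
        best: list[AlignmentResult] = []
        for rid in _candidate_ids(read.seq, db, prescreen_margin):
            res = align_local(read.seq, db.get(rid).seq, scheme, read.id, rid)
            if not best or res.score > best[0].score:
                best = [res]
            elif res.score == best[0].score:
                best.append(res)
        top = best[0]
        if top.query_cover < min_query_cover:
            unassigned.append(read.id)
            continue
        if len(best) == 1:
            lineage = taxonomy[top.ref_id]
        else:
            lineage = lowest_common_ancestor(taxonomy[b.ref_id] for b in best)
        assignments.append(
            TaxonAssignment(
                read_id=read.id,
                lineage=lineage,
                ref_id=top.ref_id,
                score=top.score,
                tie_count=len(best),
                query_cover=top.query_cover,
            )
        )
    return assignments, unassigned


def filter_low_abundance(
    assignments: Sequence[TaxonAssignment], min_reads_per_taxon: int = 2
) -> list[TaxonAssignment]:
    """Discard taxa (deepest assigned lineage) supported by fewer than
    ``min_reads_per_taxon`` reads — the singleton-discard rule."""
    counts: dict[str, int] = {}
    for a in assignments:
        key = a.lineage.format()
        counts[key] = counts.get(key, 0) + 1
    return [a for a in assignments if counts[a.lineage.format()] >= min_reads_per_taxon]


def assess_accuracy(
    control_reads: Sequence[SeqRecord],
    control_ref: SeqRecord,
    scheme: ScoringScheme = ScoringScheme(),
    min_ref_span: float = 0.8,
    span_on: str = "ref",
) -> AccuracyStats:
    """Estimate sequencing accuracy from spike-in control reads.

    Each read is aligned locally to the control; reads whose alignment spans
    less than ``min_ref_span`` of the reference (``span_on='ref'``, default)
    or of the read itself (``span_on='query'``) are excluded.  Counts are
    pooled (micro-averaged) over the surviving reads.
    """
    if not control_reads:
        raise ValueError("no control reads supplied")
    if span_on not in ("ref", "query"):
        raise ValueError("span_on must be 'ref' or 'query'")
    m = x = ins = dels = used = 0
    for read in control_reads:
        res = align_local(read.seq, control_ref.seq, scheme, read.id, control_ref.id)
        cover = res.ref_cover if span_on == "ref" else res.query_cover
        if cover < min_ref_span:
            continue
        used += 1
        m += res.matches
        x += res.mismatches
        ins += res.insertions
        dels += res.deletions
    if used == 0:
        raise EmptyResultError(
            f"no control read passed the {min_ref_span:.0%} span filter"
        )
    return AccuracyStats(used, m, x, ins, dels)
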