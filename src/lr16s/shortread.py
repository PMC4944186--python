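"""Short-read V3–V4 arm: pair joining, quality filtering, greedy 97% OTU
clustering, OTU taxonomy, rarefaction, and even-depth rarefying.

The processing mirrors the classic QIIME-era workflow: paired reads are
merged on their 3' overlap (consensus takes the higher-quality base), joined
reads shorter than 75% of the summed pair length are discarded, reads are
truncated at the first base below Q20 and dropped if less than 75% of their
length survives, and the survivors are clustered de novo by a greedy
centroid algorithm at 97% identity (identity = matches / alignment columns,
so gaps count against identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import ScoringScheme, align_global
from .classify import classify_reads
from .seqio import SeqRecord
from .synth import ReferenceDB, ReferenceRecord
from .taxonomy import Lineage

logger = logging.getLogger(__name__)


@dataclass
class Otu:
    otu_id: str
    centroid: str  # centroid sequence
    members: list[str] = field(default_factory=list)  # read ids
    lineage: Optional[Lineage] = None

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class OtuTable:
    sample_id: str
    otus: list[Otu]

    @property
    def total_count(self) -> int:
        return sum(o.count for o in self.otus)

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def counts(self) -> dict[str, int]:
        return {o.otu_id: o.count for o in self.otus}


# ---------------------------------------------------------------------------
# Pair joining and quality filtering


def join_pairs(
    r1: SeqRecord,
    r2: SeqRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_joined_frac: float = 0.75,
) -> Optional[SeqRecord]:
    """Merge a read pair on the best 3' overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally.  Among admissible overlaps (length >= ``min_overlap``,
    mismatch fraction <= ``max_mismatch_frac``) the one maximizing matched
    length (overlap length minus mismatches) wins, longer overlap breaking
    ties.  At disagreeing positions the higher-quality base is kept.  The
    joined read is rejected when shorter than ``min_joined_frac`` of the
    summed pair length.
    """
    rc2 = r2.reverse_complement()
    best: Optional[tuple[int, int]] = None  # (matched, overlap)
    max_o = min(len(r1), len(rc2))
    for o in range(min_overlap, max_o + 1):
        tail = r1.seq[len(r1) - o :]
        head = rc2.seq[:o]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches / o > max_mismatch_frac:
            continue
        cand = (o - mismatches, o)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    o = best[1]
    off = len(r1) - o
    seq = list(r1.seq)
    q1 = list(r1.qual) if r1.qual is not None else [0] * len(r1)
    q2 = list(rc2.qual) if rc2.qual is not None else [0] * len(rc2)
    qual = list(q1)
    for i in range(o):
        a, b = r1.seq[off + i], rc2.seq[i]
        qa, qb = q1[off + i], q2[i]
        if a == b:
            qual[off + i] = max(qa, qb)
        elif qb > qa:
            seq[off + i] = b
            qual[off + i] = qb
    seq.extend(rc2.seq[o:])
    qual.extend(q2[o:])
    joined = SeqRecord(r1.id.removesuffix("/1"), "".join(seq), qual)
    if len(joined) < min_joined_frac * (len(r1) + len(r2)):
        return None
    return joined


def quality_filter(
    read: SeqRecord, q_threshold: int = 20, min_retained_frac: float = 0.75
) -> Optional[SeqRecord]:
    """Truncate at the first base below ``q_threshold``; keep the read only
    if at least ``min_retained_frac`` of its original length survives."""
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    cut = len(read)
    for i, q in enumerate(read.qual):
        if q < q_threshold:
            cut = i
            break
    if cut < min_retained_frac * len(read):
        return None
    if cut == len(read):
        return read
    return SeqRecord(read.id, read.seq[:cut], read.qual[:cut])


# ---------------------------------------------------------------------------
# Greedy centroid clustering


def cluster_otus(
    reads: Sequence[SeqRecord],
    identity_threshold: float = 0.97,
    scheme: ScoringScheme = ScoringScheme(),
    sample_id: str = "sample",
) -> OtuTable:
    """De novo greedy centroid clustering at the given identity.

    Reads are dereplicated, then processed in decreasing abundance (ties:
    longer first, then lexicographic sequence) — the UCLUST-style canonical
    order, which makes the result invariant to input order.  Each read joins
    the first centroid whose global-alignment identity reaches the
    threshold, else founds a new OTU.
    """
    if not reads:
        raise ValueError("no reads to cluster")
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.seq, []).append(r.id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), -len(kv[0]), kv[0]))
    otus: list[Otu] = []
    for seq, members in ordered:
        placed = False
        for otu in otus:
            res = align_global(seq, otu.centroid, scheme)
            if res.identity >= identity_threshold:
                otu.members.extend(sorted(members))
                placed = True
                break
        if not placed:
            otus.append(Otu(f"otu{len(otus) + 1:04d}", seq, sorted(members)))
    return OtuTable(sample_id, otus)


def assign_otu_taxonomy(
    table: OtuTable,
    db: ReferenceDB,
    scheme: ScoringScheme = ScoringScheme(),
    max_primer_mismatch: int = 2,
    min_query_cover: float = 0.5,
) -> OtuTable:
    """Classify each centroid against the V3–V4 amplicon database.

    References are truncated to their in-silico PCR window before
    alignment, so an OTU inherits exactly the resolution the short amplicon
    affords (possibly an LCA-truncated lineage).  Unassignable centroids get
    a fully empty lineage.
    """
    amplicons = db.amplicons(db.primers.short, max_primer_mismatch)
    if not amplicons:
        raise ValueError("no reference yields a V3-V4 amplicon")
    trimmed = ReferenceDB(
        [
            ReferenceRecord(rid, amp.seq, db.get(rid).lineage)
            for rid, amp in amplicons.items()
        ],
        region_map=db.region_map,
        primers=db.primers,
    )
    centroids = [SeqRecord(o.otu_id, o.centroid) for o in table.otus]
    assignments, unassigned = classify_reads(
        centroids, trimmed, scheme, min_query_cover=min_query_cover
    )
    by_id = {a.read_id: a.lineage for a in assignments}
    for otu in table.otus:
        if otu.otu_id in by_id:
            otu.lineage = by_id[otu.otu_id]
        else:
            otu.lineage = Lineage()
            logger.warning("OTU %s centroid unassignable; empty lineage", otu.otu_id)
    return table


# ---------------------------------------------------------------------------
# Rarefaction


def _flatten(table: OtuTable) -> list[tuple[str, str]]:
    """(otu_id, read_id) pairs in deterministic order."""
    out = []
    for otu in table.otus:
        for rid in otu.members:
            out.append((otu.otu_id, rid))
    return out


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample the table to exactly ``depth`` reads without replacement;
    empty OTUs are dropped."""
    total = table.total_count
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    flat = _flatten(table)
    keep_idx = rng.choice(total, size=depth, replace=False)
    kept: dict[str, list[str]] = {}
    for i in sorted(map(int, keep_idx)):
        otu_id, rid = flat[i]
        kept.setdefault(otu_id, []).append(rid)
    centroid = {o.otu_id: o for o in table.otus}
    otus = [
        Otu(otu_id, centroid[otu_id].centroid, members, centroid[otu_id].lineage)
        for otu_id, members in kept.items()
    ]
    return OtuTable(table.sample_id, otus)


def rarefaction_curve(
    table: OtuTable, depths: Sequence[int], reps: int = 10, seed: int = 0
) -> list[tuple[int, float]]:
    """Mean observed OTU richness at each depth.

    Each replicate draws one random permutation of the reads and reads
    depths prefix-wise from it, so within a replicate the subsamples are
    nested and the curve is monotone non-decreasing — not merely in
    expectation.
    """
    total = table.total_count
    depths = list(depths)
    if any(d1 > d2 for d1, d2 in zip(depths, depths[1:])):
        raise ValueError("depths must be sorted ascending")
    if depths and depths[-1] > total:
        raise ValueError(f"max depth {depths[-1]} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    flat = _flatten(table)
    otu_ids = [oid for oid, _ in flat]
    means = np.zeros(len(depths))
    for _ in range(reps):
        perm = rng.permutation(total)
        seen: set[str] = set()
        k = 0
        for di, d in enumerate(depths):
            while k < d:
                seen.add(otu_ids[int(perm[k])])
                k += 1
            means[di] += len(seen)
    return [(d, means[i] / reps) for i, d in enumerate(depths)]
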