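"""Reference-sequence variant analysis over hypervariable regions.

Closely related taxon references are multiply aligned (optimal pairwise
alignment for two sequences; star-progressive alignment anchored on the
first sequence for more), variant columns are called wherever the residues
disagree (a gap counts as an allele; the minor-allele frequency of a
reported site is always in (0, 0.5]), each site is mapped back to anchor
coordinates and annotated with its V region, and per-region counts are
summarized — including counts inside an amplicon window, which is how the
"species pair indistinguishable by V3–V4 but separable full-length"
phenomenon is quantified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import ScoringScheme, align_global
from .seqio import SeqRecord
from .synth import ReferenceDB, RegionMap, in_silico_pcr

GAP = "-"


@dataclass
class VariantSite:
    column: int  # index into the multiple alignment
    anchor_pos: int  # position on the anchor sequence (0-based)
    alleles: dict[str, int]  # residue (incl. '-') -> count
    minor_allele_frequency: float
    region: str  # V-region label or "inter-region"


# ---------------------------------------------------------------------------
# Multiple alignment


def _pairwise_rows(a: str, b: str, scheme: ScoringScheme) -> tuple[str, str]:
    """Gapped rows of the optimal global alignment of a and b.

    Reconstructed by replaying the deterministic DP traceback through a
    second pass over the alignment: we re-run the aligner and rebuild the
    column string from the operation counts via a fresh traceback walk.
    """
    from .align import _codes, _fill, _traceback  # internal, same cost model

    q = _codes(a, "sequence")
    r = _codes(b, "sequence")
    H, E, F = _fill(q, r, scheme, local=False)
    # walk the same deterministic traceback, but record columns
    i, j = len(q), len(r)
    cols: list[tuple[str, str]] = []
    state = "H"
    mt, mx = scheme.match, scheme.mismatch_cost
    ge = scheme.gap_extend_cost
    while i > 0 or j > 0:
        if state == "H":
            h = int(H[i, j])
            if i > 0 and j > 0:
                s = mt if (q[i - 1] == r[j - 1] and q[i - 1] != 4) else -mx
                if h == int(H[i - 1, j - 1]) + s:
                    cols.append((a[i - 1], b[j - 1]))
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and h == int(E[i, j]):
                state = "E"
                continue
            state = "F"
        elif state == "E":
            cols.append((GAP, b[j - 1]))
            e = int(E[i, j])
            j -= 1
            if j > 0 and e == int(E[i, j]) - ge:
                continue
            state = "H"
        else:  # F
            cols.append((a[i - 1], GAP))
            f = int(F[i, j])
            i -= 1
            if i > 0 and f == int(F[i, j]) - ge:
                continue
            state = "H"
    cols.reverse()
    return "".join(c[0] for c in cols), "".join(c[1] for c in cols)


def align_references(
    seqs: Sequence[SeqRecord], scheme: ScoringScheme = ScoringScheme()
) -> list[str]:
    """Multiple alignment of reference sequences (equal-length gapped rows).

    Two sequences get their optimal global alignment.  More are aligned
    star-progressively: each sequence is aligned to the first (anchor) and
    the pairwise gap patterns are merged, inserting the maximum insertion
    run seen at each anchor position.  Deterministic; adequate for the small
    sets of closely related references this analysis handles.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    anchor = seqs[0].seq
    if len(seqs) == 2:
        r0, r1 = _pairwise_rows(anchor, seqs[1].seq, scheme)
        return [r0, r1]

    pairs = [_pairwise_rows(anchor, s.seq, scheme) for s in seqs[1:]]

    # insertion run lengths relative to the anchor: slot k = before anchor
    # position k (slot len(anchor) = after the last base)
    n = len(anchor)
    max_ins = [0] * (n + 1)
    per_seq_rows: list[tuple[list[str], list[list[str]]]] = []
    for arow, brow in pairs:
        ins_runs: list[list[str]] = [[] for _ in range(n + 1)]
        aligned: list[str] = [GAP] * n  # residue of b at each anchor position
        k = 0  # anchor position
        for ac, bc in zip(arow, brow):
            if ac == GAP:
                ins_runs[k].append(bc)
            else:
                aligned[k] = bc
                k += 1
        for slot in range(n + 1):
            max_ins[slot] = max(max_ins[slot], len(ins_runs[slot]))
        per_seq_rows.append((aligned, ins_runs))

    def build_row(aligned: Optional[list[str]], ins_runs: Optional[list[list[str]]]) -> str:
        out: list[str] = []
        for k in range(n + 1):
            run = ins_runs[k] if ins_runs else []
            out.extend(run)
            out.extend(GAP * (max_ins[k] - len(run)))
            if k < n:
                out.append(aligned[k] if aligned else anchor[k])
        return "".join(out)

    rows = [build_row(None, None)]
    for aligned, ins_runs in per_seq_rows:
        rows.append(build_row(aligned, ins_runs))
    return rows


# ---------------------------------------------------------------------------
# Variant detection


def detect_variants(
    msa: Sequence[str],
    region_map: RegionMap,
    include_gap_columns: bool = True,
) -> list[VariantSite]:
    """Call variant columns of a multiple alignment.

    A column is a variant iff its residues are not all identical; a gap
    counts as an allele (set ``include_gap_columns=False`` to recover
    gap-free counts).  The minor-allele frequency reported is the frequency
    of the second-most-common allele, always in (0, 0.5].  Sites are mapped
    to anchor (first row) coordinates — columns where the anchor is gapped
    inherit the preceding anchored position — and annotated with their V
    region, or "inter-region".
    """
    if len({len(row) for row in msa}) > 1:
        raise ValueError("alignment rows differ in length")
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned rows")
    anchor = msa[0]
    sites: list[VariantSite] = []
    anchor_pos = -1
    for col in range(len(anchor)):
        residues = [row[col] for row in msa]
        if anchor[col] != GAP:
            anchor_pos += 1
        alleles = Counter(residues)
        if len(alleles) == 1:
            continue
        if not include_gap_columns and GAP in alleles:
            continue
        freqs = sorted((c / len(residues) for c in alleles.values()), reverse=True)
        maf = freqs[1]
        region = region_map.region_of(max(anchor_pos, 0)) or "inter-region"
        sites.append(
            VariantSite(col, max(anchor_pos, 0), dict(alleles), maf, region)
        )
    return sites


def count_variants_by_region(
    sites: Sequence[VariantSite],
    region_map: RegionMap,
    window: Optional[tuple[int, int]] = None,
    anchor_length: Optional[int] = None,
) -> dict:
    """Counts per region label, the total, and (optionally) the count of
    sites whose anchor coordinate falls inside ``window`` (half-open)."""
    counts = {lab: 0 for lab in region_map.labels}
    counts["inter-region"] = 0
    for s in sites:
        counts[s.region] = counts.get(s.region, 0) + 1
    out = {"by_region": counts, "total": len(sites)}
    if window is not None:
        start, end = window
        if start < 0 or (anchor_length is not None and end > anchor_length):
            raise ValueError(f"window {window} outside anchor length {anchor_length}")
        out["window"] = [start, end]
        out["in_window"] = sum(1 for s in sites if start <= s.anchor_pos < end)
    return out


def discriminability(
    db: ReferenceDB,
    taxon_pair: tuple[str, str],
    amplicon_window: Optional[tuple[int, int]] = None,
    scheme: ScoringScheme = ScoringScheme(),
    max_primer_mismatch: int = 2,
) -> dict:
    """Can an amplicon window tell two reference taxa apart?

    Aligns the two references, calls variants, and reports whether at least
    one variant site falls inside the window (``True`` means
    distinguishable).  With no window given, the V3–V4 window is located on
    the first (anchor) reference by in-silico PCR with the short primer
    pair, so it adapts to the loaded references.
    """
    try:
        recs = [db.get(t) for t in taxon_pair]
    except KeyError as exc:
        raise ValueError(f"unknown taxon {exc.args[0]!r}") from exc
    if amplicon_window is None:
        anchor = recs[0]
        amp = in_silico_pcr(
            SeqRecord(anchor.id, anchor.seq),
            db.primers.short.fwd,
            db.primers.short.rev,
            max_primer_mismatch,
        )
        if amp is None:
            raise ValueError(f"cannot locate amplicon window on {anchor.id}")
        start = anchor.seq.find(amp.seq)
        amplicon_window = (start, start + len(amp.seq))
    msa = align_references([SeqRecord(r.id, r.seq) for r in recs], scheme)
    sites = detect_variants(msa, db.region_map)
    summary = count_variants_by_region(
        sites, db.region_map, window=amplicon_window, anchor_length=len(recs[0].seq)
    )
    summary["taxa"] = list(taxon_pair)
    summary["distinguishable"] = summary["in_window"] > 0
    return summary
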