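"""Affine-gap pairwise alignment with exact per-column operation counts.

Both a Smith–Waterman-style local aligner (used for read classification and
accuracy assessment) and a Needleman–Wunsch-style global aligner (used for
OTU identity and reference comparison) run under one cost model: match
reward ``+m``, mismatch cost ``x``, and a gap of length ``k`` costing
``open + k * extend``.  The default (1, 1, 1, 1) mirrors the LAST flags
``-q 1 -a 1 -b 1`` used for nanopore read mapping (in LAST, ``-q`` is the
mismatch cost and the match score defaults to +1).

The dynamic program is the full Gotoh recurrence, vectorized row-wise with
numpy.  The horizontal (reference-consuming) gap layer is computed with a
prefix-maximum scan: because the extension cost is linear,

    E[i, j] = max_{k < j} ( H'[i, k] - open - (j - k) * extend )

where ``H'`` excludes states already ending in a horizontal gap (chaining two
horizontal gaps is never better than one longer gap).  This removes the
within-row data dependency and keeps each row a handful of numpy ops.

Tracebacks are deterministic: among equal-scoring moves the aligner prefers
diagonal (match/mismatch) over deletion (reference-consuming gap) over
insertion (query-consuming gap), so operation counts are reproducible.
``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from numba import njit

from .seqio import validate_dna

_NEG = np.int32(-(10**7))

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Match reward and (positive) mismatch/gap costs.

    A gap of length ``k`` costs ``gap_open_cost + k * gap_extend_cost``,
    i.e. the first gap base pays both the opening and one extension.
    """

    match: int = 1
    mismatch_cost: int = 1
    gap_open_cost: int = 1
    gap_extend_cost: int = 1

    def __post_init__(self) -> None:
        for name in ("match", "mismatch_cost", "gap_open_cost", "gap_extend_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def gap_cost(self, length: int) -> int:
        return self.gap_open_cost + length * self.gap_extend_cost if length else 0


@dataclass
class AlignmentResult:
    """Counts of aligned columns by type plus score and coverage.

    ``insertions`` are query bases absent from the reference; ``deletions``
    are reference bases absent from the query.  The identities

        matches + mismatches + insertions == query bases consumed
        matches + mismatches + deletions  == reference bases consumed

    hold for every returned alignment and are re-checked at construction
    time against the score.
    """

    query_id: str
    ref_id: str
    score: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    query_cover: float
    ref_cover: float
    gap_openings: int = 0
    query_start: int = 0
    ref_start: int = 0

    @property
    def total_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        """matches / total alignment columns (gaps count against identity)."""
        n = self.total_columns
        return self.matches / n if n else 0.0


_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c


def _codes(seq: str, what: str) -> np.ndarray:
    validate_dna(seq, context=what)
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int8)


@njit(cache=True)
def _fill_kernel(q, r, mt, mx, go, ge, local, H, E, F):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    H[0, 0] = 0
    for j in range(1, n + 1):
        E[0, j] = max(E[0, j - 1] - ge, H[0, j - 1] - go - ge)
        H[0, j] = 0 if local else E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = max(F[i - 1, 0] - ge, H[i - 1, 0] - go - ge)
        H[i, 0] = 0 if local else F[i, 0]
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = mt if (qi == r[j - 1] and qi != 4) else -mx
            e = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            f = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h


def _fill(q: np.ndarray, r: np.ndarray, sch: ScoringScheme, local: bool):
    """Fill H/E/F matrices (query rows, reference columns) via Gotoh DP."""
    m, n = len(q), len(r)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    E = np.empty((m + 1, n + 1), dtype=np.int32)
    F = np.empty((m + 1, n + 1), dtype=np.int32)
    E[:, 0] = _NEG
    F[0, :] = _NEG
    _fill_kernel(
        q,
        r,
        np.int32(sch.match),
        np.int32(sch.mismatch_cost),
        np.int32(sch.gap_open_cost),
        np.int32(sch.gap_extend_cost),
        local,
        H,
        E,
        F,
    )
    return H, E, F


def _traceback(q, r, H, E, F, sch: ScoringScheme, local: bool, i: int, j: int):
    """Walk back from (i, j); returns counts and consumed spans."""
    mt, mx = sch.match, sch.mismatch_cost
    go, ge = sch.gap_open_cost, sch.gap_extend_cost
    matches = mismatches = ins = dels = gaps = 0
    state = "H"
    end_i, end_j = i, j
    while True:
        if state == "H":
            h = int(H[i, j])
            if local and h == 0:
                break
            if i == 0 and j == 0:
                break
            if i > 0 and j > 0:
                qi, rj = q[i - 1], r[j - 1]
                s = mt if (qi == rj and qi != 4) else -mx
                if h == int(H[i - 1, j - 1]) + s:
                    if s == mt and qi == rj and qi != 4:
                        matches += 1
                    else:
                        mismatches += 1
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and h == int(E[i, j]):
                state = "E"
                continue
            if i > 0 and h == int(F[i, j]):
                state = "F"
                continue
            if not local:
                if i == 0:  # leading deletions along the top edge
                    dels += j
                    gaps += 1
                    j = 0
                    break
                if j == 0:
                    ins += i
                    gaps += 1
                    i = 0
                    break
            raise AssertionError("traceback: no admissible move")
        elif state == "E":
            dels += 1
            e = int(E[i, j])
            j -= 1
            if j > 0 and e == int(E[i, j]) - ge:
                continue
            gaps += 1
            state = "H"
        else:  # F
            ins += 1
            f = int(F[i, j])
            i -= 1
            if i > 0 and f == int(F[i, j]) - ge:
                continue
            gaps += 1
            state = "H"
    return matches, mismatches, ins, dels, gaps, i, j, end_i, end_j


def _align(query_id, ref_id, query, ref, scheme, local) -> AlignmentResult:
    if not query or not ref:
        raise AlignmentError("cannot align empty sequences")
    q = _codes(query, "query")
    r = _codes(ref, "reference")
    H, E, F = _fill(q, r, scheme, local)
    if local:
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        best = int(H[i, j])
        if best <= 0:
            return AlignmentResult(query_id, ref_id, 0, 0, 0, 0, 0, 0.0, 0.0)
    else:
        i, j = len(q), len(r)
        best = int(H[i, j])
    m, x, ins, dels, gaps, si, sj, ei, ej = _traceback(
        q, r, H, E, F, scheme, local, i, j
    )
    res = AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        score=best,
        matches=m,
        mismatches=x,
        insertions=ins,
        deletions=dels,
        query_cover=(ei - si) / len(q),
        ref_cover=(ej - sj) / len(r),
        gap_openings=gaps,
        query_start=si,
        ref_start=sj,
    )
    # internal consistency: rebuilt score must equal the DP optimum
    rebuilt = (
        scheme.match * m
        - scheme.mismatch_cost * x
        - gaps * scheme.gap_open_cost
        - (ins + dels) * scheme.gap_extend_cost
    )
    if rebuilt != best:
        raise AssertionError(
            f"traceback score {rebuilt} != DP score {best} "
            f"({query_id} vs {ref_id})"
        )
    return res


def align_local(
    query: str,
    ref: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment under the affine cost model.

    The score is always >= 0; unrelated sequences may yield the empty
    alignment (score 0, all counts 0).
    """
    return _align(query_id, ref_id, query, ref, scheme, local=True)


def align_global(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentResult:
    """Optimal end-to-end (Needleman–Wunsch) alignment; covers both inputs
    fully (query_cover == ref_cover == 1)."""
    return _align(query_id, ref_id, a, b, scheme, local=False)
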