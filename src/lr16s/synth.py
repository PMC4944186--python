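"""Synthetic 16S-like references, amplicons, and simulated reads.

This module is the stand-in for the study system: a mouse-gut-like
community sequenced two ways.  It generates

* a reference database with GreenGenes-style 7-rank lineages, built from a
  single random root whose nine hypervariable intervals (V1–V9) diverge
  between genera and between species while conserved positions stay
  identical across all records;
* in-silico PCR amplicons from degenerate (IUPAC) primers — the V3–V4 pair
  printed for the short-read assay and a configurable near-full-length pair;
* long noisy reads under a per-aligned-column error process (substitution /
  insertion / deletion rates), optionally with concatemer artifacts;
* short 2x250 bp read pairs with Phred-style qualities and quality-driven
  substitution errors;
* spike-in control reads from a fixed packaged control sequence (the
  stand-in for the lambda-phage internal control).

All randomness flows from a single per-call seed; identical seeds give
byte-identical output.  Truth tables are returned (and written) as sidecar
mappings, never encoded in read ids.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .seqio import SeqRecord, reverse_complement
from .taxonomy import Lineage

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# IUPAC

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(primer: str) -> str:
    return primer.translate(_IUPAC_COMPLEMENT)[::-1]


def _check_primer(primer: str) -> None:
    bad = set(primer.upper()) - set(IUPAC)
    if bad:
        raise ParameterError(f"primer {primer!r} has non-IUPAC characters {sorted(bad)}")


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RegionInterval:
    label: str
    start: int  # 0-based, half-open
    end: int


@dataclass(frozen=True)
class RegionMap:
    """Ordered, non-overlapping V-region intervals on reference coordinates."""

    intervals: tuple[RegionInterval, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in self.intervals:
            if not (0 <= iv.start < iv.end):
                raise ParameterError(f"bad interval {iv}")
            if iv.start < prev_end:
                raise ParameterError("region intervals overlap or are unsorted")
            prev_end = iv.end

    @property
    def span(self) -> int:
        return self.intervals[-1].end if self.intervals else 0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)

    def region_of(self, pos: int) -> Optional[str]:
        for iv in self.intervals:
            if iv.start <= pos < iv.end:
                return iv.label
        return None

    def positions(self, labels: Optional[Iterable[str]] = None) -> np.ndarray:
        wanted = set(labels) if labels is not None else None
        out: list[np.ndarray] = []
        for iv in self.intervals:
            if wanted is None or iv.label in wanted:
                out.append(np.arange(iv.start, iv.end))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


#: Conventional E. coli-numbering V1–V9 boundaries (0-based, half-open).
DEFAULT_REGION_MAP = RegionMap(
    tuple(
        RegionInterval(lab, s, e)
        for lab, s, e in [
            ("V1", 68, 99),
            ("V2", 136, 242),
            ("V3", 338, 533),
            ("V4", 576, 682),
            ("V5", 821, 879),
            ("V6", 985, 1043),
            ("V7", 1116, 1173),
            ("V8", 1243, 1294),
            ("V9", 1434, 1465),
        ]
    )
)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both given in primer orientation."""

    fwd: str
    rev: str

    def __post_init__(self) -> None:
        _check_primer(self.fwd)
        _check_primer(self.rev)


@dataclass(frozen=True)
class PrimerSet:
    """The two assays' primer pairs plus their planted template sites.

    ``*_start`` give the 0-based template positions where concrete
    realizations of the primers (forward) and their reverse complements
    (reverse) are written into every generated reference, so in-silico PCR
    always succeeds on synthetic references.
    """

    full_length: PrimerPair
    short: PrimerPair
    fl_fwd_start: int = 8
    fl_rev_site_start: int = 1390  # site of revcomp(full-length rev primer)
    sr_fwd_start: int = 340
    sr_rev_site_start: int = 785


#: V3–V4 primer cores used by the short-read assay.
V3V4_PRIMERS = PrimerPair(fwd="CCTACGGGNGGCWGCAG", rev="GACTACHVGGGTATCTAATCC")

#: Near-full-length pair (Klindworth et al. S-D-Bact-0008-c-S-20 /
#: S-D-Bact-1391-a-A-17); the study names these primers without printing
#: their sequences, so they are configurable defaults.
FULL_LENGTH_PRIMERS = PrimerPair(fwd="AGRGTTYGATYMTGGCTCAG", rev="GACGGGCGGTGTGTRCA")

DEFAULT_PRIMER_SET = PrimerSet(full_length=FULL_LENGTH_PRIMERS, short=V3V4_PRIMERS)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-aligned-column substitution / insertion / deletion probabilities.

    Expected alignment accuracy under the profile is
    ``1 - (p_sub + p_ins + p_del)``.
    """

    p_sub: float
    p_ins: float
    p_del: float

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.p_sub + self.p_ins + self.p_del >= 1.0:
            raise ParameterError("error probabilities must sum to < 1")

    @property
    def expected_accuracy(self) -> float:
        return 1.0 - (self.p_sub + self.p_ins + self.p_del)


#: The study's alignment-estimated nanopore error decomposition.
NANOPORE_PROFILE = ErrorProfile(p_sub=0.090, p_ins=0.064, p_del=0.050)

ERROR_FREE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass
class Community:
    """Relative abundances over reference ids; normalized to sum to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ParameterError("community is empty")
        if any(w < 0 for w in self.weights.values()):
            raise ParameterError("community weights must be non-negative")
        total = float(sum(self.weights.values()))
        if total <= 0:
            raise ParameterError("community weights sum to zero")
        self.weights = {k: v / total for k, v in self.weights.items()}

    @property
    def ids(self) -> list[str]:
        return sorted(self.weights)

    def probabilities(self) -> np.ndarray:
        return np.array([self.weights[i] for i in self.ids])

    def validate_against(self, db: "ReferenceDB") -> None:
        missing = set(self.weights) - {r.id for r in db.records}
        if missing:
            raise ParameterError(f"community ids not in reference DB: {sorted(missing)}")


@dataclass
class ReferenceRecord:
    id: str
    seq: str
    lineage: Lineage

    def as_seqrecord(self) -> SeqRecord:
        return SeqRecord(self.id, self.seq)


@dataclass
class ReferenceDB:
    records: list[ReferenceRecord]
    region_map: RegionMap = DEFAULT_REGION_MAP
    primers: PrimerSet = DEFAULT_PRIMER_SET

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ParameterError("duplicate reference ids")
        if any(not r.seq for r in self.records):
            raise ParameterError("empty reference sequence")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rid: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def taxonomy(self) -> dict[str, Lineage]:
        return {r.id: r.lineage for r in self.records}

    def amplicons(self, pair: PrimerPair, max_mismatch: int = 2) -> dict[str, SeqRecord]:
        """In-silico PCR of every reference; references without both primer
        sites are omitted (with a logged warning)."""
        out: dict[str, SeqRecord] = {}
        for rec in self.records:
            amp = in_silico_pcr(rec.as_seqrecord(), pair.fwd, pair.rev, max_mismatch)
            if amp is None:
                logger.warning("no amplicon for reference %s", rec.id)
            else:
                out[rec.id] = amp
        return out


# ---------------------------------------------------------------------------
# In-silico PCR

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _primer_matches(template: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where `primer` (IUPAC) matches with <= max_mismatch."""
    sets = [set(IUPAC[c]) for c in primer.upper()]
    k = len(primer)
    hits: list[int] = []
    for start in range(0, len(template) - k + 1):
        mism = 0
        for off, allowed in enumerate(sets):
            if template[start + off] not in allowed:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def in_silico_pcr(
    record: SeqRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
) -> Optional[SeqRecord]:
    """Extract the amplicon delimited by a degenerate primer pair.

    The forward primer is searched on the forward strand (leftmost hit wins);
    the reverse primer, given in primer orientation, is searched as its
    reverse complement downstream of the forward site (rightmost hit wins).
    Returns the inclusive span from the forward-primer start to the end of
    the reverse site, or ``None`` when either site is absent or the sites
    overlap.
    """
    _check_primer(fwd_primer)
    _check_primer(rev_primer)
    fwd_hits = _primer_matches(record.seq, fwd_primer, max_mismatch)
    if not fwd_hits:
        return None
    fstart = fwd_hits[0]
    rc_rev = iupac_reverse_complement(rev_primer)
    rev_hits = [h for h in _primer_matches(record.seq, rc_rev, max_mismatch) if h >= fstart]
    if not rev_hits:
        return None
    rstart = rev_hits[-1]
    end = rstart + len(rc_rev)
    if end - fstart < len(fwd_primer) + len(rev_primer):
        return None
    return SeqRecord(f"{record.id}|amplicon", record.seq[fstart:end])


# ---------------------------------------------------------------------------
# Reference-database generator


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    """Pick one concrete base per IUPAC code (seeded, deterministic)."""
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in primer.upper())


def _mutate(codes: np.ndarray, positions: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if len(positions) == 0 or rate == 0.0:
        return
    hit = positions[rng.random(len(positions)) < rate]
    codes[hit] = (codes[hit] + rng.integers(1, 4, size=len(hit))) % 4


def generate_reference_db(
    n_genera: int,
    species_per_genus: int,
    length: int = 1500,
    per_region_divergence: float | Mapping[str, float] = 0.02,
    between_genus_divergence: float = 0.05,
    seed: int = 0,
    region_map: RegionMap = DEFAULT_REGION_MAP,
    primers: PrimerSet = DEFAULT_PRIMER_SET,
) -> ReferenceDB:
    """Generate a 16S-like reference database with known structure.

    A single random root sequence supplies the conserved backbone.  Genus
    ancestors substitute bases only inside V-region intervals at
    ``between_genus_divergence``; each species then substitutes its genus
    ancestor inside V regions at the per-region rates.  Concrete primer
    realizations are written verbatim into every record (excluded from
    mutation) so in-silico PCR always finds them.  Deterministic given seed.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ParameterError("need at least one genus and one species per genus")
    if length < region_map.span:
        raise ParameterError(
            f"length {length} shorter than region map span {region_map.span}"
        )
    rates: dict[str, float]
    if isinstance(per_region_divergence, Mapping):
        rates = {lab: float(per_region_divergence.get(lab, 0.0)) for lab in region_map.labels}
    else:
        rates = {lab: float(per_region_divergence) for lab in region_map.labels}
    for lab, rate in list(rates.items()) + [("between_genus", between_genus_divergence)]:
        if rate > 0.75:
            raise ParameterError(f"divergence rate {rate} for {lab} exceeds 0.75 (saturation)")
        if rate < 0:
            raise ParameterError(f"negative divergence rate for {lab}")

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length).astype(np.int8)

    # plant concrete primer realizations
    planted: list[tuple[int, str]] = [
        (primers.fl_fwd_start, _resolve_iupac(primers.full_length.fwd, rng)),
        (
            primers.fl_rev_site_start,
            reverse_complement(_resolve_iupac(primers.full_length.rev, rng)),
        ),
        (primers.sr_fwd_start, _resolve_iupac(primers.short.fwd, rng)),
        (
            primers.sr_rev_site_start,
            reverse_complement(_resolve_iupac(primers.short.rev, rng)),
        ),
    ]
    code_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    primer_positions: set[int] = set()
    for start, site in planted:
        if start < 0 or start + len(site) > length:
            raise ParameterError("primer site outside reference length")
        for off, base in enumerate(site):
            root[start + off] = code_of[base]
            primer_positions.add(start + off)

    mutable_by_region = {
        lab: np.array(
            [p for p in region_map.positions([lab]) if p not in primer_positions],
            dtype=int,
        )
        for lab in region_map.labels
    }
    all_v_positions = (
        np.concatenate([v for v in mutable_by_region.values() if len(v)])
        if any(len(v) for v in mutable_by_region.values())
        else np.empty(0, dtype=int)
    )

    records: list[ReferenceRecord] = []
    for g in range(n_genera):
        genus_seq = root.copy()
        _mutate(genus_seq, all_v_positions, between_genus_divergence, rng)
        for s in range(species_per_genus):
            sp_seq = genus_seq.copy()
            for lab in region_map.labels:
                _mutate(sp_seq, mutable_by_region[lab], rates[lab], rng)
            genus_name = f"G{g + 1}"
            species_name = f"{genus_name}_S{s + 1}"
            lineage = Lineage(
                (
                    "Bacteria",
                    f"P{g // 4 + 1}",
                    f"C{g // 3 + 1}",
                    f"O{g // 2 + 1}",
                    f"F{g + 1}",
                    genus_name,
                    species_name,
                )
            )
            records.append(
                ReferenceRecord(f"ref_{species_name}", _decode(sp_seq), lineage)
            )
    return ReferenceDB(records, region_map=region_map, primers=primers)


# ---------------------------------------------------------------------------
# Read simulators


def _corrupt(tpl: np.ndarray, profile: ErrorProfile, rng: np.random.Generator) -> np.ndarray:
    """Apply the per-aligned-column error process to template codes.

    Each alignment column is independently an insertion (emits a uniform
    random base, consumes no template), a deletion (consumes a template base,
    emits nothing), a substitution (consumes and emits one of the 3 other
    bases) or a match, with the profile's probabilities.  Columns are drawn
    until the template is exhausted.
    """
    L = len(tpl)
    p_ins, p_del, p_sub = profile.p_ins, profile.p_del, profile.p_sub
    if L == 0:
        return np.empty(0, dtype=np.int8)
    chunks: list[np.ndarray] = []
    consumed = 0
    est = max(32, int(L / max(1e-9, 1.0 - p_ins) * 1.2) + 32)
    while consumed < L:
        u = rng.random(est)
        ops = np.full(est, 3, dtype=np.int8)  # match
        ops[u < p_ins + p_del + p_sub] = 2  # substitution
        ops[u < p_ins + p_del] = 1  # deletion
        ops[u < p_ins] = 0  # insertion
        consume = ops != 0
        ccum = np.cumsum(consume)
        if consumed + ccum[-1] >= L:
            k = int(np.searchsorted(ccum, L - consumed))
            ops = ops[: k + 1]
            chunks.append(ops)
            consumed = L
        else:
            chunks.append(ops)
            consumed += int(ccum[-1])
    opa = np.concatenate(chunks)
    consume = opa != 0
    tpl_idx = np.cumsum(consume) - 1
    bases = np.empty(len(opa), dtype=np.int8)
    match_mask = opa == 3
    bases[match_mask] = tpl[tpl_idx[match_mask]]
    sub_mask = opa == 2
    n_sub = int(sub_mask.sum())
    bases[sub_mask] = (tpl[tpl_idx[sub_mask]] + rng.integers(1, 4, size=n_sub)) % 4
    ins_mask = opa == 0
    bases[ins_mask] = rng.integers(0, 4, size=int(ins_mask.sum()))
    return bases[opa != 1]


_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in {"A": 0, "C": 1, "G": 2, "T": 3}.items():
    _ENCODE_LUT[ord(_b)] = _c


def _encode_seq(seq: str) -> np.ndarray:
    codes = _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ParameterError("template contains non-ACGT characters")
    return codes


LONG_READ_QUALITY = 10  # constant placeholder Phred score for long reads


def simulate_long_reads(
    db: ReferenceDB,
    community: Community,
    n_reads: int,
    profile: ErrorProfile = NANOPORE_PROFILE,
    p_concat: float = 0.0,
    seed: int = 0,
    amplicons: Optional[dict[str, SeqRecord]] = None,
) -> tuple[list[SeqRecord], dict[str, tuple[str, ...]]]:
    """Simulate noisy long reads of full-length amplicons.

    Sources are drawn from the community; each amplicon is corrupted by the
    per-column error process.  With probability ``p_concat`` a read is the
    concatenation of two independently drawn, independently corrupted
    amplicons (the hairpin-adapter concatemer artifact).  Returns the reads
    and a truth table mapping read id to the tuple of source reference ids.
    """
    community.validate_against(db)
    if amplicons is None:
        amplicons = db.amplicons(db.primers.full_length, max_mismatch=2)
    missing = [i for i in community.ids if i not in amplicons]
    if missing:
        raise ParameterError(f"no full-length amplicon for community ids {missing}")
    rng = np.random.default_rng(seed)
    ids = community.ids
    probs = community.probabilities()
    templates = {i: _encode_seq(amplicons[i].seq) for i in ids}
    reads: list[SeqRecord] = []
    truth: dict[str, tuple[str, ...]] = {}
    for k in range(n_reads):
        sources = [ids[rng.choice(len(ids), p=probs)]]
        if p_concat > 0 and rng.random() < p_concat:
            sources.append(ids[rng.choice(len(ids), p=probs)])
        parts = [_corrupt(templates[s], profile, rng) for s in sources]
        codes = np.concatenate(parts)
        rid = f"lr{k:06d}"
        seq = _decode(codes % 4) if len(codes) else "N"
        reads.append(SeqRecord(rid, seq, [LONG_READ_QUALITY] * len(seq)))
        truth[rid] = tuple(sources)
    return reads, truth


def control_sequence(length: int = 1400, seed: int = 101) -> SeqRecord:
    """The packaged spike-in control: a fixed seeded random sequence standing
    in for the lambda-phage internal control amplicon."""
    rng = np.random.default_rng(seed)
    return SeqRecord("control", _decode(rng.integers(0, 4, size=length).astype(np.int8)))


def simulate_control_reads(
    control: SeqRecord,
    n: int,
    profile: ErrorProfile = NANOPORE_PROFILE,
    seed: int = 0,
) -> list[SeqRecord]:
    """Reads from the single control template (no concatemers)."""
    if n < 1:
        raise ParameterError("need at least one control read")
    rng = np.random.default_rng(seed)
    tpl = _encode_seq(control.seq)
    reads = []
    for k in range(n):
        codes = _corrupt(tpl, profile, rng)
        seq = _decode(codes % 4) if len(codes) else "N"
        reads.append(SeqRecord(f"ctl{k:06d}", seq, [LONG_READ_QUALITY] * len(seq)))
    return reads


#: (q_high, q_low, p_lowq_tail) defaults for the short-read quality model.
DEFAULT_QUALITY_MODEL = (38, 10, 0.10)

_TAIL_MEAN = 15  # mean geometric low-quality tail length (bases)


def simulate_short_read_pairs(
    db: ReferenceDB,
    community: Community,
    n_pairs: int,
    read_len: int = 250,
    quality_model: tuple[int, int, float] = DEFAULT_QUALITY_MODEL,
    seed: int = 0,
    amplicons: Optional[dict[str, SeqRecord]] = None,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], dict[str, str]]:
    """Simulate 2 x read_len paired reads of the V3–V4 amplicons.

    R1 is the first ``read_len`` bases of the amplicon; R2 the reverse
    complement of the last ``read_len`` bases.  Per-base qualities are
    ``q_high`` except for a geometric low-quality 3' tail (quality
    ``q_low``) entered with probability ``p_lowq_tail`` per read;
    substitution errors are drawn per base at rate ``10**(-q/10)``.
    Sources whose amplicon is shorter than ``read_len`` are skipped with a
    logged warning.
    """
    community.validate_against(db)
    if amplicons is None:
        amplicons = db.amplicons(db.primers.short, max_mismatch=2)
    q_high, q_low, p_tail = quality_model
    usable: list[str] = []
    for i in community.ids:
        if i not in amplicons:
            logger.warning("skipping %s: no V3-V4 amplicon", i)
        elif len(amplicons[i]) < read_len:
            logger.warning(
                "skipping %s: amplicon length %d < read length %d",
                i, len(amplicons[i]), read_len,
            )
        else:
            usable.append(i)
    if not usable:
        raise ParameterError("no community source has a usable amplicon")
    weights = np.array([community.weights[i] for i in usable])
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    fwd = {i: _encode_seq(amplicons[i].seq) for i in usable}
    rev = {i: _encode_seq(reverse_complement(amplicons[i].seq)) for i in usable}

    def one_mate(tpl: np.ndarray) -> SeqRecord:
        codes = tpl[:read_len].copy()
        qual = np.full(read_len, q_high, dtype=int)
        if p_tail > 0 and rng.random() < p_tail:
            tail = int(min(read_len, rng.geometric(1.0 / _TAIL_MEAN)))
            qual[read_len - tail :] = q_low
        err_p = 10.0 ** (-qual / 10.0)
        hit = rng.random(read_len) < err_p
        n_hit = int(hit.sum())
        if n_hit:
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=n_hit)) % 4
        return SeqRecord("tmp", _decode(codes), list(map(int, qual)))

    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    truth: dict[str, str] = {}
    for k in range(n_pairs):
        src = usable[rng.choice(len(usable), p=weights)]
        r1 = one_mate(fwd[src])
        r2 = one_mate(rev[src])
        base = f"sr{k:06d}"
        r1.id = f"{base}/1"
        r2.id = f"{base}/2"
        pairs.append((r1, r2))
        truth[base] = src
    return pairs, truth


# ---------------------------------------------------------------------------
# Truth-table sidecars


def write_truth(path: str | os.PathLike, truth: Mapping[str, Sequence[str] | str]) -> None:
    with open(path, "w") as fh:
        for rid, src in truth.items():
            srcs = src if isinstance(src, str) else ",".join(src)
            fh.write(f"{rid}\t{srcs}\n")


def read_truth(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            rid, srcs = line.rstrip("\n").split("\t")
            out[rid] = tuple(srcs.split(","))
    return out
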