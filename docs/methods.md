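# Methods

`lr16s` re-implements, as a self-contained simulation-driven pipeline, a
two-platform 16S rRNA community-profiling analysis: near-full-length (~1.5 kb)
noisy long reads phylotyped by best-hit alignment against a taxonomic
reference, and short V3–V4 paired reads processed through the classic
join → quality-filter → 97%-OTU workflow, with cross-platform concordance
statistics and a hypervariable-region variant analysis that explains where
the short amplicon loses species-level resolution.

## Synthetic reference database

Real studies classify against a curated database (e.g. GreenGenes 13_8)
using reads from biological samples; neither is redistributable here, so the
`synth` module generates both sides with known ground truth.

A single random root sequence (default length 1500 nt, uniform base
composition) supplies the conserved backbone shared by all references. Nine
intervals play the role of the hypervariable regions V1–V9, using the
conventional E. coli-numbering boundaries (0-based, half-open; shipped as an
overridable `RegionMap`). Genus ancestors substitute bases only inside
V intervals at `between_genus_divergence` (default 0.05 per site); each
species then substitutes its genus ancestor inside V intervals at per-region
rates (default 0.02 per site, configurable per region — setting the rate of
all but V1–V2 to zero constructs species pairs that the V3–V4 amplicon
cannot separate). Conserved (non-V) positions are identical across every
record. Reference evolution is substitution-only; indels between references
are out of scope, which keeps variant columns exactly addressable in root
coordinates.

Concrete realizations of the primers are written verbatim into every
record (and masked from mutation), so in-silico PCR always succeeds on
synthetic references:

| primer | sequence | planted site |
|---|---|---|
| full-length fwd (S-D-Bact-0008-c-S-20) | `AGRGTTYGATYMTGGCTCAG` | 8 |
| full-length rev (S-D-Bact-1391-a-A-17) | `GACGGGCGGTGTGTRCA` | revcomp at 1390 |
| V3–V4 fwd core | `CCTACGGGNGGCWGCAG` | 340 |
| V3–V4 rev core | `GACTACHVGGGTATCTAATCC` | revcomp at 785 |

With the default layout the full-length amplicon is 1399 nt and the V3–V4
amplicon 466 nt (the field's usual "~469 bp" target). The full-length pair
is a configurable default (the standard broad-range sequences), since
full-length assays name rather than print their primers.

In-silico PCR is IUPAC-aware: the leftmost forward-primer site and the
rightmost reverse-complemented reverse site downstream of it are located
with at most `max_mismatch` mismatches; the amplicon is the inclusive span.

Lineages are synthetic seven-rank labels (`k__Bacteria; …; g__G2; s__G2_S3`)
with genera grouped into shared families/orders/classes/phyla so that
coarser ranks aggregate several genera.

## Long-read error model

Long reads are simulated by a **per-aligned-column** process: each alignment
column is independently an insertion (probability `p_ins`, emits a uniform
random base, consumes no template), a deletion (`p_del`, consumes a template
base, emits nothing), a substitution (`p_sub`, uniform over the three other
bases) or a match, drawn until the template is exhausted. The default
profile is the nanopore-like decomposition (sub 0.090, ins 0.064,
del 0.050), i.e. an expected column accuracy of 79.6%. Under this process
the exact expected read length is `L (1 − p_del) / (1 − p_ins)` (≈ 1.5%
longer than the template; the familiar first-order form
`L (1 − p_del + p_ins)` agrees to ~0.1%).

There is no context-dependent (homopolymer) error structure and no quality
model for long reads (a constant placeholder Phred 10 is emitted): the rates
being emulated are aggregate, alignment-estimated quantities. Concatemer
artifacts — reads that are two independently drawn, independently corrupted
amplicons back to back — occur with probability `p_concat` (default 0.02 in
the pipeline config). Truth tables are sidecar TSVs keyed by read id, never
encoded in the ids themselves.

### Known bias: realignment parsimony

Accuracy assessment re-aligns each control read optimally and tallies
columns, which is *not* the inverse of the generator: the optimal alignment
is more parsimonious than the generative one. Whenever an insertion lands
within a few columns of a deletion, re-explaining the segment diagonally
(as substitutions/matches) costs less under the (1, 1, 1, 1) scheme than
paying two gaps, so the measured insertion and deletion fractions sit
below the generative rates and the measured accuracy and mismatch fraction
above them. This is a property of optimal affine-gap alignment at ~20%
error, not of this implementation (whose scores are verified exactly
against a brute-force DP oracle in the test suite); the acceptance script
reports the honestly measured values.

## Short-read model

R1 is the first `read_len` (default 250) bases of the V3–V4 amplicon and R2
the reverse complement of the last `read_len` bases. Per-base qualities are
`q_high` (default 38) except for a geometric low-quality 3′ tail (mean 15
bases, quality `q_low` = 10) entered with probability 0.10 per read;
substitution errors are drawn per base at the Phred rate `10^(−q/10)`.
There is no short-read indel model and no chimera simulation beyond the
long-read concatemers.

## Alignment

Both aligners implement the full Gotoh affine-gap recurrence (no
seed-and-extend heuristics), with match +1, mismatch −1 and a gap of length
k costing 1 + k — the published LAST flags `-q 1 -a 1 -b 1` read as LAST
defines them (`-q` is the mismatch *cost*; match defaults to +1). `N` never
matches anything, including another `N`. The fill is a numba-compiled
kernel; traceback is deterministic, preferring diagonal over deletion
(reference gap) over insertion (query gap) among equal-scoring moves, so
operation counts are reproducible. Each result carries exact match /
mismatch / insertion / deletion column counts, satisfying

    matches + mismatches + insertions = query bases consumed
    matches + mismatches + deletions  = reference bases consumed

and the score identity, all re-checked at construction.

## Classification and accuracy

Each long read is aligned locally against every reference; the best score
wins. Reads whose best alignment covers < 50% of the read (default) are
unassigned. Score ties are resolved by truncating to the lowest common
ancestor of the tied lineages — reproducible and conservative. Taxa
supported by fewer than 2 reads are discarded (the singleton rule). An
optional edit-distance prescreen (edlib, infix mode) skips references whose
edit distance exceeds the best by > 60 before running the exact DP; it is a
speed heuristic only and `prescreen_margin=None` restores the exhaustive
scan (the suite checks both routes agree).

Accuracy pools column counts over control reads whose alignment spans at
least 80% of the control reference (`span_on="ref"`; the read-side filter
is available by flag), so `accuracy + mismatch + insertion + deletion = 1`
holds exactly by construction.

## Short-read arm

Pairs are merged on the overlap maximizing matched length (minimum 10 nt,
mismatch fraction ≤ 0.10; the higher-quality base wins disagreements);
joins shorter than 75% of the summed pair length are discarded. Reads are
truncated at the first base below Q20 and kept only if ≥ 75% of the length
survives. Survivors are dereplicated and clustered greedily in decreasing
abundance (ties: longer, then lexicographic — a canonical order that makes
clustering input-order invariant); a read joins the first centroid with
global-alignment identity ≥ 0.97, where identity = matches / alignment
columns (gaps count against identity). OTU centroids are classified against
the references *truncated to their V3–V4 windows*, so an OTU inherits
exactly the resolution the short amplicon affords. Chimera removal and
closed-reference pre-clustering are intentionally omitted: the simulator
produces no chimeras.

Rarefying subsamples the table without replacement to an exact even depth.
Rarefaction curves draw one permutation per replicate and read depths
prefix-wise, so subsamples are nested and every replicate's curve is
monotone non-decreasing, not merely the mean.

## Comparison statistics

Per-rank profiles count reads by lineage truncated at the rank; unlabelled
reads are excluded from abundances but counted in the rank-coverage
denominator. Detection groups follow the convention I = both platforms,
II = nanopore-only, III = short-read-only. log2 fold-changes are computed
on relative abundances, only for group I (no pseudocounts), and |log2 FC| >
1 flags a significant deviation. Spearman correlation is reported as rho²
with an exact permutation p-value for n ≤ 9 pairs and the t approximation
otherwise. No multiple-testing correction is applied.

## Variant analysis

Two references get their optimal global alignment; larger sets are aligned
star-progressively against the first sequence as anchor (adequate for the
handfuls of closely related references this analysis targets, and
dependency-free — a deliberate simplification of guide-tree progressive
alignment). A column is a variant iff its residues are not all identical;
gaps count as alleles (a flag recovers gap-free counts). The reported
minor-allele frequency is the second-most-common allele's frequency, always
in (0, 0.5] — the strict "< 50%" reading would exclude pairwise differences
(each allele at exactly 50%), which the analysis plainly intends to count.
Sites map to anchor coordinates (gap columns inherit the preceding anchored
position) and are annotated with their V region. Discriminability of a
taxon pair through an amplicon asks whether any variant falls inside the
window; by default the V3–V4 window is located on the anchor by in-silico
PCR rather than by fixed coordinates, so it adapts to the loaded
references.

## Pipeline scale and determinism

The default run configuration uses 4 genera × 3 species, 400 long reads,
300 control reads, 3,000 read pairs and an even rarefying depth of 2,000 —
sizes chosen so a full run completes in minutes on one CPU while every
downstream statistic still has enough support; all sizes are config fields.
Every stage seeds its own `numpy` generator from the master seed, so a
serialized config reproduces every artifact byte-for-byte (asserted in the
suite). Thresholds default to the study values: 97% OTU identity, Q20, 75%
join/retention, 80% control span, |log2 FC| > 1, singleton discard.

## Limitations

- The generator emulates amplicon structure and aggregate error rates, not
  base-calling physics: no homopolymer bias, no length-dependent coverage,
  no chimeras beyond concatemers, no unalignable-read fraction. Passing
  tests demonstrate correctness of the analysis machinery under these
  conditions, not performance on real flow-cell data.
- Best-hit phylotyping replaces naive-Bayes OTU taxonomy; star alignment
  replaces guide-tree progressive alignment. Both are documented
  simplifications appropriate at this scale.
- Realignment parsimony (above) means generative error rates are recovered
  with a predictable bias at high error rates; the accuracy module reports
  what an aligner can see, which is also what real studies report.
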