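# lr16s

Full-length 16S rRNA long-read microbiome profiling, rebuilt as a tested,
simulation-driven pipeline.

Short-read 16S assays sequence one or two hypervariable regions (typically
V3–V4, ~469 bp) and often cannot separate species whose amplicons are
identical, even when the full ~1.5 kb gene tells them apart. Long-read
platforms span all nine hypervariable regions (V1–V9) but at a much higher
error rate (~20%), so their usefulness hinges on whether best-hit taxonomy
assignment survives the noise. `lr16s` implements both arms of that
comparison end to end, driven by a synthetic-data generator with known
ground truth, for anyone who wants to study — or teach — how read length,
error rate and amplicon choice interact in community profiling:

- **Simulation** (`lr16s.synth`): a 16S-like reference database with
  GreenGenes-style lineages and V1–V9 structure, IUPAC-aware in-silico PCR,
  long reads under a per-column substitution/insertion/deletion process
  (defaults 9.0% / 6.4% / 5.0%), 2×250 bp pairs with Phred qualities, a
  packaged spike-in control, and concatemer artifacts.
- **Alignment** (`lr16s.align`): exact affine-gap local and global DP with
  match +1, mismatch −1, gap `1 + k` (the published LAST parameters) and
  exact per-column operation counts.
- **Phylotyping** (`lr16s.classify`): best-hit assignment with LCA
  resolution of score ties, the singleton-discard rule, and spike-in
  accuracy assessment — pooled `matches / (matches + mismatches +
  insertions + deletions)` over reads spanning ≥80% of the control.
- **Short-read arm** (`lr16s.shortread`): pair joining, Q20 filtering,
  greedy de novo OTU clustering at 97% identity, OTU taxonomy through the
  V3–V4 window, rarefying and rarefaction curves.
- **Concordance** (`lr16s.compare`): per-rank abundance profiles and rank
  coverage, detection groups (I both / II nanopore-only / III
  short-read-only), log2 fold-change flags, Spearman rho², Venn counts.
- **Variant analysis** (`lr16s.regions`): multiple alignment of reference
  taxa, variant columns with minor-allele frequencies, V-region annotation,
  and amplicon-window discriminability.

## Worked example

```python
from lr16s import (control_sequence, simulate_control_reads, assess_accuracy,
                   NANOPORE_PROFILE, generate_reference_db, discriminability)

control = control_sequence()                       # packaged 1,400 bp spike-in
reads = simulate_control_reads(control, 200, NANOPORE_PROFILE, seed=1)
stats = assess_accuracy(reads, control)
print(f"accuracy {stats.accuracy:.1%}  mismatches {stats.mismatch_rate:.1%}  "
      f"insertions {stats.insertion_rate:.1%}  deletions {stats.deletion_rate:.1%}")

db = generate_reference_db(1, 2, per_region_divergence={"V1": 0.15, "V2": 0.15},
                           between_genus_divergence=0.0, seed=23)
pair = tuple(r.id for r in db.records)
v34 = discriminability(db, pair)                   # V3-V4 window by in-silico PCR
full = discriminability(db, pair, amplicon_window=(0, 1500))
print(f"V3-V4 window: distinguishable={v34['distinguishable']} "
      f"({v34['in_window']}/{v34['total']} variants in window)")
print(f"full length : distinguishable={full['distinguishable']} "
      f"({full['in_window']}/{full['total']})")
```

prints

```
accuracy 81.4%  mismatches 10.2%  insertions 4.9%  deletions 3.6%
V3-V4 window: distinguishable=False (0/38 variants in window)
full length : distinguishable=True (38/38)
```

The first line is the spike-in error decomposition: reads generated at
per-column rates summing to a 79.6% expected accuracy are re-aligned and
tallied; optimal realignment explains some nearby insertion+deletion pairs
as substitutions, so the measured insertion/deletion fractions sit slightly
below the generative rates (see `docs/methods.md`). The second block is the
species-resolution phenomenon in miniature: a species pair whose divergence
is confined to V1–V2 shows 38 variant sites over the full gene but zero
inside the V3–V4 amplicon — indistinguishable to the short-read assay,
cleanly separated by full-length reads.

The whole pipeline runs from one config:

```bash
lr16s run --seed 7 --out runs/demo          # or --config run.yaml
```

which writes the reference DB, both read sets with truth tables, assignment
and OTU tables, per-rank comparison tables, concordance statistics, variant
tables, and a `summary.json`, all byte-reproducible from the seed.
Individual stages are exposed as `lr16s simulate | classify | accuracy |
shortread | compare | regions`.

## Layout

```
src/lr16s/      taxonomy, seqio, synth, align, classify, shortread,
                compare, regions, config, pipeline, cli
tests/          pytest suite (unit, property and acceptance tests)
scripts/        acceptance.py
docs/           methods.md — models, parameters, design choices, limitations
```
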