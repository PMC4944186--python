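"""End-to-end orchestration: simulate -> classify / short-read arm ->
compare -> region analysis, with every intermediate persisted to disk.

Stage order and artifacts::

    refs.fasta, taxonomy.tsv, community.tsv      reference DB + community
    long_reads.fastq, long_truth.tsv             nanopore-like reads
    control_reads.fastq, accuracy.json           spike-in accuracy
    assignments.tsv, assignments_filtered.tsv    best-hit phylotyping
    sr_R1.fastq, sr_R2.fastq, sr_truth.tsv       short pairs
    otu_table.tsv, otu_table_rarefied.tsv        clustering (+ even depth)
    rarefaction.tsv                              richness curve
    comparison_<rank>.tsv, concordance.json      platform concordance
    variants.tsv, region_counts.json             V-region discriminability
    summary.json                                 one JSON with the headline
                                                 numbers of every stage

Each stage draws its randomness from a seed derived from the master seed,
so a serialized config reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional, Sequence

import numpy as np

from . import classify as clf
from . import compare as cmp
from . import regions as reg
from . import shortread as sr
from .align import ScoringScheme
from .config import RunConfig
from .seqio import (
    SeqRecord,
    read_fastq,
    write_fasta,
    write_fastq,
    write_taxonomy,
)
from .synth import (
    Community,
    ReferenceDB,
    control_sequence,
    generate_reference_db,
    simulate_control_reads,
    simulate_long_reads,
    simulate_short_read_pairs,
    write_truth,
)
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

COMPARE_RANKS = ("order", "family", "genus", "species")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# table (de)serialization


def write_assignments(path: str, assignments: Sequence[clf.TaxonAssignment]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlineage\tref_id\tscore\ttie_count\tquery_cover\n")
        for a in assignments:
            fh.write(
                f"{a.read_id}\t{a.lineage.format()}\t{a.ref_id}\t{a.score}"
                f"\t{a.tie_count}\t{a.query_cover:.4f}\n"
            )


def read_assignments(path: str) -> list[clf.TaxonAssignment]:
    out: list[clf.TaxonAssignment] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, lin, ref, score, ties, qc = line.rstrip("\n").split("\t")
            out.append(
                clf.TaxonAssignment(rid, Lineage.parse(lin), ref, int(score), int(ties), float(qc))
            )
    return out


def write_otu_table(path: str, table: sr.OtuTable) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tcount\tlineage\tcentroid\tmembers\n")
        for o in table.otus:
            lin = o.lineage.format() if o.lineage is not None else ""
            fh.write(f"{o.otu_id}\t{o.count}\t{lin}\t{o.centroid}\t{','.join(o.members)}\n")


def read_otu_table(path: str, sample_id: str = "sample") -> sr.OtuTable:
    otus: list[sr.Otu] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            otu_id, count, lin, centroid, members = line.rstrip("\n").split("\t")
            otus.append(
                sr.Otu(
                    otu_id,
                    centroid,
                    members.split(",") if members else [],
                    Lineage.parse(lin) if lin else None,
                )
            )
    return sr.OtuTable(sample_id, otus)


def write_comparison(path: str, records: Sequence[cmp.ComparisonRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\trank\tabundance_short\tabundance_nanopore\tgroup\tlog2fc\tsignificant\n")
        for r in records:
            fc = "" if r.log2fc is None else f"{r.log2fc:.4f}"
            fh.write(
                f"{r.taxon}\t{r.rank}\t{r.abundance_a:.6f}\t{r.abundance_b:.6f}"
                f"\t{r.group}\t{fc}\t{int(r.significant_deviation)}\n"
            )


def write_variants(path: str, sites: Sequence[reg.VariantSite]) -> None:
    with open(path, "w") as fh:
        fh.write("column\tanchor_pos\talleles\tmaf\tregion\n")
        for s in sites:
            alleles = ",".join(f"{a}:{c}" for a, c in sorted(s.alleles.items()))
            fh.write(f"{s.column}\t{s.anchor_pos}\t{alleles}\t{s.minor_allele_frequency:.4f}\t{s.region}\n")


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline


def _draw_community(db: ReferenceDB, alpha: float, seed: int) -> Community:
    rng = np.random.default_rng(seed)
    ids = sorted(r.id for r in db.records)
    weights = rng.dirichlet(np.full(len(ids), alpha))
    return Community(dict(zip(ids, map(float, weights))))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    scheme = ScoringScheme()
    th = config.thresholds
    summary: dict = {"seed": config.seed}

    def path(name: str) -> str:
        return os.path.join(out, name)

    # --- stage 1: reference database + community
    stage = "reference"
    try:
        rc = config.reference
        db = generate_reference_db(
            rc.n_genera,
            rc.species_per_genus,
            rc.length,
            rc.per_region_divergence,
            rc.between_genus_divergence,
            seed=config.derived_seed(1),
            primers=config.primers,
        )
        write_fasta(path("refs.fasta"), [r.as_seqrecord() for r in db.records])
        write_taxonomy(path("taxonomy.tsv"), db.taxonomy)
        community = _draw_community(db, config.community_alpha, config.derived_seed(2))
        with open(path("community.tsv"), "w") as fh:
            for rid in community.ids:
                fh.write(f"{rid}\t{community.weights[rid]:.6f}\n")
        summary["n_references"] = len(db)
        logger.info("stage %s: %d references", stage, len(db))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 2: long reads + spike-in accuracy
    stage = "long_reads"
    try:
        lrc = config.long_reads
        long_reads, long_truth = simulate_long_reads(
            db, community, lrc.n_reads, lrc.profile, lrc.p_concat,
            seed=config.derived_seed(3),
        )
        write_fastq(path("long_reads.fastq"), long_reads)
        write_truth(path("long_truth.tsv"), long_truth)
        control = control_sequence(config.control.length, seed=101)
        control_reads = simulate_control_reads(
            control, config.control.n_reads, lrc.profile, seed=config.derived_seed(4)
        )
        write_fasta(path("control_ref.fasta"), [control])
        write_fastq(path("control_reads.fastq"), control_reads)
        acc = clf.assess_accuracy(control_reads, control, scheme, th.min_ref_span)
        _write_json(path("accuracy.json"), acc.as_dict())
        summary["accuracy"] = acc.as_dict()
        logger.info("stage %s: %d reads, accuracy %.3f", stage, lrc.n_reads, acc.accuracy)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 3: best-hit phylotyping
    stage = "classify"
    try:
        assignments, unassigned = clf.classify_reads(
            long_reads, db, scheme, th.min_query_cover
        )
        write_assignments(path("assignments.tsv"), assignments)
        filtered = clf.filter_low_abundance(assignments, th.min_reads_per_taxon)
        write_assignments(path("assignments_filtered.tsv"), filtered)
        summary["long_read_classification"] = {
            "n_assigned": len(assignments),
            "n_unassigned": len(unassigned),
            "n_after_singleton_filter": len(filtered),
        }
        logger.info("stage %s: %d assigned / %d unassigned", stage, len(assignments), len(unassigned))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 4: short-read arm
    stage = "shortread"
    try:
        src = config.short_reads
        pairs, sr_truth = simulate_short_read_pairs(
            db, community, src.n_pairs, src.read_len,
            (src.q_high, src.q_low, src.p_lowq_tail),
            seed=config.derived_seed(5),
        )
        write_fastq(path("sr_R1.fastq"), [p[0] for p in pairs])
        write_fastq(path("sr_R2.fastq"), [p[1] for p in pairs])
        write_truth(path("sr_truth.tsv"), sr_truth)
        joined = []
        for r1, r2 in pairs:
            j = sr.join_pairs(r1, r2, th.min_overlap, th.max_mismatch_frac, th.min_joined_frac)
            if j is not None:
                joined.append(j)
        passed = []
        for read in joined:
            q = sr.quality_filter(read, th.quality_q, th.min_retained_frac)
            if q is not None:
                passed.append(q)
        if not passed:
            raise RuntimeError("no short read survived join + quality filtering")
        table = sr.cluster_otus(passed, th.otu_identity, scheme, sample_id="short")
        table = sr.assign_otu_taxonomy(table, db, scheme, min_query_cover=th.min_query_cover)
        write_otu_table(path("otu_table.tsv"), table)
        depth = config.rarefy_depth
        if depth is not None and depth <= table.total_count:
            rarefied = sr.rarefy(table, depth, seed=config.derived_seed(6))
        else:
            rarefied = table
        write_otu_table(path("otu_table_rarefied.tsv"), rarefied)
        total = rarefied.total_count
        grid = sorted({max(1, total // 10 * k) for k in range(1, 11)} | {total})
        curve = sr.rarefaction_curve(rarefied, grid, reps=5, seed=config.derived_seed(7))
        with open(path("rarefaction.tsv"), "w") as fh:
            fh.write("depth\tmean_observed_otus\n")
            for d, v in curve:
                fh.write(f"{d}\t{v:.2f}\n")
        summary["shortread"] = {
            "n_pairs": len(pairs),
            "n_joined": len(joined),
            "n_quality_passed": len(passed),
            "n_otus": table.n_otus,
            "n_otus_rarefied": rarefied.n_otus,
            "rarefied_depth": rarefied.total_count,
        }
        logger.info("stage %s: %d OTUs from %d reads", stage, table.n_otus, len(passed))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 5: platform comparison
    stage = "compare"
    try:
        concordance: dict = {}
        group_counts: dict = {}
        for rank in COMPARE_RANKS:
            prof_short = cmp.profile_abundance(rarefied, rank)
            prof_nano = cmp.profile_abundance(filtered, rank)
            records = cmp.compare_platforms(prof_short, prof_nano)
            write_comparison(path(f"comparison_{rank}.tsv"), records)
            r2, p, n_shared = cmp.rank_concordance(prof_short, prof_nano)
            venn = cmp.venn_counts(prof_short.taxa, prof_nano.taxa, prof_short, prof_nano)
            groups = {g: sum(1 for r in records if r.group == g) for g in ("I", "II", "III")}
            n_sig = sum(1 for r in records if r.significant_deviation)
            concordance[rank] = {
                "rho2": None if np.isnan(r2) else round(r2, 6),
                "p": None if np.isnan(p) else p,
                "n_shared": n_shared,
                "coverage_short": round(prof_short.rank_coverage, 6),
                "coverage_nanopore": round(prof_nano.rank_coverage, 6),
                "venn": [venn.shared, venn.only_a, venn.only_b],
                "n_significant_deviation": n_sig,
            }
            group_counts[rank] = groups
        _write_json(path("concordance.json"), concordance)
        summary["concordance"] = concordance
        summary["group_counts"] = group_counts
        logger.info("stage %s: genus rho2 %s", stage, concordance["genus"]["rho2"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- stage 6: hypervariable-region variant analysis
    stage = "regions"
    try:
        pair = config.regions_taxon_pair
        if pair is None:
            pair = [db.records[0].id, db.records[1].id]
        result = reg.discriminability(db, (pair[0], pair[1]), scheme=scheme)
        msa = reg.align_references(
            [SeqRecord(t, db.get(t).seq) for t in pair], scheme
        )
        sites = reg.detect_variants(msa, db.region_map)
        write_variants(path("variants.tsv"), sites)
        _write_json(path("region_counts.json"), result)
        summary["regions"] = result
        logger.info("stage %s: %d variants (%d in window)", stage, result["total"], result["in_window"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_json(path("summary.json"), summary)
    return summary
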