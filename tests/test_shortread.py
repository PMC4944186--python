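import numpy as np
import pytest

from lr16s.seqio import SeqRecord, reverse_complement
from lr16s.shortread import (
    Otu,
    OtuTable,
    assign_otu_taxonomy,
    cluster_otus,
    join_pairs,
    quality_filter,
    rarefaction_curve,
    rarefy,
)
from lr16s.synth import Community, ERROR_FREE, simulate_short_read_pairs

from conftest import random_dna


def _pair_from_amplicon(amp: str, read_len: int, q: int = 40):
    r1 = SeqRecord("p/1", amp[:read_len], [q] * read_len)
    r2 = SeqRecord("p/2", reverse_complement(amp[-read_len:]), [q] * read_len)
    return r1, r2


class TestJoinPairs:
    def test_469bp_amplicon_with_31_base_overlap_retained(self, rnd):
        amp = random_dna(rnd, 469)
        r1, r2 = _pair_from_amplicon(amp, 250)
        joined = join_pairs(r1, r2, min_overlap=10, max_mismatch_frac=0.05)
        assert joined is not None and joined.seq == amp
        assert len(joined) == 469 >= 0.75 * 500

    def test_non_overlapping_reads_give_none(self, rnd):
        r1 = SeqRecord("a/1", random_dna(rnd, 100), [40] * 100)
        r2 = SeqRecord("a/2", random_dna(rnd, 100), [40] * 100)
        assert join_pairs(r1, r2, min_overlap=10, max_mismatch_frac=0.0) is None

    def test_mismatch_fraction_threshold(self, rnd):
        """2 mismatches in a 30-base overlap (6.7%): rejected at 5%,
        joined at 10%."""
        amp = random_dna(rnd, 470)
        r1, r2 = _pair_from_amplicon(amp, 250)
        # corrupt 2 bases of r2 inside the 30-base overlap
        seq2 = list(r2.seq)
        rc = reverse_complement(amp[-250:])
        for k in (245, 248):  # last bases of r2 = start of the overlap region
            orig = seq2[k]
            seq2[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[orig]
        r2_bad = SeqRecord("a/2", "".join(seq2), [10] * 250)  # lower quality than r1
        assert join_pairs(r1, r2_bad, 10, 0.05) is None
        joined = join_pairs(r1, r2_bad, 10, 0.10)
        assert joined is not None
        # consensus takes r1's higher-quality bases: amplicon restored
        assert joined.seq == amp

    def test_too_short_joined_read_rejected(self, rnd):
        # overlap so large that the join is < 75% of the summed pair length
        amp = random_dna(rnd, 300)
        r1, r2 = _pair_from_amplicon(amp, 250)
        assert join_pairs(r1, r2, min_overlap=10, max_mismatch_frac=0.0) is None


class TestQualityFilter:
    def test_all_high_quality_unchanged(self):
        r = SeqRecord("r", "ACGT" * 25, [40] * 100)
        assert quality_filter(r) is r

    def test_late_quality_drop_truncates(self):
        qual = [30] * 80 + [10] * 20
        r = SeqRecord("r", "A" * 100, qual)
        out = quality_filter(r, 20, 0.75)
        assert out is not None and len(out) == 80

    def test_early_quality_drop_discards(self):
        qual = [30] * 50 + [10] * 50
        r = SeqRecord("r", "A" * 100, qual)
        assert quality_filter(r, 20, 0.75) is None


class TestClusterOtus:
    def test_identical_reads_one_otu(self, rnd):
        seq = random_dna(rnd, 120)
        reads = [SeqRecord(f"r{i}", seq) for i in range(10)]
        table = cluster_otus(reads)
        assert table.n_otus == 1 and table.otus[0].count == 10

    def test_identity_threshold_splits_at_97(self, rnd):
        base = random_dna(rnd, 100)

        def mutate(seq, positions):
            out = list(seq)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        near = mutate(base, [10, 50])  # identity 0.98
        far = mutate(base, [10, 30, 50, 70])  # identity 0.96
        t1 = cluster_otus([SeqRecord("a", base), SeqRecord("b", near)])
        t2 = cluster_otus([SeqRecord("a", base), SeqRecord("b", far)])
        assert t1.n_otus == 1 and t2.n_otus == 2

    def test_two_divergent_species_partition_cleanly(self, rnd):
        a = random_dna(rnd, 200)
        b = "".join(
            c if rnd.random() > 0.10 else {"A": "C", "C": "G", "G": "T", "T": "A"}[c]
            for c in a
        )
        reads = [SeqRecord(f"a{i}", a) for i in range(6)] + [
            SeqRecord(f"b{i}", b) for i in range(4)
        ]
        table = cluster_otus(reads)
        assert table.n_otus == 2
        members = {frozenset(o.members) for o in table.otus}
        assert members == {
            frozenset(f"a{i}" for i in range(6)),
            frozenset(f"b{i}" for i in range(4)),
        }

    def test_input_order_invariance(self, rnd):
        seqs = [random_dna(rnd, 150) for _ in range(5)]
        reads = [SeqRecord(f"r{i}", seqs[i % 5]) for i in range(20)]
        t1 = cluster_otus(reads)
        t2 = cluster_otus(list(reversed(reads)))
        assert {o.centroid for o in t1.otus} == {o.centroid for o in t2.otus}
        assert sorted(o.count for o in t1.otus) == sorted(o.count for o in t2.otus)


class TestOtuTaxonomy:
    def test_centroid_matching_amplicon_gets_species(self, tiny_db):
        amps = tiny_db.amplicons(tiny_db.primers.short, 2)
        rid = tiny_db.records[0].id
        table = OtuTable("s", [Otu("otu1", amps[rid].seq, ["x"])])
        table = assign_otu_taxonomy(table, tiny_db)
        assert table.otus[0].lineage == tiny_db.get(rid).lineage

    def test_shared_v3v4_truncates_to_genus(self):
        """Two species identical over V3-V4 (divergence confined to V1-V2)
        cannot be told apart by the short amplicon: the OTU lineage stops at
        genus."""
        from lr16s.synth import generate_reference_db

        db = generate_reference_db(
            1, 2, per_region_divergence={"V1": 0.1, "V2": 0.1},
            between_genus_divergence=0.0, seed=17,
        )
        amps = db.amplicons(db.primers.short, 2)
        a, b = (amps[r.id].seq for r in db.records)
        assert a == b, "V3-V4 amplicons should be identical by construction"
        table = OtuTable("s", [Otu("otu1", a, ["x"])])
        table = assign_otu_taxonomy(table, db)
        lin = table.otus[0].lineage
        assert lin.label("genus") == "G1" and lin.label("species") == ""

    def test_junk_centroid_gets_empty_lineage(self, tiny_db, rnd):
        table = OtuTable("s", [Otu("otu1", random_dna(rnd, 300), ["x"])])
        table = assign_otu_taxonomy(table, tiny_db)
        assert table.otus[0].lineage.is_empty


def _table(counts: dict[str, int]) -> OtuTable:
    otus = [
        Otu(oid, f"SEQ{oid}", [f"{oid}_m{i}" for i in range(n)]) for oid, n in counts.items()
    ]
    return OtuTable("s", otus)


class TestRarefy:
    def test_full_depth_identity(self):
        t = _table({"a": 5, "b": 7})
        r = rarefy(t, 12, seed=0)
        assert r.counts() == {"a": 5, "b": 7}

    def test_depth_one(self):
        r = rarefy(_table({"a": 5, "b": 7}), 1, seed=3)
        assert r.total_count == 1 and r.n_otus == 1

    def test_sum_equals_depth_exactly(self):
        t = _table({"a": 50, "b": 30, "c": 20})
        for depth in (1, 17, 60, 100):
            assert rarefy(t, depth, seed=depth).total_count == depth

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefy(_table({"a": 3}), 4)

    def test_deterministic(self):
        t = _table({"a": 40, "b": 25})
        assert rarefy(t, 20, seed=5).counts() == rarefy(t, 20, seed=5).counts()


class TestRarefactionCurve:
    def test_full_depth_observes_all_otus(self):
        t = _table({"a": 4, "b": 6, "c": 2})
        curve = rarefaction_curve(t, [12], reps=5, seed=0)
        assert curve == [(12, 3.0)]

    def test_depth_one_mean_is_one(self):
        t = _table({"a": 4, "b": 6})
        assert rarefaction_curve(t, [1], reps=10, seed=0) == [(1, 1.0)]

    def test_monotone_in_depth_every_replicate(self):
        """Nested prefix subsampling makes every replicate's curve
        non-decreasing, hence the mean too."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            counts = {f"o{i}": int(rng.integers(1, 20)) for i in range(10)}
            t = _table(counts)
            total = t.total_count
            depths = sorted(set(np.linspace(1, total, 8, dtype=int)))
            curve = rarefaction_curve(t, depths, reps=3, seed=trial)
            values = [v for _, v in curve]
            assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_unsorted_depths_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(_table({"a": 5}), [3, 2], reps=1, seed=0)
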