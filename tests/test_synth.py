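import numpy as np
import pytest
from scipy import stats as sps

from lr16s.seqio import SeqRecord, reverse_complement
from lr16s.synth import (
    Community,
    DEFAULT_REGION_MAP,
    ERROR_FREE,
    ErrorProfile,
    NANOPORE_PROFILE,
    ParameterError,
    control_sequence,
    generate_reference_db,
    in_silico_pcr,
    simulate_control_reads,
    simulate_long_reads,
    simulate_short_read_pairs,
    _primer_matches,
)


class TestErrorProfile:
    def test_validates_range_and_sum(self):
        with pytest.raises(ParameterError):
            ErrorProfile(1.2, 0, 0)
        with pytest.raises(ParameterError):
            ErrorProfile(0.5, 0.4, 0.2)
        assert ErrorProfile(0.09, 0.064, 0.05).expected_accuracy == pytest.approx(0.796)


class TestReferenceGenerator:
    def test_single_record_matches_root_outside_primers(self):
        db = generate_reference_db(1, 1, seed=3)
        assert len(db) == 1
        assert len(db.records[0].seq) == 1500

    def test_zero_divergence_identical_sequences_distinct_lineages(self):
        db = generate_reference_db(
            2, 2, per_region_divergence=0.0, between_genus_divergence=0.0, seed=3
        )
        seqs = {r.seq for r in db.records}
        lineages = {r.lineage.format() for r in db.records}
        assert len(db) == 4 and len(seqs) == 1 and len(lineages) == 4

    def test_all_lineages_complete(self, small_db):
        assert all(r.lineage.depth == 7 for r in small_db.records)

    def test_divergence_confined_to_requested_regions(self):
        """Species generated with divergence only in V1-V2 differ only at
        V1-V2 columns (no indels, so direct column comparison is exact)."""
        rates = {"V1": 0.1, "V2": 0.1}
        db = generate_reference_db(
            1, 2, per_region_divergence=rates, between_genus_divergence=0.0, seed=9
        )
        a, b = db.records[0].seq, db.records[1].seq
        diff_cols = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert diff_cols, "expected some divergence"
        for i in diff_cols:
            assert db.region_map.region_of(i) in {"V1", "V2"}

    def test_saturating_rate_rejected(self):
        with pytest.raises(ParameterError):
            generate_reference_db(1, 1, per_region_divergence=0.9, seed=0)

    def test_deterministic_given_seed(self):
        a = generate_reference_db(2, 2, seed=42)
        b = generate_reference_db(2, 2, seed=42)
        assert [r.seq for r in a.records] == [r.seq for r in b.records]


class TestInSilicoPcr:
    def test_exact_sites_whole_template(self):
        fwd, rev = "ACGTACGTAC", "TTGGCCAATT"
        template = fwd + "A" * 50 + reverse_complement(rev)
        amp = in_silico_pcr(SeqRecord("t", template), fwd, rev, 0)
        assert amp is not None and amp.seq == template

    def test_iupac_degenerate_match(self):
        # N matches A, W matches T in the printed forward V3-V4 primer core
        primer = "CCTACGGGNGGCWGCAG"
        segment = "CCTACGGGAGGCTGCAG"
        assert _primer_matches(segment, primer, 0) == [0]

    def test_absent_reverse_site_gives_none(self):
        fwd = "ACGTACGTAC"
        template = fwd + "A" * 50
        assert in_silico_pcr(SeqRecord("t", template), fwd, "TTGGCCAATT", 0) is None

    def test_overlapping_sites_give_none(self):
        fwd = "ACGTACGTAC"
        # reverse site entirely inside the forward primer footprint
        template = fwd + "AA"
        assert in_silico_pcr(SeqRecord("t", template), fwd, reverse_complement(fwd), 0) is None

    def test_references_always_amplify(self, small_db):
        fl = small_db.amplicons(small_db.primers.full_length, max_mismatch=2)
        sr = small_db.amplicons(small_db.primers.short, max_mismatch=2)
        assert len(fl) == len(small_db) and len(sr) == len(small_db)
        # amplicon lengths match the planted site layout
        assert all(len(a) == 1399 for a in fl.values())
        assert all(len(a) == 466 for a in sr.values())


def _uniform_community(db):
    return Community({r.id: 1.0 for r in db.records})


class TestLongReads:
    def test_noiseless_reads_are_exact_amplicons(self, tiny_db):
        amps = tiny_db.amplicons(tiny_db.primers.full_length, 2)
        reads, truth = simulate_long_reads(
            tiny_db, _uniform_community(tiny_db), 20, ERROR_FREE, 0.0, seed=1
        )
        assert len(reads) == 20
        for r in reads:
            (src,) = truth[r.id]
            assert r.seq == amps[src].seq

    def test_mean_length_matches_model_expectation(self, tiny_db):
        """E[len] = L (1 - p_del) / (1 - p_ins) for the per-column process,
        within 3 standard errors."""
        profile = NANOPORE_PROFILE
        reads, truth = simulate_long_reads(
            tiny_db, _uniform_community(tiny_db), 1000, profile, 0.0, seed=2
        )
        amps = tiny_db.amplicons(tiny_db.primers.full_length, 2)
        exp = np.mean(
            [len(amps[truth[r.id][0]]) for r in reads]
        ) * (1 - profile.p_del) / (1 - profile.p_ins)
        lens = np.array([len(r) for r in reads], dtype=float)
        se = lens.std(ddof=1) / np.sqrt(len(lens))
        assert abs(lens.mean() - exp) < 3 * se

    def test_forced_concatemers_carry_two_forward_primer_sites(self, tiny_db):
        reads, truth = simulate_long_reads(
            tiny_db, _uniform_community(tiny_db), 10, ERROR_FREE, 1.0, seed=3
        )
        fwd = tiny_db.primers.full_length.fwd
        for r in reads:
            assert len(truth[r.id]) == 2
            assert len(_primer_matches(r.seq, fwd, 0)) == 2

    def test_truth_composition_matches_community(self, small_db):
        """Chi-square goodness of fit of truth labels vs community weights
        is not rejected at alpha = 0.01 (n = 5000)."""
        ids = sorted(r.id for r in small_db.records)
        w = np.linspace(1, 4, len(ids))
        community = Community(dict(zip(ids, w / w.sum())))
        _, truth = simulate_long_reads(small_db, community, 5000, ERROR_FREE, 0.0, seed=4)
        observed = np.array(
            [sum(1 for v in truth.values() if v[0] == i) for i in ids], dtype=float
        )
        expected = community.probabilities() * 5000
        p = sps.chisquare(observed, expected).pvalue
        assert p > 0.01

    def test_deterministic_given_seed(self, tiny_db):
        c = _uniform_community(tiny_db)
        r1, t1 = simulate_long_reads(tiny_db, c, 5, NANOPORE_PROFILE, 0.1, seed=9)
        r2, t2 = simulate_long_reads(tiny_db, c, 5, NANOPORE_PROFILE, 0.1, seed=9)
        assert [r.seq for r in r1] == [r.seq for r in r2] and t1 == t2

    def test_empty_community_rejected(self):
        with pytest.raises(ParameterError):
            Community({})


class TestControlReads:
    def test_packaged_control_is_stable(self):
        assert control_sequence().seq == control_sequence().seq
        assert len(control_sequence()) == 1400

    def test_noiseless_reads_equal_control(self):
        ctl = control_sequence()
        reads = simulate_control_reads(ctl, 3, ERROR_FREE, seed=0)
        assert all(r.seq == ctl.seq for r in reads)

    def test_single_read_reproducible(self):
        ctl = control_sequence()
        a = simulate_control_reads(ctl, 1, NANOPORE_PROFILE, seed=7)
        b = simulate_control_reads(ctl, 1, NANOPORE_PROFILE, seed=7)
        assert a[0].seq == b[0].seq

    def test_zero_reads_rejected(self):
        with pytest.raises(ParameterError):
            simulate_control_reads(control_sequence(), 0, ERROR_FREE, seed=0)


class TestShortReadPairs:
    def test_pair_geometry_and_overlap_arithmetic(self, tiny_db):
        """2x250 reads of a 466 bp amplicon leave a 2*250-466 = 34 base
        overlap; R1/R2 reconstruct the amplicon exactly at q_high with no
        low-quality tail."""
        pairs, truth = simulate_short_read_pairs(
            tiny_db, _uniform_community(tiny_db), 5, 250, (60, 10, 0.0), seed=5
        )
        amps = tiny_db.amplicons(tiny_db.primers.short, 2)
        for r1, r2 in pairs:
            src = truth[r1.id.removesuffix("/1")]
            amp = amps[src].seq
            assert len(r1) == len(r2) == 250
            assert r1.seq == amp[:250]
            assert r2.seq == reverse_complement(amp[-250:])
            assert 2 * 250 - len(amp) == 34

    def test_error_rate_follows_phred(self, tiny_db):
        """At constant Q20 the per-base mismatch rate vs truth is ~1%."""
        pairs, truth = simulate_short_read_pairs(
            tiny_db, _uniform_community(tiny_db), 200, 250, (20, 20, 0.0), seed=6
        )
        amps = tiny_db.amplicons(tiny_db.primers.short, 2)
        mism = total = 0
        for r1, _ in pairs:
            amp = amps[truth[r1.id.removesuffix("/1")]].seq
            mism += sum(a != b for a, b in zip(r1.seq, amp))
            total += 250
        assert 0.005 < mism / total < 0.015

    def test_zero_pairs(self, tiny_db):
        pairs, truth = simulate_short_read_pairs(
            tiny_db, _uniform_community(tiny_db), 0, seed=1
        )
        assert pairs == [] and truth == {}

    def test_all_sources_too_short_rejected(self, tiny_db):
        # every V3-V4 amplicon (466 bp) is shorter than a 500 bp read
        with pytest.raises(ParameterError):
            simulate_short_read_pairs(
                tiny_db, _uniform_community(tiny_db), 10, read_len=500, seed=1
            )


def test_region_map_intervals_sorted_nonoverlapping():
    prev_end = 0
    for iv in DEFAULT_REGION_MAP.intervals:
        assert iv.start >= prev_end and iv.end > iv.start
        prev_end = iv.end
    assert DEFAULT_REGION_MAP.span <= 1500
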