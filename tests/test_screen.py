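import io
import random

import numpy as np
import pytest

from acetotrace.concat import build_concatenated_query
from acetotrace.screen import (
    HitRecord,
    SearchFormatError,
    count_cxxc_motifs,
    dedup_exact,
    default_rules,
    parse_search_output,
    per_subquery_coverage,
    per_subquery_identity,
    screen,
    split_hit_by_subquery,
)
from acetotrace import synthetic


def _row(qstart, qend, sstart, send, qseq, sseq, sseqid="G1|c1", bitscore=100.0):
    return "\t".join(
        [
            "query", sseqid, "0.0", str(len(qseq)), str(qstart), str(qend),
            str(sstart), str(send), "1e-30", str(bitscore), qseq, sseq,
        ]
    )


class TestParse:
    def test_well_formed_rows_are_counted(self):
        text = "\n".join(
            [
                _row(1, 4, 100, 111, "ACDE", "ACDE"),
                _row(1, 4, 300, 289, "ACDE", "ACDF"),
                _row(5, 8, 400, 411, "MKVL", "MKVL"),
            ]
        )
        records = parse_search_output(io.StringIO(text))
        assert len(records) == 3
        assert records[0].genome_id == "G1" and records[0].contig_id == "c1"

    def test_sstart_greater_than_send_flags_minus_strand(self):
        rec = parse_search_output(io.StringIO(_row(1, 4, 300, 289, "ACDE", "ACDF")))[0]
        assert rec.minus_strand and rec.strand == "-"

    def test_empty_input_gives_empty_list(self):
        assert parse_search_output(io.StringIO("")) == []

    def test_malformed_row_reported_with_line_number(self):
        text = _row(1, 4, 100, 111, "ACDE", "ACDE") + "\nnot\ttabular\n"
        with pytest.raises(SearchFormatError, match="line 2"):
            parse_search_output(io.StringIO(text))

    def test_missing_aligned_columns_named_in_error(self):
        with pytest.raises(SearchFormatError, match="qseq"):
            parse_search_output(
                io.StringIO(""),
                columns=("qseqid", "sseqid", "qstart", "qend", "sstart", "send", "bitscore", "sseq"),
            )

    def test_custom_column_order_accepted(self):
        text = "G1|c1\t1\t4\t100\t111\t50.0\tACDE\tACDE"
        rec = parse_search_output(
            io.StringIO(text),
            columns=("sseqid", "qstart", "qend", "sstart", "send", "bitscore", "qseq", "sseq"),
        )[0]
        assert rec.qstart == 1 and rec.bitscore == 50.0


class TestIdentity:
    @pytest.mark.parametrize(
        "q, s, expected",
        [
            ("ACDE", "ACDE", 100.0),
            ("ACDE", "ACDF", 75.0),
            ("AC-DE", "ACWDE", 80.0),
            ("acde", "ACDE", 100.0),
            ("A-DE", "A-DE", 75.0),  # a shared gap column never matches
        ],
    )
    def test_identity_over_all_columns(self, q, s, expected):
        assert per_subquery_identity(q, s) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_subquery_identity("AC", "ACD")


class TestCoverage:
    def test_union_of_overlapping_hsps(self):
        assert per_subquery_coverage([(1, 50), (41, 90)], 100) == pytest.approx(90.0)

    def test_exact_threshold_value(self):
        assert per_subquery_coverage([(1, 80)], 100) == pytest.approx(80.0)

    def test_empty_hsp_list_is_zero(self):
        assert per_subquery_coverage([], 100) == 0.0

    def test_monotone_as_hsps_added(self):
        rng = np.random.default_rng(0)
        hsps = []
        prev = 0.0
        for _ in range(20):
            a = int(rng.integers(1, 90))
            b = int(rng.integers(a, 101))
            hsps.append((a, b))
            cur = per_subquery_coverage(hsps, 100)
            assert cur >= prev - 1e-12
            prev = cur

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError):
            per_subquery_coverage([(0, 10)], 100)


class TestMotifs:
    @pytest.mark.parametrize(
        "protein, expected",
        [
            ("MCGGCLLCGGCK", 3),  # Cs at 2,5,8,11: pairs 2-5, 5-8, 8-11
            ("MCGGCAALCGGCK", 2),  # two disjoint motifs
            ("MAAAA", 0),
            ("CAACAAC", 2),  # overlapping occurrences both count
            ("cggc", 1),
        ],
    )
    def test_cxxc_count(self, protein, expected):
        assert count_cxxc_motifs(protein) == expected


@pytest.fixture(scope="module")
def boundary_map():
    rng = np.random.default_rng(11)
    # long subqueries so 0.1%-resolution identities are exactly representable
    qa = synthetic.random_protein(1000, rng)
    eche = list(synthetic.random_protein(1000, rng, alphabet="ADEFGHIKLMNPQRSTVWY"))
    for pos in (100, 500):
        eche[pos] = "C"
        eche[pos + 3] = "C"
    return build_concatenated_query([("qa", qa), ("echE", "".join(eche))])


def _hit_for(submap, name, subject, sstart=5000, bitscore=500.0, qlen=None):
    iv = submap.interval_of(name)
    qlen = qlen if qlen is not None else len(subject)
    return HitRecord(
        genome_id="G1",
        contig_id="c1",
        qstart=iv.start,
        qend=iv.start + qlen - 1,
        sstart=sstart,
        send=sstart + 3 * len(subject.replace("-", "")) - 1,
        bitscore=bitscore,
        evalue=1e-40,
        aligned_query=submap.subquery_sequence(name)[:qlen],
        aligned_subject=subject,
    )


def _mutated(seq, n_changes):
    """Force mismatches at the first n_changes positions (never to C)."""
    out = list(seq)
    for i in range(n_changes):
        out[i] = "A" if out[i] != "A" else "D"
    return "".join(out)


class TestScreenRules:
    """The retention rules at their exact boundaries (inclusive minima)."""

    def test_exact_25_identity_80_coverage_passes(self, boundary_map):
        subject = _mutated(boundary_map.subquery_sequence("qa"), 750)
        hit = _hit_for(boundary_map, "qa", subject[:800], qlen=800)
        # 800 columns; ensure exactly 200 matches inside the first 800
        sub = list(subject[:800])
        q = boundary_map.subquery_sequence("qa")[:800]
        matches = sum(a == b for a, b in zip(sub, q))
        need = 200 - matches
        for i in range(len(sub)):
            if need == 0:
                break
            if sub[i] != q[i]:
                sub[i] = q[i]
                need -= 1
        hit.aligned_subject = "".join(sub)
        [s] = screen([hit], boundary_map)
        assert s.identity_pct == pytest.approx(25.0)
        assert s.coverage_pct == pytest.approx(80.0)
        assert s.passed and s.fail_reason == "none"

    def test_identity_24_9_fails_with_identity_reason(self, boundary_map):
        q = boundary_map.subquery_sequence("qa")
        subject = _mutated(q, 751)  # 249/1000 matches
        [s] = screen([_hit_for(boundary_map, "qa", subject)], boundary_map)
        assert s.identity_pct == pytest.approx(24.9)
        assert not s.passed and s.fail_reason == "identity"

    def test_coverage_79_9_fails_with_coverage_reason(self, boundary_map):
        q = boundary_map.subquery_sequence("qa")
        subject = q[:799]  # identity 100, coverage 79.9
        [s] = screen([_hit_for(boundary_map, "qa", subject)], boundary_map)
        assert s.coverage_pct == pytest.approx(79.9)
        assert not s.passed and s.fail_reason == "coverage"

    @pytest.mark.parametrize("n_motifs, passes", [(2, True), (1, False), (0, False)])
    def test_eche_motif_rule(self, boundary_map, n_motifs, passes):
        rules = default_rules(eche_subqueries=["echE"])
        q = boundary_map.subquery_sequence("echE")
        subject = list(_mutated(q, 650))  # ~35% identity > 28 cutoff
        for pos in (100, 500):
            subject[pos] = subject[pos + 3] = "A"
        for pos in ((100, 500)[:n_motifs]):
            subject[pos] = subject[pos + 3] = "C"
        [s] = screen([_hit_for(boundary_map, "echE", "".join(subject))], boundary_map, rules)
        assert s.identity_pct >= 28.0
        assert s.motif_count == n_motifs
        assert s.passed is passes
        if not passes:
            assert s.fail_reason == "motif"

    def test_eche_identity_cutoff_is_28(self, boundary_map):
        rules = default_rules(eche_subqueries=["echE"])
        q = boundary_map.subquery_sequence("echE")
        subject = list(_mutated(q, 730))  # 27% identity
        for pos in (100, 500):
            subject[pos] = subject[pos + 3] = "C"
        [s] = screen([_hit_for(boundary_map, "echE", "".join(subject))], boundary_map, rules)
        assert 25.0 <= s.identity_pct < 28.0
        assert not s.passed and s.fail_reason == "identity"

    def test_rule_for_unknown_subquery_rejected(self, boundary_map):
        from acetotrace.screen import ScreenRule, ScreenRules

        rules = ScreenRules(per_subquery={"nonesuch": ScreenRule()})
        with pytest.raises(ValueError, match="nonesuch"):
            screen([], boundary_map, rules)


class TestSpacerAndMerging:
    def test_hsp_spanning_spacer_is_split_and_spacer_excluded(self, boundary_map):
        iva = boundary_map.interval_of("qa")
        ivb = boundary_map.interval_of("echE")
        qa_tail = boundary_map.subquery_sequence("qa")[-20:]
        eche_head = boundary_map.subquery_sequence("echE")[:20]
        spacer = "x" * 100
        aligned_q = qa_tail + spacer + eche_head
        aligned_s = qa_tail + "A" * 100 + eche_head
        hit = HitRecord(
            genome_id="G1", contig_id="c1",
            qstart=iva.end - 19, qend=ivb.start + 19,
            sstart=1000, send=1000 + 3 * len(aligned_s) - 1,
            bitscore=100.0, evalue=0.0,
            aligned_query=aligned_q, aligned_subject=aligned_s,
        )
        segments = split_hit_by_subquery(hit, boundary_map)
        assert {s.subquery_name for s in segments} == {"qa", "echE"}
        for seg in segments:
            assert seg.identity == pytest.approx(100.0)
            assert len(seg.aligned_query) == 20

    def test_nearby_hsps_merge_into_one_locus_with_union_coverage(self, boundary_map):
        q = boundary_map.subquery_sequence("qa")
        iv = boundary_map.interval_of("qa")
        h1 = HitRecord(
            genome_id="G1", contig_id="c1",
            qstart=iv.start, qend=iv.start + 499,
            sstart=10_000, send=10_000 + 1500 - 1,
            bitscore=300.0, evalue=0.0,
            aligned_query=q[:500], aligned_subject=q[:500],
        )
        h2 = HitRecord(
            genome_id="G1", contig_id="c1",
            qstart=iv.start + 400, qend=iv.start + 899,
            sstart=11_600, send=11_600 + 1500 - 1,
            bitscore=290.0, evalue=0.0,
            aligned_query=q[400:900], aligned_subject=q[400:900],
        )
        screened = screen([h1, h2], boundary_map)
        assert len(screened) == 1
        [s] = screened
        assert s.coverage_pct == pytest.approx(90.0)
        assert s.passed

    def test_distant_hsps_stay_separate_loci(self, boundary_map):
        q = boundary_map.subquery_sequence("qa")
        iv = boundary_map.interval_of("qa")
        mk = lambda sstart: HitRecord(
            genome_id="G1", contig_id="c1",
            qstart=iv.start, qend=iv.start + 999,
            sstart=sstart, send=sstart + 3000 - 1,
            bitscore=300.0, evalue=0.0,
            aligned_query=q, aligned_subject=q,
        )
        screened = screen([mk(1000), mk(50_000)], boundary_map)
        assert len(screened) == 2


class TestOrderIndependence:
    def test_permuting_hits_does_not_change_verdicts(self, search_records, submap, screened):
        rules = default_rules(eche_subqueries=["echE"])
        shuffled = list(search_records)
        random.Random(1).shuffle(shuffled)
        again = screen(shuffled, submap, rules)
        key = lambda hs: {
            (h.genome_id, h.contig_id, h.subquery_name, h.start, h.end, h.passed)
            for h in hs
        }
        assert key(again) == key(screened)


class TestDedup:
    def test_exact_duplicates_collapse_keeping_first(self):
        out = dedup_exact([("A", "MKV"), ("B", "MKV"), ("C", "MLV")])
        assert [n for n, _ in out] == ["A", "C"]

    def test_all_unique_unchanged(self):
        seqs = [("A", "MK"), ("B", "ML"), ("C", "MN")]
        assert dedup_exact(seqs) == seqs

    def test_case_and_gap_normalization(self):
        out = dedup_exact([("A", "mkv"), ("B", "MKV"), ("C", "M-KV")])
        assert [n for n, _ in out] == ["A"]
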