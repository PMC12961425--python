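"""Hit-table parsing, threshold filtering, nesting, and merging."""

import numpy as np
import pytest

from oracles import mask_from_spans, spans_from_mask, random_spans
from mycomob.hitio import (
    HOST_REFSEQ,
    TE_HMM,
    TE_PEP,
    HitThresholds,
    ProteinHit,
    filter_hits,
    merge_adjacent,
    parse_blast_tab,
    parse_domtbl,
    project_hits,
    read_hits_tsv,
    resolve_nested,
    write_hits_tsv,
)

BLAST_LINE = "cons7_5\tXP_1.1\t91.2\t100\t8\t0\t1\t100\t1\t100\t1e-30\t150.5"

DOMTBL_LINE = (
    "RT_profile - 250 cons1_2 - 400 5e-10 80.5 0.1 1 1 "
    "5e-10 5e-10 80.5 0.1 1 250 10 60 10 60 0.95 -"
)


def mk(cid="c", frame=1, q=(0, 10), cat=TE_PEP, sub="s", ev=1e-10, bs=100.0, nt=None):
    nt_start, nt_end = (nt if nt else (None, None))
    return ProteinHit(
        consensus_id=cid, frame=frame, q_start=q[0], q_end=q[1], subject_id=sub,
        subject_category=cat, evalue=ev, bitscore=bs, nt_start=nt_start, nt_end=nt_end,
    )


class TestBlastParsing:
    def test_coordinates_and_frame_suffix(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE + "\n")
        (hit,) = parse_blast_tab(p, HOST_REFSEQ)
        assert hit.consensus_id == "cons7"
        assert hit.frame == 5
        assert hit.q_span == (0, 100)
        assert hit.evalue == pytest.approx(1e-30)
        assert hit.subject_category == HOST_REFSEQ

    def test_swapped_query_coordinates_normalized(self, tmp_path):
        fields = BLAST_LINE.split("\t")
        fields[6], fields[7] = "100", "1"
        p = tmp_path / "hits.tsv"
        p.write_text("\t".join(fields) + "\n")
        assert parse_blast_tab(p, TE_PEP)[0].q_span == (0, 100)

    def test_empty_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert parse_blast_tab(p, TE_PEP) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE + "\n" + "only\tthree\tcols\n")
        with pytest.raises(ValueError, match=":2"):
            parse_blast_tab(p, TE_PEP)

    def test_bad_frame_suffix_errors(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE.replace("cons7_5", "cons7_9") + "\n")
        with pytest.raises(ValueError, match="frame suffix"):
            parse_blast_tab(p, TE_PEP)


class TestDomtblParsing:
    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text("# a comment\n#another\n")
        assert parse_domtbl(p) == []

    def test_envelope_coordinates_and_fullseq_stats(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text("# header\n" + DOMTBL_LINE + "\n")
        (hit,) = parse_domtbl(p)
        assert hit.q_span == (9, 60)
        assert hit.subject_id == "RT_profile"
        assert hit.consensus_id == "cons1"
        assert hit.frame == 2
        assert hit.evalue == pytest.approx(5e-10)
        assert hit.bitscore == pytest.approx(80.5)
        assert hit.subject_category == TE_HMM

    def test_weak_hit_survives_parsing(self, tmp_path):
        # filtering is a separate stage: an E-value of 0.005 must parse fine
        p = tmp_path / "t.domtbl"
        p.write_text(DOMTBL_LINE.replace("5e-10 80.5 0.1 1 1", "0.005 80.5 0.1 1 1", 1) + "\n")
        (hit,) = parse_domtbl(p)
        assert hit.evalue == pytest.approx(0.005)

    def test_truncated_line_reports_line_number(self, tmp_path):
        p = tmp_path / "t.domtbl"
        p.write_text("short line only\n")
        with pytest.raises(ValueError, match=":1"):
            parse_domtbl(p)


class TestFiltering:
    def test_hmm_bitscore_floor_is_inclusive(self):
        below = mk(cat=TE_HMM, ev=5e-4, bs=49.0)
        at = mk(cat=TE_HMM, ev=5e-4, bs=50.0)
        assert filter_hits([below]) == []
        assert filter_hits([at]) == [at]

    def test_evalue_ceiling_is_inclusive(self):
        hit = mk(cat=HOST_REFSEQ, ev=1e-3)
        assert filter_hits([hit]) == [hit]
        assert filter_hits([mk(cat=HOST_REFSEQ, ev=1.1e-3)]) == []

    def test_mixed_list_keeps_exactly_the_qualifying_hits(self):
        # enumerated by hand against the category thresholds
        hits = [
            mk(cat=HOST_REFSEQ, ev=1e-5, sub="keep1"),
            mk(cat=HOST_REFSEQ, ev=0.01, sub="drop1"),
            mk(cat=TE_HMM, ev=1e-4, bs=51.0, sub="keep2"),
            mk(cat=TE_HMM, ev=1e-4, bs=20.0, sub="drop2"),
            mk(cat=TE_PEP, ev=1e-3, sub="keep3"),
            mk(cat=TE_PEP, ev=0.5, sub="drop3"),
        ]
        kept = filter_hits(hits)
        assert [h.subject_id for h in kept] == ["keep1", "keep2", "keep3"]

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(3)
        hits = [
            mk(cat=rng.choice([HOST_REFSEQ, TE_HMM, TE_PEP]),
               ev=float(10 ** rng.uniform(-8, 1)), bs=float(rng.uniform(0, 100)),
               sub=f"s{i}")
            for i in range(50)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert all(h in hits for h in once)

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            HitThresholds(host_evalue_max=0)


class TestProjection:
    def test_nt_span_is_three_times_residue_span(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE + "\n")
        hits = project_hits(parse_blast_tab(p, TE_PEP), {"cons7": 400})
        (h,) = hits
        assert h.nt_end - h.nt_start == 3 * (h.q_end - h.q_start)
        assert 0 <= h.nt_start < h.nt_end <= 400

    def test_missing_length_errors(self):
        with pytest.raises(ValueError, match="no consensus length"):
            project_hits([mk()], {})


class TestResolveNested:
    def test_high_quality_container_wins(self):
        a = mk(sub="A", bs=200.0, nt=(0, 300), q=(0, 100))
        b = mk(sub="B", bs=90.0, nt=(30, 150), q=(10, 50))
        assert resolve_nested([a, b]) == [a]

    def test_container_loses_to_better_contained_hit(self):
        a = mk(sub="A", bs=90.0, nt=(0, 300), q=(0, 100))
        b = mk(sub="B", bs=200.0, nt=(30, 150), q=(10, 50))
        assert resolve_nested([a, b]) == [b]

    def test_disjoint_hit_is_unaffected(self):
        a = mk(sub="A", bs=200.0, nt=(0, 300), q=(0, 100))
        b = mk(sub="B", bs=90.0, nt=(30, 150), q=(10, 50))
        c = mk(sub="C", bs=10.0, nt=(600, 630), q=(200, 210))
        assert resolve_nested([a, b, c]) == [a, c]

    def test_mixed_consensus_ids_error(self):
        with pytest.raises(ValueError, match="multiple consensus ids"):
            resolve_nested([mk(cid="x", nt=(0, 30)), mk(cid="y", nt=(0, 30))])

    def test_no_containment_pair_remains(self):
        rng = np.random.default_rng(5)
        hits = []
        for i in range(40):
            rs = int(rng.integers(0, 200))
            re_ = int(rng.integers(rs + 1, rs + 80))
            hits.append(
                mk(sub=f"s{i}", bs=float(rng.uniform(10, 300)), q=(rs, re_),
                   nt=(3 * rs, 3 * re_))
            )
        kept = resolve_nested(hits)
        for x in kept:
            for y in kept:
                if x is y:
                    continue
                xs, xe = x.nt_span
                ys, ye = y.nt_span
                assert not (xs >= ys and xe <= ye)


class TestMergeAdjacent:
    def test_overlap_merges(self):
        hits = [mk(sub="a", q=(0, 13), nt=(12, 51)), mk(sub="b", q=(0, 13), nt=(42, 81))]
        assert merge_adjacent(hits, 0).intervals == ((12, 81),)

    def test_gap_rule(self):
        hits = [mk(sub="a", q=(0, 13), nt=(12, 51)), mk(sub="b", q=(0, 10), nt=(57, 87))]
        assert merge_adjacent(hits, 30).intervals == ((12, 87),)
        assert merge_adjacent(hits, 0).intervals == ((12, 51), (57, 87))

    def test_negative_gap_errors(self):
        with pytest.raises(ValueError):
            merge_adjacent([mk(nt=(0, 30))], -1)

    def test_total_length_matches_boolean_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            spans = []
            hits = []
            for i, (s, e) in enumerate(random_spans(rng, 900)):
                s -= s % 3
                e = s + 3 * max(1, (e - s) // 3)
                spans.append((s, e))
                hits.append(mk(sub=f"s{i}", q=(s // 3, e // 3), nt=(s, e)))
            if not hits:
                continue
            merged = merge_adjacent(hits, 0)
            assert merged.total_length() == int(mask_from_spans(spans, 1300).sum())
            assert list(merged.intervals) == spans_from_mask(mask_from_spans(spans, 1300))


class TestHitTsv:
    def test_round_trip(self, tmp_path):
        hits = [mk(sub="a", nt=(0, 30)), mk(cat=TE_HMM, sub="b", bs=77.0)]
        p = tmp_path / "hits.tsv"
        write_hits_tsv(hits, p)
        assert read_hits_tsv(p) == hits
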