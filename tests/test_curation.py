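"""Host-gene rule, evidence codes, quality filters, genome flags."""

import numpy as np
import pytest

from oracles import exclusive_residues, host_gene_flag, random_spans
from mycomob.curation import (
    ClassMap,
    CurationThresholds,
    GenomeMetadata,
    classify_host_gene,
    curate_library,
    flag_lq_genome,
    label_evidence,
    n50,
    quality_filter,
)
from mycomob.hitio import HOST_REFSEQ, TE_HMM, TE_PEP, IntervalSet, ProteinHit
from mycomob.seqio import ConsensusRecord


def hit(cid="c1", cat=TE_PEP, sub="TEpep_gypsy", nt=(0, 300), frame=1, ev=1e-10, bs=100.0):
    return ProteinHit(
        consensus_id=cid, frame=frame, q_start=nt[0] // 3, q_end=nt[1] // 3,
        subject_id=sub, subject_category=cat, evalue=ev, bitscore=bs,
        nt_start=nt[0], nt_end=nt[1],
    )


CMAP = ClassMap(
    {
        "TEpep_gypsy": ("LTR", "Gypsy"),
        "TEpep_copia": ("LTR", "Copia"),
        "TEpep_ltr": ("LTR", ""),
        "TEpep_hat": ("DNA", "hAT"),
        "TEpep_blank": ("", ""),
    }
)


class TestHostGeneRule:
    def test_branch_i_refseq_only(self):
        assert classify_host_gene(IntervalSet([(0, 600)]), IntervalSet()) == (True, 200)

    def test_branch_ii_below_threshold(self):
        got = classify_host_gene(IntervalSet([(0, 300)]), IntervalSet([(57, 300)]))
        assert got == (False, 19)

    def test_branch_ii_above_threshold(self):
        got = classify_host_gene(IntervalSet([(0, 600)]), IntervalSet([(447, 780)]))
        assert got == (True, 149)

    def test_no_refseq_coverage_is_never_host_gene(self):
        assert classify_host_gene(IntervalSet(), IntervalSet([(0, 900)])) == (False, 0)

    def test_matches_per_position_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            L = int(rng.integers(100, 3000))
            ref = random_spans(rng, L)
            te = random_spans(rng, L)
            hg, excl = classify_host_gene(IntervalSet(ref), IntervalSet(te))
            assert excl == exclusive_residues(ref, te, L)
            assert hg == host_gene_flag(ref, te, L)

    def test_monotonicity_in_te_and_refseq_coverage(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            L = 2000
            ref = random_spans(rng, L, max_n=6)
            te = random_spans(rng, L, max_n=6)
            extra = random_spans(rng, L, max_n=3)
            if not (ref and te):
                continue
            hg, _ = classify_host_gene(IntervalSet(ref), IntervalSet(te))
            # more TE coverage can only demote a host-gene call
            hg_more_te, _ = classify_host_gene(
                IntervalSet(ref), IntervalSet(te + extra)
            )
            if not hg:
                assert not hg_more_te
            # more RefSeq coverage can only promote under branch (ii)
            hg_more_ref, _ = classify_host_gene(
                IntervalSet(ref + extra), IntervalSet(te)
            )
            if hg:
                assert hg_more_ref


class TestEvidence:
    def test_concordant_hits_give_pe(self):
        hits = [hit(sub="TEpep_gypsy"), hit(sub="TEpep_ltr")]
        assert label_evidence("LTR", "Gypsy", hits, CMAP) == "PE"

    def test_discordant_high_level_gives_da(self):
        assert label_evidence("DNA", "hAT", [hit(sub="TEpep_copia")], CMAP) == "DA"

    def test_discordance_beats_concordance(self):
        hits = [hit(sub="TEpep_gypsy"), hit(sub="TEpep_hat")]
        assert label_evidence("LTR", "Gypsy", hits, CMAP) == "DA"

    def test_sub_level_conflict_within_high_level_is_discordant(self):
        assert label_evidence("LTR", "Gypsy", [hit(sub="TEpep_copia")], CMAP) == "DA"

    def test_no_hits_gives_ne(self):
        assert label_evidence("Unknown", "", [], CMAP) == "NE"

    def test_unmapped_or_blank_subjects_give_ne(self):
        hits = [hit(sub="mystery_protein"), hit(sub="TEpep_blank")]
        assert label_evidence("LTR", "Gypsy", hits, CMAP) == "NE"

    def test_unknown_classification_with_mapped_hits_gives_da(self):
        assert label_evidence("Unknown", "", [hit(sub="TEpep_gypsy")], CMAP) == "DA"

    def test_refseq_hits_never_count_as_te_evidence(self):
        hits = [hit(cat=HOST_REFSEQ, sub="TEpep_gypsy")]
        assert label_evidence("LTR", "Gypsy", hits, CMAP) == "NE"

    def test_ne_iff_no_mapped_te_hits(self):
        rng = np.random.default_rng(13)
        subjects = list(CMAP._exact) + ["unmapped1", "unmapped2"]
        for _ in range(100):
            hits = [
                hit(sub=subjects[int(rng.integers(len(subjects)))])
                for _ in range(int(rng.integers(0, 5)))
            ]
            code = label_evidence("LTR", "Gypsy", hits, CMAP)
            mapped = [h for h in hits if CMAP.resolve(h.subject_id)]
            assert (code == "NE") == (not mapped)

    def test_prefix_matching_resolves_accessions(self):
        cmap = ClassMap({"Gypsy-": ("LTR", "Gypsy")})
        assert cmap.resolve("Gypsy-12_ZM") == ("LTR", "Gypsy")


class TestQualityFilter:
    def test_length_strictly_below_120_removed(self):
        removed, reasons = quality_filter(ConsensusRecord("s", "A" * 119))
        assert removed and reasons == ["SHORT"]

    def test_length_120_retained(self):
        assert quality_filter(ConsensusRecord("s", "A" * 120)) == (False, [])

    def test_n_fraction_5_percent_inclusive(self):
        removed, reasons = quality_filter(
            ConsensusRecord("s", "A" * 190 + "N" * 10)
        )
        assert removed and reasons == ["N_RICH"]

    def test_n_fraction_just_below_retained(self):
        seq = "A" * 961 + "N" * 39  # 3.9% N
        assert quality_filter(ConsensusRecord("s", seq)) == (False, [])

    def test_both_rules_fire(self):
        removed, reasons = quality_filter(ConsensusRecord("s", "N" * 100))
        assert removed and set(reasons) == {"SHORT", "N_RICH"}


class TestGenomeQuality:
    def test_n50_from_contigs(self):
        # descending cumulative sum reaches half-total (500k) at 300k
        assert n50([100_000, 200_000, 300_000, 400_000]) == 300_000

    def test_lq_requires_both_clauses(self):
        base = dict(assembly_id="a", busco_complete_pct=85.0)
        assert flag_lq_genome(GenomeMetadata(n50_bp=40_000, **base))
        assert not flag_lq_genome(
            GenomeMetadata(assembly_id="a", n50_bp=40_000, busco_complete_pct=95.0)
        )
        assert not flag_lq_genome(
            GenomeMetadata(assembly_id="a", n50_bp=60_000, busco_complete_pct=85.0)
        )

    def test_contig_based_n50_dominates_busco(self):
        meta = GenomeMetadata(
            assembly_id="a",
            contig_lengths=[100_000, 200_000, 300_000, 400_000],
            busco_complete_pct=10.0,
        )
        assert not flag_lq_genome(meta)  # N50 300 kb is above the floor

    def test_missing_busco_errors(self):
        with pytest.raises(ValueError, match="BUSCO"):
            flag_lq_genome(GenomeMetadata(assembly_id="a", n50_bp=40_000))


class TestCurateLibrary:
    def recs(self):
        return [
            ConsensusRecord("r1", "ACGT" * 100, "LTR", "Gypsy"),
            ConsensusRecord("r2", "ACGT" * 80),
            ConsensusRecord("r3", "A" * 60),
        ]

    def test_library_without_hits_all_retained_ne_non_autonomous(self):
        retained, verdicts = curate_library(self.recs(), [])
        assert [v.retained for v in verdicts] == [True, True, False]
        assert all(v.evidence == "NE" for v in verdicts)
        assert all(v.non_autonomous for v in verdicts)
        assert [r.record_id for r in retained] == ["r1", "r2"]

    def test_partition_into_exactly_one_outcome(self):
        hits = [hit(cid="r1", cat=HOST_REFSEQ, sub="XP_1", nt=(0, 390))]
        _, verdicts = curate_library(self.recs(), hits)
        for v in verdicts:
            assert sum([v.host_gene, v.removed_quality, v.retained]) == 1

    def test_host_gene_stage_precedes_quality(self):
        # 60 nt record with RefSeq-only coverage: accounted as host gene
        hits = [hit(cid="r3", cat=HOST_REFSEQ, sub="XP_1", nt=(0, 60), frame=1)]
        _, verdicts = curate_library(self.recs(), hits)
        v = {v.consensus_id: v for v in verdicts}["r3"]
        assert v.host_gene and not v.removed_quality

    def test_orphan_hits_error_lists_ids(self):
        with pytest.raises(ValueError, match="ghost"):
            curate_library(self.recs(), [hit(cid="ghost", nt=(0, 30))])

    def test_per_subject_mode_is_stricter_than_union(self):
        # two RefSeq subjects, each 45 exclusive residues; union = 90
        recs = [ConsensusRecord("r1", "A" * 900)]
        hits = [
            hit(cid="r1", cat=HOST_REFSEQ, sub="XP_a", nt=(0, 135)),
            hit(cid="r1", cat=HOST_REFSEQ, sub="XP_b", nt=(600, 735)),
            hit(cid="r1", cat=TE_PEP, sub="TEpep_gypsy", nt=(300, 600)),
        ]
        _, v_union = curate_library(recs, hits, class_map=CMAP)
        _, v_per = curate_library(
            recs, hits, class_map=CMAP, host_gene_mode="per_subject"
        )
        assert v_union[0].host_gene
        assert not v_per[0].host_gene

    def test_retained_records_carry_evidence_and_lq(self):
        recs = [
            ConsensusRecord("r1", "ACGT" * 100, "LTR", "Gypsy", source_genome="asm1")
        ]
        hits = [hit(cid="r1", sub="TEpep_gypsy", nt=(0, 300))]
        meta = {
            "asm1": GenomeMetadata(
                assembly_id="asm1", n50_bp=30_000, busco_complete_pct=70.0
            )
        }
        retained, _ = curate_library(recs, hits, meta, class_map=CMAP)
        assert retained[0].evidence == "PE"
        assert retained[0].lq_genome
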