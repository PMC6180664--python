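"""The five-step identification cascade and positional classification."""

import numpy as np
import pandas as pd
import pytest

from lnckit import (
    AnnotationSet,
    ScorePanel,
    classify_position,
    consensus_noncoding,
    filter_sense_overlap,
    filter_short,
    filter_single_exon,
    filter_small_rna,
    paper_style_rules,
    run_identification,
    split_known_novel,
)
from lnckit.intervals import make_transcript

from conftest import brute_force_overlap, random_transcript


def _coding_ref():
    return AnnotationSet(
        [
            make_transcript(
                "PC1", "PC1", "chr1", "+", [(1000, 1300), (1600, 1900)],
                "protein_coding",
            )
        ]
    )


class TestFilters:
    def test_duplicate_of_coding_transcript_removed(self):
        ref = _coding_ref()
        dup = make_transcript("T1", "X1", "chr1", "+", [(1000, 1300), (1600, 1900)])
        kept, removed = filter_sense_overlap([dup], ref)
        assert removed == [dup] and kept == []

    def test_opposite_strand_overlap_kept(self):
        ref = _coding_ref()
        t = make_transcript("T1", "X1", "chr1", "-", [(1000, 1300), (1600, 1900)])
        kept, _ = filter_sense_overlap([t], ref)
        assert kept == [t]

    def test_protein_coding_biotype_removed_without_overlap(self):
        ref = _coding_ref()
        t = make_transcript(
            "T1", "X1", "chr2", "+", [(0, 500)], biotype="protein_coding"
        )
        _, removed = filter_sense_overlap([t], ref)
        assert removed == [t]

    def test_sense_overlap_matches_brute_force(self, noiseless_dataset):
        ds = noiseless_dataset
        coding = [f for f in ds.reference if f.biotype == "protein_coding"]
        _, removed = filter_sense_overlap(ds.assembled, ds.reference)
        expected = {
            t.transcript_id
            for t in ds.assembled
            if t.biotype == "protein_coding"
            or brute_force_overlap(t, coding, "same", "exon")
        }
        assert {t.transcript_id for t in removed} == expected

    def test_single_exon_partition(self):
        rng = np.random.default_rng(0)
        ts = [random_transcript(rng, f"T{i}") for i in range(10)]
        kept, removed = filter_single_exon(ts)
        assert all(t.exon_count >= 2 for t in kept)
        assert all(t.exon_count == 1 for t in removed)
        assert len(kept) + len(removed) == 10

    @pytest.mark.parametrize(
        "length,is_kept", [(199, False), (200, True), (201, True)]
    )
    def test_length_boundary_on_spliced_length(self, length, is_kept):
        half = length // 2
        t = make_transcript(
            "T", "X", "chr1", "+", [(0, half), (1000, 1000 + length - half)]
        )
        kept, removed = filter_short([t])
        assert (t in kept) is is_kept

    def test_small_rna_hits_removed(self):
        ts = [
            make_transcript(f"T{i}", "X", "chr1", "+", [(0, 300)]) for i in range(3)
        ]
        hits = pd.DataFrame(
            {"transcript_id": ["T1"], "family_accession": ["RF00005"],
             "family_class": ["tRNA"]}
        )
        kept, removed = filter_small_rna(ts, hits)
        assert [t.transcript_id for t in removed] == ["T1"]
        kept, removed = filter_small_rna(ts, None)
        assert len(kept) == 3 and not removed


class TestConsensus:
    def test_all_five_noncoding_kept(self):
        panel = ScorePanel(
            {"T1": {"CPC": -1.0, "CNCI": -0.5, "PLEK": -0.2, "FEELnc": 0.3}}
        )
        kept, verdicts = consensus_noncoding(panel, paper_style_rules())
        assert kept == {"T1"}
        assert (verdicts.loc["T1"] == "noncoding").all()

    def test_pfam_hit_marks_coding(self):
        panel = ScorePanel(
            {"T1": {"CPC": -1.0, "CNCI": -0.5, "PLEK": -0.2, "FEELnc": 0.3,
                    "Pfam": 1e-5}}
        )
        kept, verdicts = consensus_noncoding(panel, paper_style_rules())
        assert kept == set()
        assert verdicts.loc["T1", "Pfam"] == "coding"

    def test_kept_set_is_venn_intersection(self):
        rng = np.random.default_rng(13)
        rules = paper_style_rules()
        ids = [f"T{i}" for i in range(200)]
        panel = ScorePanel(
            {
                tid: {
                    "CPC": rng.normal(),
                    "CNCI": rng.normal(),
                    "PLEK": rng.normal(),
                    "FEELnc": rng.random(),
                    **({"Pfam": 10 ** rng.uniform(-6, 1)} if rng.random() < 0.5 else {}),
                }
                for tid in ids
            }
        )
        kept, _ = consensus_noncoding(panel, rules)
        per_tool_noncoding = [
            {t for t in ids if r.verdict(panel.get(t, r.tool_name)) == "noncoding"}
            for r in rules
        ]
        assert kept == set.intersection(*per_tool_noncoding)

    def test_duplicate_tool_rejected(self):
        rules = paper_style_rules() + paper_style_rules()[:1]
        with pytest.raises(ValueError, match="distinct tool"):
            consensus_noncoding(ScorePanel({}), rules)

    def test_unknown_tool_in_panel_rejected(self):
        panel = ScorePanel({"T1": {"mystery": 1.0}})
        with pytest.raises(ValueError, match="no rule"):
            consensus_noncoding(panel, paper_style_rules())


class TestKnownNovelAndPosition:
    def _ref(self):
        return AnnotationSet(
            [
                make_transcript(
                    "KL1", "KL1", "chr1", "+", [(100, 400), (800, 1100)], "lncRNA"
                ),
                make_transcript("SNO1", "SNO1", "chr2", "+", [(500, 600)], "snoRNA"),
            ]
        )

    def test_identical_candidate_is_known(self):
        cand = make_transcript("C1", "X", "chr1", "+", [(100, 400), (800, 1100)])
        known, novel = split_known_novel([cand], self._ref())
        assert known == [cand] and novel == []

    def test_terminal_extension_still_known(self):
        cand = make_transcript("C1", "X", "chr1", "+", [(60, 400), (800, 1150)])
        known, _ = split_known_novel([cand], self._ref())
        assert known == [cand]

    def test_candidate_without_reference_lncrna_is_novel(self):
        cand = make_transcript("C1", "X", "chr9", "+", [(100, 400), (800, 1100)])
        _, novel = split_known_novel([cand], self._ref())
        assert novel == [cand]

    def test_no_overlap_is_intergenic(self):
        lnc = make_transcript("L", "X", "chr3", "+", [(0, 300), (500, 800)])
        assert classify_position(lnc, self._ref()) == "intergenic"

    def test_opposite_snorna_overlap_is_antisense_snorna(self):
        lnc = make_transcript("L", "X", "chr2", "-", [(550, 700), (900, 1100)])
        assert classify_position(lnc, self._ref()) == "antisense:snoRNA"


class TestFullCascade:
    def test_ground_truth_fates_recovered(self, noiseless_dataset):
        ds = noiseless_dataset
        report = run_identification(
            ds.assembled, ds.reference, sequences=ds.sequences, hits=ds.rfam_hits
        )
        assert report.fates == ds.truth.labels

    def test_stage_counts_monotone_and_fates_partition(self, noiseless_dataset):
        ds = noiseless_dataset
        report = run_identification(
            ds.assembled, ds.reference, sequences=ds.sequences, hits=ds.rfam_hits
        )
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert len(report.fates) == len(ds.assembled)
        removed = sum(
            1 for f in report.fates.values() if f.startswith("removed")
        )
        assert removed + len(report.lncrnas) == len(ds.assembled)

    def test_empty_input_gives_empty_report(self):
        report = run_identification(
            [], AnnotationSet([]), sequences={}, hits=None
        )
        assert report.stage_counts["input"] == 0
        assert report.fates == {} and report.lncrnas == []

    def test_final_kept_set_is_order_independent(self, noiseless_dataset):
        """The cascade is a set intersection: applying the standalone
        filters in any order keeps the same final set."""
        from lnckit.identify import build_internal_panel, internal_rules

        ds = noiseless_dataset
        report = run_identification(
            ds.assembled, ds.reference, sequences=ds.sequences, hits=ds.rfam_hits
        )
        s1 = set(
            t.transcript_id
            for t in filter_sense_overlap(ds.assembled, ds.reference)[0]
        )
        s2 = {t.transcript_id for t in filter_single_exon(ds.assembled)[0]}
        s3 = {t.transcript_id for t in filter_short(ds.assembled)[0]}
        panel = build_internal_panel(ds.sequences)
        s4, _ = consensus_noncoding(panel, internal_rules())
        s5 = {
            t.transcript_id for t in filter_small_rna(ds.assembled, ds.rfam_hits)[0]
        }
        standalone = s1 & s2 & s3 & set(s4) & s5
        assert {t.transcript_id for t in report.lncrnas} == standalone
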