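import itertools

import pytest

from annocure.curation import (CorrectionRecord, apply_corrections,
                               assign_inherited_id, cds_coverage_nt,
                               model_from_transcript, propose_replacement,
                               resolve_redundant_curations)
from annocure.io import GeneModel, TranscriptEvidence


def _t(tid, exons, evidence="rnaseq_assembly"):
    return TranscriptEvidence(tid, "s1", "+", exons, "M" * 100,
                              evidence_class=evidence)


@pytest.fixture()
def fused_old():
    # fused model spanning two true genes A=[100,400) and B=[700,1000)
    return GeneModel("old1", "s1", "+", [(100, 400), (700, 1000)])


class TestProposeReplacement:
    def test_fusion_split_into_two_transcripts(self, fused_old):
        rec = propose_replacement(fused_old, [_t("tA", [(100, 400)]),
                                              _t("tB", [(700, 1000)])])
        assert sorted(m.gene_id for m in rec.new_models) == ["tA", "tB"]
        assert rec.residual_segments == []

    def test_single_full_cover(self, fused_old):
        rec = propose_replacement(fused_old, [_t("tAB", [(100, 400), (700, 1000)])])
        assert [m.gene_id for m in rec.new_models] == ["tAB"]
        assert rec.residual_segments == []

    def test_uncovered_stretch_becomes_residual_with_pseudo_id(self):
        # 300 aa gene; transcript covers the first 250 aa -> one 50 aa residual
        old = GeneModel("old2", "s1", "+", [(0, 900)])
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(300))
        rec = propose_replacement(old, [_t("tC", [(0, 750)])], old_protein=protein)
        assert len(rec.residual_segments) == 1
        pid, seq = rec.residual_segments[0]
        assert pid == "old2_res1"
        assert seq == protein[250:300]

    def test_minus_strand_residual_maps_to_protein_start(self):
        # on the minus strand the uncovered left-most genomic stretch is the
        # protein's C-terminus
        old = GeneModel("old3", "s1", "-", [(0, 900)])
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(300))
        t = TranscriptEvidence("tD", "s1", "-", [(150, 900)], "M" * 250)
        rec = propose_replacement(old, [t], old_protein=protein)
        assert rec.residual_segments == [("old3_res1", protein[250:300])]

    def test_short_residuals_discarded(self):
        old = GeneModel("old4", "s1", "+", [(0, 900)])
        rec = propose_replacement(old, [_t("tE", [(30, 900)])],
                                  old_protein="M" * 300)  # 10 aa uncovered
        assert rec.residual_segments == []

    def test_conflicting_candidates_resolved_greedily(self, fused_old):
        # tFull covers 600 nt, tA only 300 and overlaps tFull -> tFull wins
        rec = propose_replacement(fused_old,
                                  [_t("tA", [(100, 400)]),
                                   _t("tFull", [(100, 400), (700, 1000)])])
        assert [m.gene_id for m in rec.new_models] == ["tFull"]

    def test_no_overlapping_candidate_is_an_error(self, fused_old):
        with pytest.raises(ValueError):
            propose_replacement(fused_old, [_t("tFar", [(5000, 5400)])])


class TestInheritedId:
    def _m(self, gid, length):
        return GeneModel(gid, "s1", "+", [(0, length)])

    def test_most_conserved_wins(self, fused_old):
        models = [self._m("tA", 300), self._m("tB", 900)]
        got = assign_inherited_id(fused_old, models,
                                  {"tA": 1e-50, "tB": 1e-8})
        assert got == "tA"

    def test_longest_wins_without_scores(self, fused_old):
        models = [self._m("tA", 450), self._m("tB", 900)]
        assert assign_inherited_id(fused_old, models) == "tB"

    def test_single_model_inherits(self, fused_old):
        assert assign_inherited_id(fused_old, [self._m("tA", 300)]) == "tA"

    def test_empty_is_an_error(self, fused_old):
        with pytest.raises(ValueError):
            assign_inherited_id(fused_old, [])


def _rec(rid, n_models, evidence="rnaseq_assembly", old="old1"):
    models = [GeneModel(f"{rid}_m{i}", "s1", "+", [(i * 1000, i * 1000 + 300)])
              for i in range(n_models)]
    return CorrectionRecord(rid, old, models, provenance=[evidence])


class TestResolveRedundant:
    def test_more_models_preferred(self):
        assert resolve_redundant_curations([_rec("r1", 1), _rec("r2", 2)]).record_id == "r2"

    def test_transcript_evidence_beats_legacy(self):
        got = resolve_redundant_curations([_rec("r1", 1, "legacy_prediction"),
                                           _rec("r2", 1, "isoseq")])
        assert got.record_id == "r2"

    def test_identical_records_pick_deterministic_first(self):
        assert resolve_redundant_curations([_rec("r2", 1), _rec("r1", 1)]).record_id == "r1"

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            resolve_redundant_curations([])


class TestApplyCorrections:
    @pytest.fixture()
    def annotation(self):
        return {f"g{i}": GeneModel(f"g{i}", "s1", "+",
                                   [(i * 2000, i * 2000 + 600)])
                for i in range(10)}

    def test_one_replacement_by_two_models_gives_eleven_genes(self, annotation):
        rec = CorrectionRecord(
            "replace:g0", "g0",
            [GeneModel("n1", "s1", "+", [(0, 300)]),
             GeneModel("n2", "s1", "+", [(350, 600)])],
            inherited_id_assignee="n1")
        new, log = apply_corrections(annotation, [rec])
        assert len(new) == 11
        assert "g0" in new and new["g0"].cds_exons == [(0, 300)]
        assert log[0]["assignee"] == "g0"

    def test_pure_addition(self, annotation):
        rec = CorrectionRecord("add:nX", None,
                               [GeneModel("nX", "s1", "+", [(90000, 90300)])])
        new, log = apply_corrections(annotation, [rec])
        assert len(new) == 11 and log[0]["old_id"] == ""

    def test_empty_corrections_is_identity(self, annotation):
        new, log = apply_corrections(annotation, [])
        assert new == annotation and log == []

    def test_missing_target_rejected(self, annotation):
        rec = CorrectionRecord("replace:nope", "nope", [])
        with pytest.raises(KeyError):
            apply_corrections(annotation, [rec])

    def test_double_deletion_rejected(self, annotation):
        recs = [CorrectionRecord("r1", "g0", []),
                CorrectionRecord("r2", "g0", [])]
        with pytest.raises(ValueError):
            apply_corrections(annotation, recs)

    def test_order_independent_for_non_conflicting(self, annotation):
        recs = [CorrectionRecord("r1", "g0",
                                 [GeneModel("n1", "s1", "+", [(0, 300)])],
                                 inherited_id_assignee="n1"),
                CorrectionRecord("r2", None,
                                 [GeneModel("n2", "s1", "+", [(95000, 95300)])])]
        outcomes = [apply_corrections(annotation, list(p))[0]
                    for p in itertools.permutations(recs)]
        assert all(o == outcomes[0] for o in outcomes)


class TestIdentifierAndCdsConservation:
    def test_every_replaced_id_survives_exactly_once(self, standard_result):
        curated_ids = set(standard_result.curated_annotation)
        replaced = [c.old_gene_id for c in standard_result.corrections
                    if c.old_gene_id is not None]
        assert len(replaced) == len(set(replaced))
        for old_id in replaced:
            assert old_id in curated_ids

    def test_cds_coverage_never_decreases(self, standard_bundle, standard_result):
        truth = standard_bundle.truth_annotation
        before = cds_coverage_nt(truth, standard_bundle.corrupted_annotation)
        after = cds_coverage_nt(truth, standard_result.curated_annotation)
        assert after >= before

    def test_curated_gene_count_equals_truth(self, standard_bundle, standard_result):
        assert len(standard_result.curated_annotation) == \
               len(standard_bundle.truth_annotation)

    def test_model_from_transcript_promotes_exons_to_cds(self):
        t = _t("tZ", [(0, 120), (200, 320)])
        m = model_from_transcript(t)
        assert m.cds_exons == [(0, 120), (200, 320)]
        assert m.source == "transcript_evidence"
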