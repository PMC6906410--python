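import glob
import os

import pytest

from annocure.io import GeneModel
from annocure.simulate import (InfeasibleConfig, ScenarioConfig,
                               emit_hit_tables, generate_scenario,
                               inject_fusion, inject_utr_hidden, load_bundle)


def spans_two_cds_sets(model, truth_models):
    """Brute-force check: does this model's CDS cover the CDS of >=2 truth genes?"""
    covered = 0
    for t in truth_models.values():
        if t.scaffold != model.scaffold:
            continue
        hit = all(any(ms <= s and e <= me for ms, me in model.cds_exons)
                  for s, e in t.cds_exons)
        if hit:
            covered += 1
    return covered >= 2


class TestGenerateScenario:
    def test_identity_when_no_errors_configured(self):
        b = generate_scenario(ScenarioConfig(
            n_genes=10, n_scaffolds=1, fusion_count=0, missing_count=0,
            utr_hidden_count=0, misannotation_count=0, hit_noise=0.0, seed=5))
        assert b.corrupted_annotation == b.truth_annotation

    def test_configured_fusion_count_realised(self):
        b = generate_scenario(ScenarioConfig(
            n_genes=20, n_scaffolds=1, fusion_count=3, missing_count=0,
            utr_hidden_count=0, misannotation_count=0, seed=7))
        n_spanning = sum(spans_two_cds_sets(m, b.truth_annotation)
                         for m in b.corrupted_annotation.values())
        assert n_spanning == 3
        assert len(b.truth.fused_models) == 3

    def test_error_conservation_counts(self, standard_bundle):
        b = standard_bundle
        cfg = b.config
        absent = set(b.truth_annotation) - set(b.corrupted_annotation)
        assert len(absent) == (cfg.missing_count + cfg.utr_hidden_count
                               + cfg.fusion_count)  # fusions drop one id each
        assert len(b.truth.genes_with("deleted")) == cfg.missing_count
        assert len(b.truth.genes_with("utr_hidden_in:")) == cfg.utr_hidden_count
        assert len(b.truth.genes_with("frame_corrupted")) == cfg.misannotation_count
        assert len(b.truth.fused_models) == cfg.fusion_count

    def test_one_correct_transcript_per_truth_gene(self, standard_bundle):
        tids = {t.transcript_id for t in standard_bundle.transcripts}
        assert tids == {f"t_{g}" for g in standard_bundle.truth_annotation}
        for t in standard_bundle.transcripts:
            truth = standard_bundle.truth_annotation[t.gene_id]
            assert t.exons == truth.cds_exons
            assert t.orf_protein == standard_bundle.truth_proteins[t.gene_id]

    def test_byte_identical_bundles_for_same_seed(self, tmp_path):
        cfg = ScenarioConfig(n_genes=30, n_scaffolds=2, fusion_count=2,
                             missing_count=2, utr_hidden_count=1,
                             misannotation_count=1, hit_noise=0.3, seed=7)
        d1, d2 = tmp_path / "b1", tmp_path / "b2"
        generate_scenario(cfg).write(d1)
        generate_scenario(cfg).write(d2)
        files = sorted(os.path.relpath(p, d1)
                       for p in glob.glob(str(d1 / "**/*"), recursive=True)
                       if os.path.isfile(p))
        assert files
        for f in files:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_bundle_round_trips_through_disk(self, tmp_path, small_bundle):
        small_bundle.write(tmp_path / "b")
        back = load_bundle(tmp_path / "b")
        assert back.truth.error_class == small_bundle.truth.error_class
        assert back.truth.ortholog_map == small_bundle.truth.ortholog_map
        assert set(back.corrupted_annotation) == set(small_bundle.corrupted_annotation)
        assert {n: len(h) for n, h in back.hit_tables.items()} == \
               {n: len(h) for n, h in small_bundle.hit_tables.items()}

    @pytest.mark.parametrize("kwargs,message", [
        (dict(n_genes=10, fusion_count=3, missing_count=4, utr_hidden_count=2,
              misannotation_count=2), "error counts"),
        (dict(n_genes=10, fusion_count=-1), "non-negative"),
        (dict(n_genes=10, hit_noise=1.5), "hit_noise"),
        (dict(n_genes=4, n_scaffolds=4, fusion_count=2), "adjacent"),
    ])
    def test_infeasible_configs_name_the_constraint(self, kwargs, message):
        defaults = dict(fusion_count=0, missing_count=0, utr_hidden_count=0,
                        misannotation_count=0, seed=1)
        with pytest.raises(InfeasibleConfig, match=message):
            generate_scenario(ScenarioConfig(**{**defaults, **kwargs}))


class TestInjectFusion:
    def test_union_of_cds_exons(self):
        a = GeneModel("a", "s", "+", [(100, 200)])
        b = GeneModel("b", "s", "+", [(300, 400)])
        fused = inject_fusion(a, b)
        assert fused.cds_exons == [(100, 200), (300, 400)]
        assert fused.span == (100, 400)
        assert fused.gene_id == "a"

    def test_opposite_strands_rejected(self):
        a = GeneModel("a", "s", "+", [(100, 200)])
        b = GeneModel("b", "s", "-", [(300, 400)])
        with pytest.raises(ValueError):
            inject_fusion(a, b)

    def test_fused_protein_is_concatenation(self, standard_bundle):
        for fid, (a, b) in standard_bundle.truth.fused_models.items():
            assert standard_bundle.annotation_proteins[fid] == \
                   (standard_bundle.truth_proteins[a]
                    + standard_bundle.truth_proteins[b])


class TestInjectUtrHidden:
    def test_victim_exons_become_host_utr(self):
        host = GeneModel("h", "s", "+", [(1000, 1600)])
        victim = GeneModel("v", "s", "+", [(50, 120), (300, 400)])
        new = inject_utr_hidden(host, victim)
        assert [(s, e) for s, e, k in new.utr_exons] == [(50, 120), (300, 400)]
        assert all(k == "five_prime" for _, _, k in new.utr_exons)
        assert new.cds_exons == host.cds_exons

    def test_truth_annotation_retains_victims(self, standard_bundle):
        for victim in standard_bundle.truth.utr_hosts:
            assert victim in standard_bundle.truth_annotation
            assert victim not in standard_bundle.corrupted_annotation

    def test_evidence_still_contains_victim_transcript(self, standard_bundle):
        tids = {t.transcript_id for t in standard_bundle.transcripts}
        for victim in standard_bundle.truth.utr_hosts:
            assert f"t_{victim}" in tids


class TestEmitHitTables:
    PROT_Q = {"q1": "M" * 100, "q2": "K" * 80}
    PROT_S = {"s1": "M" * 100, "s2": "K" * 80}

    def test_no_noise_keeps_every_true_pair_below_threshold(self):
        tables = emit_hit_tables({"q1": "s1", "q2": "s2"},
                                 self.PROT_Q, self.PROT_S, hit_noise=0.0, seed=1)
        assert {(h.query_id, h.subject_id) for h in tables["forward"]} == \
               {("q1", "s1"), ("q2", "s2")}
        assert all(h.e_value < 1e-5 for h in tables["forward"] + tables["reverse"])

    def test_fused_subject_hits_both_queries(self):
        prot_s = {"fused": "M" * 100 + "K" * 80}
        tables = emit_hit_tables({"q1": "fused", "q2": "fused"},
                                 self.PROT_Q, prot_s, hit_noise=0.0, seed=1)
        subjects = {(h.query_id, h.sstart) for h in tables["forward"]}
        assert subjects == {("q1", 1), ("q2", 101)}

    def test_self_searches_contain_identity_hits(self):
        tables = emit_hit_tables({"q1": "s1"}, self.PROT_Q, self.PROT_S, seed=1)
        ids = {(h.query_id, h.subject_id) for h in tables["query_self"]}
        assert ids == {("q1", "q1"), ("q2", "q2")}
        assert all(h.percent_identity == 100.0 for h in tables["query_self"])

    def test_full_noise_is_deterministic_given_seed(self):
        t1 = emit_hit_tables({"q1": "s1", "q2": "s2"}, self.PROT_Q, self.PROT_S,
                             hit_noise=1.0, seed=9)
        t2 = emit_hit_tables({"q1": "s1", "q2": "s2"}, self.PROT_Q, self.PROT_S,
                             hit_noise=1.0, seed=9)
        assert t1 == t2
        surviving = t1["forward"] + t1["reverse"]
        assert all(1e-5 <= h.e_value < 1e-3 for h in surviving)

    def test_unknown_identifier_rejected(self):
        with pytest.raises(KeyError):
            emit_hit_tables({"ghost": "s1"}, self.PROT_Q, self.PROT_S, seed=1)


def test_noise_moves_evalues_into_weak_band(noisy_bundle):
    band = [h for h in noisy_bundle.hit_tables["ref_vs_annotation"]
            if 1e-5 <= h.e_value < 1e-3]
    assert band  # at 15% noise some hits must land in the borderline band
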