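"""Classifier tests, anchored by an independent hand-written truth table."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgene_atlas.annotation_io import DomainEvidence, GenomeAnnotation
from rgene_atlas.architecture_classifier import (
    ClassifierConfig,
    call_nbs_status,
    classify_all,
    classify_gene,
    kinase2_diagnostic,
)
from rgene_atlas.synthetic_data import TABLE1_CLASS_COUNTS

from conftest import evidence, make_genes

CFG = ClassifierConfig()


def truth_table_code(nbs, tir, cc, lrr, similarity, kinase2):
    """Independent re-statement of the letter-code rules as one lookup.

    Written directly from the classification contract, not by calling the
    classifier: partials first, then N-terminal domain evidence, then the
    clade-free fallback chain (kinase-2 residue), else CC-side default.
    """
    if nbs != "full":
        if nbs == "partial" or similarity:
            return "P"
        return "unclassified"
    if tir:  # TIR beats CC on conflict
        return "TNL" if lrr else "TN"
    if cc:
        return "CNL" if lrr else "CN"
    tir_side = kinase2 == "D"
    if lrr:
        return "NL_TIR" if tir_side else "NL_CC"
    return "N_TIR" if tir_side else "N_CC"


class TestNbsStatus:
    def test_strong_hit_with_coverage_is_full(self):
        assert call_nbs_status(evidence(nbs_e=1e-30, nbs_cov=0.95), CFG) == "full"

    def test_low_coverage_is_partial(self):
        assert call_nbs_status(evidence(nbs_e=1e-5, nbs_cov=0.40), CFG) == "partial"

    def test_no_hit_is_absent(self):
        assert call_nbs_status(evidence(nbs=False), CFG) == "absent"

    def test_evalue_threshold_is_inclusive(self):
        assert call_nbs_status(evidence(nbs_e=0.01, nbs_cov=0.95), CFG) == "full"
        assert call_nbs_status(evidence(nbs_e=0.011, nbs_cov=0.95), CFG) == "absent"

    @given(e1=st.floats(min_value=1e-50, max_value=1.0),
           e2=st.floats(min_value=1e-50, max_value=1.0),
           cov=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_weakening_pass_threshold_never_demotes(self, e1, e2, cov):
        """Raising pass_evalue may only move genes toward 'full'."""
        lo, hi = sorted([e1, e2])
        ev = evidence(nbs_e=e1, nbs_cov=cov)
        order = {"absent": 0, "partial": 1, "full": 2}
        strict = call_nbs_status(ev, ClassifierConfig(pass_evalue=lo))
        loose = call_nbs_status(ev, ClassifierConfig(pass_evalue=hi))
        assert order[loose] >= order[strict]


class TestKinase2Diagnostic:
    @pytest.mark.parametrize("residue,expected", [
        ("D", "TIR-type"), ("W", "CC-type"), ("A", "indeterminate"),
        (None, "indeterminate"),
    ])
    def test_diagnostic_residues(self, residue, expected):
        assert kinase2_diagnostic(residue, CFG) == expected


class TestClassifyGene:
    def test_tir_nbs_lrr_is_tnl(self):
        call = classify_gene(evidence(tir=True, lrr=True), None, CFG)
        assert call.letter_code == "TNL" and call.family == "TNL_type"
        assert call.nterm_type_source == "domain"

    def test_cc_nbs_without_lrr_is_cn(self):
        call = classify_gene(evidence(cc=True), None, CFG)
        assert call.letter_code == "CN" and call.family == "CNL_type"

    def test_bare_nbs_typed_by_kinase2_when_no_clade(self):
        call = classify_gene(evidence(kinase2="W"), None, CFG)
        assert call.letter_code == "N_CC" and call.nterm_type_source == "kinase2"

    def test_clade_takes_precedence_over_kinase2(self):
        call = classify_gene(evidence(kinase2="W"), "TIR", CFG)
        assert call.letter_code == "N_TIR" and call.nterm_type_source == "clade"

    def test_rpw8_reported_in_cnl_family_with_flag(self):
        call = classify_gene(evidence(rpw8=True, lrr=True), None, CFG)
        assert call.family == "CNL_type" and call.rpw8
        assert call.nterm_type == "RPW8" and call.letter_code == "CNL"

    def test_tir_cc_conflict_resolved_by_precedence_with_flag(self):
        call = classify_gene(evidence(tir=True, cc=True, lrr=True), None, CFG)
        assert call.letter_code == "TNL" and call.conflict

    def test_partial_with_similarity_is_p(self):
        call = classify_gene(evidence(nbs=False, similarity=True), None, CFG)
        assert call.letter_code == "P" and call.family == "partial"

    def test_no_evidence_is_unclassified(self):
        call = classify_gene(DomainEvidence(gene_id="g"), None, CFG)
        assert call.letter_code == "unclassified" and call.family == "none"

    def test_exhaustive_truth_table(self):
        """Every evidence combination yields exactly the tabulated code."""
        combos = itertools.product(
            ["full", "partial", "absent"],       # NBS status
            [False, True], [False, True],        # TIR, CC
            [False, True],                       # LRR
            [False, True],                       # similarity hit
            ["D", "W", None],                    # kinase-2 residue
        )
        for nbs, tir, cc, lrr, sim, k2 in combos:
            ev = evidence(
                nbs=nbs != "absent",
                nbs_e=1e-30, nbs_cov=0.95 if nbs == "full" else 0.4,
                tir=tir, cc=cc, lrr=lrr, similarity=sim, kinase2=k2,
            )
            call = classify_gene(ev, None, CFG)
            expected = truth_table_code(nbs, tir, cc, lrr, sim, k2)
            assert call.letter_code == expected, (nbs, tir, cc, lrr, sim, k2)
            # letter code P if and only if the family is partial
            assert (call.letter_code == "P") == (call.family == "partial")
            if call.letter_code in ("N_TIR", "NL_TIR", "TNL", "TN"):
                assert call.nterm_type == "TIR"

    def test_phylogeny_eligibility_tracks_full_nbs(self):
        assert classify_gene(evidence(), None, CFG).phylogeny_eligible
        assert not classify_gene(evidence(nbs_cov=0.5, similarity=True),
                                 None, CFG).phylogeny_eligible


class TestClassifyAll:
    def test_unknown_evidence_gene_is_fatal(self):
        ann = GenomeAnnotation(make_genes([1000]))
        with pytest.raises(KeyError, match="ghost"):
            classify_all(ann, {"ghost": DomainEvidence(gene_id="ghost")})

    def test_empty_evidence_classifies_everything_unclassified(self):
        ann = GenomeAnnotation(make_genes([1000, 5000, 9000]))
        calls = classify_all(ann, {})
        assert [c.letter_code for c in calls] == ["unclassified"] * 3

    def test_exclusion_list_suppresses_evidence(self):
        ann = GenomeAnnotation(make_genes([1000]))
        calls = classify_all(ann, {"g1": evidence(gene_id="g1", cc=True, lrr=True)},
                             exclude=["g1"])
        assert calls[0].letter_code == "unclassified"

    def test_families_partition_classified_genes(self, small_synth):
        from rgene_atlas.annotation_io import (
            read_domain_evidence,
            read_gene_models,
            read_simple_map,
        )

        cfg, paths, truth = small_synth
        ann = read_gene_models(paths.gff, [f"chr{i+1}" for i in range(cfg.n_chromosomes)])
        ev = read_domain_evidence(paths.domains, paths.cc, paths.similarity,
                                  paths.kinase2)
        calls = classify_all(ann, ev, read_simple_map(paths.clades, "clade_label"))
        by_family = {}
        for c in calls:
            by_family.setdefault(c.family, []).append(c)
        n_classified = sum(len(v) for f, v in by_family.items() if f != "none")
        assert n_classified == cfg.n_nbs
        # generator truth is recovered gene by gene
        for c in calls:
            expected = truth["codes"].get(c.gene_id, "unclassified")
            assert c.letter_code == expected


def test_config_rejects_overlapping_diagnostic_sets():
    with pytest.raises(ValueError):
        ClassifierConfig(tir_diag_residues=frozenset("DW"),
                        cc_diag_residues=frozenset("W"))


def test_table1_proportions_recovered_from_large_synthetic(tmp_path):
    """Full-scale generator + classifier reproduce the planted class counts."""
    from rgene_atlas.annotation_io import (
        read_domain_evidence,
        read_simple_map,
    )
    from rgene_atlas.architecture_classifier import classify_gene
    from rgene_atlas.synthetic_data import SynthConfig, generate

    cfg = SynthConfig(seed=5, n_chromosomes=6, chromosome_length_bp=15_000_000,
                      n_genes_total=4_000, n_nbs=327)
    paths, truth = generate(cfg, tmp_path)
    ev = read_domain_evidence(paths.domains, paths.cc, paths.similarity,
                              paths.kinase2)
    clades = read_simple_map(paths.clades, "clade_label")
    counts = {}
    for gid, e in ev.items():
        code = classify_gene(e, clades.get(gid), CFG).letter_code
        counts[code] = counts.get(code, 0) + 1
    assert counts == TABLE1_CLASS_COUNTS
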