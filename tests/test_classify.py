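"""Architecture rules, subtype calling, nearest-reference, decapod names."""

import pytest

from crustakin.classify import (
    NameRegistry, ReferencePanel, assign_decapod_name, classify_family,
    classify_pka_c_isoform, classify_pka_r, classify_record, nearest_reference,
)
from crustakin.core_io import DomainAnnotation, SequenceRecord
from crustakin.simulate import build_templates


def ann(seq_id, name, start, end, complete=True):
    return DomainAnnotation(seq_id=seq_id, domain_name=name, start=start,
                            end=end, complete=complete)


def template_record(label, seq_id=None):
    tpl = build_templates()[label]
    rec = SequenceRecord(id=seq_id or label, residues=tpl.residues,
                         species="Synthspecies_01", phylum="Arthropoda")
    anns = [ann(rec.id, n, s, e) for n, s, e in tpl.domains]
    return rec, anns


class TestFamilyRules:
    def test_c1_before_c2_is_conventional_pkc(self):
        rec = SequenceRecord(id="s", residues="M" * 650)
        anns = [ann("s", "C1", 40, 90), ann("s", "C2", 120, 210),
                ann("s", "kinase", 350, 600)]
        assert classify_family(rec, anns).family == "cPKC"

    def test_c2_before_c1_is_novel_pkc(self):
        rec = SequenceRecord(id="s", residues="M" * 700)
        anns = [ann("s", "C2", 30, 130), ann("s", "C1", 180, 240),
                ann("s", "kinase", 350, 600)]
        assert classify_family(rec, anns).family == "nPKC"

    def test_hr1_repeats_make_pkn(self):
        rec = SequenceRecord(id="s", residues="M" * 900)
        anns = [ann("s", "HR1", 10, 80), ann("s", "HR1", 100, 170),
                ann("s", "HR1", 190, 260), ann("s", "C2", 300, 400),
                ann("s", "kinase", 600, 850)]
        result = classify_family(rec, anns)
        assert result.family == "PKN"

    def test_pb1_single_c1_kinase_is_atypical(self):
        rec = SequenceRecord(id="s", residues="M" * 550)
        anns = [ann("s", "PB1", 20, 100), ann("s", "C1", 130, 180),
                ann("s", "kinase", 250, 500)]
        assert classify_family(rec, anns).family == "aPKC"

    def test_two_camp_domains_make_regulatory(self):
        rec = SequenceRecord(id="s", residues="M" * 400)
        anns = [ann("s", "cAMP_binding", 120, 230),
                ann("s", "cAMP_binding", 250, 360)]
        result = classify_family(rec, anns)
        assert result.family == "PKA-R"
        # truncated subunit: missing docking domain noted in evidence
        assert any("dimerization" in o for _, o in result.evidence)

    def test_kinase_only_with_mgn_start_is_catalytic(self):
        rec = SequenceRecord(id="s", residues="MGNAAATK" + "L" * 292)
        result = classify_family(rec, [ann("s", "kinase", 60, 290)])
        assert result.family == "PKA-C"

    def test_kinase_only_without_evidence_is_unknown(self):
        rec = SequenceRecord(id="s", residues="QQQQQQQQ" + "L" * 292)
        result = classify_family(rec, [ann("s", "kinase", 60, 290)])
        assert result.family == "unknown"

    def test_contradictory_overlapping_annotations_error(self):
        rec = SequenceRecord(id="s", residues="M" * 400)
        anns = [ann("s", "C1", 40, 140), ann("s", "C2", 50, 130),
                ann("s", "kinase", 200, 390)]
        with pytest.raises(ValueError, match="contradictory"):
            classify_family(rec, anns)

    def test_invariant_to_annotation_order(self):
        rec, anns = template_record("PKN")
        fwd = classify_family(rec, anns).family
        rev = classify_family(rec, list(reversed(anns))).family
        assert fwd == rev == "PKN"


class TestPkaCSubtypes:
    def test_mgn_start_is_ancestral_c1(self):
        rec, anns = template_record("PKA-C_1")
        assert classify_pka_c_isoform(rec, anns) == "C_1"

    def test_glycine_tract_wins_priority(self):
        rec, anns = template_record("PKA-C_GLY")
        assert classify_pka_c_isoform(rec, anns) == "C_GLY"

    def test_matl_motif_is_decapod_d1(self):
        rec, anns = template_record("PKA-C_D1")
        assert classify_pka_c_isoform(rec, anns) == "C_D1"


class TestPkaRSubtypes:
    def test_rrvs_linker_with_gly_tract_is_rii_gly(self):
        rec, anns = template_record("PKA-RII_GLY")
        assert classify_pka_r(rec, anns) == "RII_GLY"

    def test_pseudosubstrate_linker_is_ri(self):
        rec, anns = template_record("PKA-RI")
        assert classify_pka_r(rec, anns) == "RI"

    def test_ri_call_never_hides_rrxs(self):
        # a linker with both motifs must surface as unresolved, not RI
        rec, anns = template_record("PKA-RI")
        residues = list(rec.residues)
        residues[60:64] = "RRVS"  # inject substrate motif into the linker
        rec2 = SequenceRecord(id=rec.id, residues="".join(residues))
        assert classify_pka_r(rec2, anns) == "R-unresolved"


class TestNearestReference:
    def _panel(self):
        delta, _ = template_record("nPKC-delta-like", "ex_delta")
        eps, _ = template_record("nPKC-epsilon-like", "ex_eps")
        return ReferencePanel([(delta, "nPKC-delta-like"),
                               (eps, "nPKC-epsilon-like")])

    def test_exact_exemplar_match_scores_100(self):
        rec, _ = template_record("nPKC-delta-like")
        label, ident, sim = nearest_reference(rec, self._panel())
        assert label == "nPKC-delta-like"
        assert ident == pytest.approx(100.0)
        assert sim == pytest.approx(100.0)

    def test_mutated_record_recovers_its_exemplar(self):
        from crustakin.simulate import SimSpec, generate_dataset
        records, anns, truth = generate_dataset(SimSpec(
            classes=("nPKC-delta-like", "nPKC-epsilon-like"),
            n_species=5, seed=42))
        panel = self._panel()
        for rec in records:
            label, _, _ = nearest_reference(rec, panel)
            assert label == truth[rec.id].family

    def test_tie_breaks_to_lexicographic_exemplar(self):
        a = SequenceRecord(id="ex_a", residues="MGNAAAK")
        b = SequenceRecord(id="ex_b", residues="MGNAAAK")
        panel = ReferencePanel([(b, "B"), (a, "A")])
        rec = SequenceRecord(id="q", residues="MGNAAAK")
        label, _, _ = nearest_reference(rec, panel)
        assert label == "A"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel([])


class TestDecapodNames:
    def _result(self, family, subtype=""):
        from crustakin.classify import ClassificationResult
        r = ClassificationResult(seq_id="s", family=family, subtype=subtype)
        r.note("architecture", "test")
        return r

    def test_first_conventional_pkc(self):
        registry = NameRegistry()
        assert assign_decapod_name(
            self._result("cPKC"), "C. maenas", registry) == "cPKC_D1"

    def test_pkn_ordinals_accumulate(self):
        registry = NameRegistry()
        names = [assign_decapod_name(self._result("PKN"), "sp", registry)
                 for _ in range(3)]
        assert names == ["PKN_D1", "PKN_D2", "PKN_D3"]

    def test_second_glycine_rich_catalytic(self):
        registry = NameRegistry()
        first = assign_decapod_name(
            self._result("PKA-C", "C_GLY"), "sp", registry)
        second = assign_decapod_name(
            self._result("PKA-C", "C_GLY"), "sp", registry)
        assert (first, second) == ("PKA-C_GLY1", "PKA-C_GLY2")

    def test_novel_subfamilies_carry_greek_suffix(self):
        registry = NameRegistry()
        assert assign_decapod_name(
            self._result("nPKC-delta-like"), "sp", registry) == "nPKC_D1δ"
        assert assign_decapod_name(
            self._result("nPKC-epsilon-like"), "sp", registry) == "nPKC_D1ε"

    def test_ordinals_are_per_species(self):
        registry = NameRegistry()
        assert assign_decapod_name(
            self._result("aPKC"), "sp1", registry) == "aPKC_D1"
        assert assign_decapod_name(
            self._result("aPKC"), "sp2", registry) == "aPKC_D1"

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            assign_decapod_name(self._result("unknown"), "sp", NameRegistry())

    def test_no_duplicate_names_within_species(self):
        registry = NameRegistry()
        seen = set()
        for family in ("cPKC", "cPKC", "aPKC", "PKN", "PKN"):
            name = assign_decapod_name(self._result(family), "sp", registry)
            assert name not in seen
            seen.add(name)


class TestSharedCoreInvariant:
    def test_isoforms_of_one_species_share_family(self):
        """PKA-C isoforms differ only N-terminally; all classify PKA-C."""
        from crustakin.simulate import SimSpec, generate_dataset
        records, anns, truth = generate_dataset(SimSpec(
            classes=("PKA-C_1", "PKA-C_GLY", "PKA-C_D1"),
            n_species=4, seed=7))
        for rec in records:
            a = [x for x in anns if x.seq_id == rec.id]
            assert classify_record(rec, a).family == "PKA-C"
        # identical catalytic core within a species
        by_species = {}
        for rec in records:
            kin = next(x for x in anns
                       if x.seq_id == rec.id and x.domain_name == "kinase")
            core = rec.residues[kin.start - 1:]
            by_species.setdefault(rec.species, set()).add(core)
        assert all(len(cores) == 1 for cores in by_species.values())
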