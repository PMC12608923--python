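"""Motif grammar, scanning, consensus, AI-site typing, glycine tracts."""

import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from crustakin.core_io import Alignment, DomainAnnotation, SequenceRecord
from crustakin.motifs import (
    MotifSyntaxError, STANDARD_PATTERNS, classify_ai_site, compile_motif,
    consensus, find_motif, glycine_rich_regions, is_gly_rich_nterm,
    motif_report, nterm_region,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def regex_oracle(pattern: str, residues: str, anchored: bool = False):
    """Independent scanner: translate the bracket grammar to a regex."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "x":
            out.append(f"[{AA20}]")
            i += 1
        elif ch == "[":
            close = pattern.index("]", i)
            out.append("[" + pattern[i + 1:close].replace("/", "") + "]")
            i = close + 1
        else:
            out.append(re.escape(ch))
            i += 1
    body = "".join(out)
    if anchored:
        m = re.match(body, residues)
        return [1] if m else []
    return [m.start() + 1
            for m in re.finditer(f"(?={body})", residues)]


class TestCompile:
    def test_chordate_start_motif(self):
        motif = compile_motif("MGNxxxx[K/R]")
        assert len(motif) == 8
        assert motif.compiled[7] == frozenset("KR")
        assert motif.compiled[3] == frozenset(AA20)

    def test_decapod_matl_motif(self):
        motif = compile_motif("MATL[M/T/A]A[F/T]")
        assert len(motif) == 7
        assert motif.compiled[4] == frozenset("MTA")

    def test_lone_wildcard(self):
        assert compile_motif("x").compiled[0] == frozenset(AA20)

    @pytest.mark.parametrize("bad", ["MGN[K/R", "M[]K", "mgn", "M[K//R]", ""])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(MotifSyntaxError):
            compile_motif(bad)


class TestFind:
    def test_anchored_invertebrate_start(self):
        rec = SequenceRecord(id="s", residues="MGNAAATKLLL")
        motif = compile_motif("MGNxxxxK", anchored=True)
        hits = find_motif(rec, motif)
        assert [(h.start, h.end, h.matched) for h in hits] == \
            [(1, 8, "MGNAAATK")]

    def test_fxxxw_interior_match(self):
        rec = SequenceRecord(id="s", residues="AFAAAWA")
        hits = find_motif(rec, "FxxxW")
        assert [(h.start, h.end) for h in hits] == [(2, 6)]

    def test_alternation_widens_anchored_match(self):
        rec = SequenceRecord(id="s", residues="MGNAAATR")
        strict = compile_motif("MGNxxxxK", anchored=True)
        wide = compile_motif("MGNxxxx[K/R]", anchored=True)
        assert find_motif(rec, strict) == []
        assert len(find_motif(rec, wide)) == 1

    def test_x_in_sequence_never_matches(self):
        rec = SequenceRecord(id="s", residues="FAXAW")
        assert find_motif(rec, "FxxxW") == []  # X fails the wildcard too

    def test_region_restricts_search(self):
        rec = SequenceRecord(id="s", residues="FAAAWAAFAAAW")
        assert len(find_motif(rec, "FxxxW")) == 2
        assert len(find_motif(rec, "FxxxW", region=(1, 6))) == 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA20 + "X", min_size=1, max_size=50),
           st.sampled_from(STANDARD_PATTERNS))
    def test_matches_regex_oracle(self, residues, pattern):
        rec = SequenceRecord(id="s", residues=residues)
        anchored = pattern in ("MGNxxxx[K/R]", "MGNxxxxK")
        motif = compile_motif(pattern, anchored=anchored)
        got = [h.start for h in find_motif(rec, motif)]
        assert got == regex_oracle(pattern, residues, anchored)


class TestAISite:
    def test_rii_substrate_site(self):
        rec = SequenceRecord(id="s", residues="AAEIRRVSVAA")
        assert classify_ai_site(rec) == "RII"

    def test_ri_pseudosubstrate_site(self):
        rec = SequenceRecord(id="s", residues="AAETRRRGAAA")
        assert classify_ai_site(rec) == "RI"  # RRxG at the RRRG offset

    def test_no_motif_is_none(self):
        rec = SequenceRecord(id="s", residues="KAQSA")
        assert classify_ai_site(rec) == "none"

    def test_both_motifs_ambiguous(self):
        rec = SequenceRecord(id="s", residues="RRAGAARRVS")
        assert classify_ai_site(rec) == "ambiguous"

    def test_linker_restriction(self):
        rec = SequenceRecord(id="s", residues="RRVSAAAAAARRAG")
        assert classify_ai_site(rec, linker=(1, 5)) == "RII"
        assert classify_ai_site(rec, linker=(6, 14)) == "RI"


class TestNtermRegion:
    def test_region_ends_before_first_core_domain(self, pka_c1_record):
        anns = [DomainAnnotation(seq_id="c1", domain_name="kinase",
                                 start=120, end=200, complete=True)]
        assert nterm_region(pka_c1_record, anns) == (1, 119, False)

    def test_domain_at_position_one_gives_empty_region(self, pka_c1_record):
        anns = [DomainAnnotation(seq_id="c1", domain_name="kinase",
                                 start=1, end=200, complete=True)]
        start, end, empty = nterm_region(pka_c1_record, anns)
        assert empty

    def test_min_over_multiple_core_domains(self):
        rec = SequenceRecord(id="r", residues="M" * 400)
        anns = [DomainAnnotation(seq_id="r", domain_name="cAMP_binding",
                                 start=150, end=260, complete=True),
                DomainAnnotation(seq_id="r", domain_name="cAMP_binding",
                                 start=280, end=390, complete=True)]
        assert nterm_region(rec, anns) == (1, 149, False)

    def test_no_core_domain_errors(self, pka_c1_record):
        with pytest.raises(ValueError, match="domain"):
            nterm_region(pka_c1_record, [])


class TestGlycineRich:
    def test_dense_tract_detected(self):
        tract = "GGSGGGAGGGSGGGAGGGSGGGAGG"
        assert tract.count("G") == 19 and len(tract) == 25
        rec = SequenceRecord(id="s", residues=tract + "M" * 100)
        regions, warn = glycine_rich_regions(rec, search_span=(1, 25))
        assert not warn
        assert regions[0].gly_fraction == pytest.approx(19 / 25)

    def test_poly_alanine_is_not_gly_rich(self):
        rec = SequenceRecord(id="s", residues="A" * 60 + "M" * 100)
        anns = [DomainAnnotation(seq_id="s", domain_name="kinase",
                                 start=61, end=160, complete=True)]
        assert not is_gly_rich_nterm(rec, anns)

    def test_window_longer_than_span_warns(self):
        rec = SequenceRecord(id="s", residues="G" * 10 + "M" * 50)
        regions, warn = glycine_rich_regions(rec, window=25, search_span=(1, 10))
        assert regions == [] and warn

    def test_lowering_min_frac_keeps_regions(self):
        rng = random.Random(13)
        residues = "".join(
            rng.choice("G" if rng.random() < 0.4 else AA20) for _ in range(200))
        rec = SequenceRecord(id="s", residues=residues)
        strict, _ = glycine_rich_regions(rec, min_frac=0.5)
        loose, _ = glycine_rich_regions(rec, min_frac=0.3)
        for region in strict:  # every strict region survives, possibly merged
            assert any(l.start <= region.start and l.end >= region.end
                       for l in loose)


class TestConsensus:
    def test_unanimous_column(self):
        aln = Alignment(ids=["a", "b"], rows=["G", "G"])
        assert consensus(aln) == "G"

    def test_even_split_emits_alternation(self):
        rows = ["K"] * 10 + ["R"] * 10
        aln = Alignment(ids=[f"s{i}" for i in range(20)], rows=rows)
        assert consensus(aln) == "[K/R]"

    def test_high_diversity_emits_wildcard(self):
        aln = Alignment(ids=[f"s{i}" for i in range(20)], rows=list(AA20))
        assert consensus(aln) == "x"

    def test_gap_majority_emits_gap(self):
        aln = Alignment(ids=["a", "b", "c"], rows=["A-", "--", "A-"])
        assert consensus(aln) == "A-"

    def test_permutation_invariant(self):
        rng = random.Random(21)
        rows = ["MGNAA", "MGNAK", "MGNGK", "MSNAK"]
        ids = ["a", "b", "c", "d"]
        base = consensus(Alignment(ids=ids, rows=rows))
        for _ in range(5):
            perm = rng.sample(range(4), 4)
            shuffled = Alignment(ids=[ids[i] for i in perm],
                                 rows=[rows[i] for i in perm])
            assert consensus(shuffled) == base

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            consensus(Alignment(ids=[], rows=[]))


class TestMotifReport:
    def test_constructed_catalytic_nterm(self):
        rec = SequenceRecord(id="s", residues="MGNAAATKFAQLWGG" + "L" * 50)
        report = motif_report(rec)
        assert report["G2"] is True
        assert report["MGNxxxxK"] == 1
        assert report["FxxxW"] == 9

    def test_chordate_exemplar_start(self):
        rec = SequenceRecord(id="s", residues="MGNAAAAKK" + "L" * 20)
        assert motif_report(rec)["MGNxxxx[K/R]"] == 1

    def test_motif_free_sequence_all_absent(self):
        rec = SequenceRecord(id="s", residues="PPPPQQQQPPPPQQQQ")
        report = motif_report(rec)
        assert all(report[p] is None for p in STANDARD_PATTERNS)
        assert report["G2"] is False
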