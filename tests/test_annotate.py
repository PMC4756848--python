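"""Annotation grammar, structure diffing, conservation, orchestration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirimpact.annotate import (
    Annotation,
    analyze_variant,
    annotate_changes,
    choose_reference_boundary,
    conservation,
    diff_structures,
    highest_impact,
    locate_variant,
)
from mirimpact.fold import MockFold, mock_fold_result
from mirimpact.mirna_db import Mature, MiRNAGene, RegionModel, Segment, RefBoundary
from mirimpact.variant_io import GenomicVariant


class TestLocateVariant:
    def test_mature5p_position_from_arm_boundary(self, mir125_model):
        # 8 nt into mature5p (gene-relative 15..39)
        assert str(locate_variant(mir125_model, 22, 23)) == "mature5p(a+8)"

    def test_lower_arm_counts_upstream_of_mature(self, mir125_model):
        assert str(locate_variant(mir125_model, 5, 6)) == "arm5p(m-10)"

    def test_seed_suffix_at_mature_position_2(self, mir125_model):
        assert str(locate_variant(mir125_model, 16, 17)) == "mature5p(a+2)seed"

    def test_deletion_spanning_mature3p_end_gets_e_and_join(self, mir125_model):
        # mature3p ends at 74; delete its last 2 bases plus 3 arm bases
        got = str(locate_variant(mir125_model, 72, 77))
        assert got == "mature3p(a+21:22e)&arm3p(m+1:3)"

    def test_flank_and_upstream_count_from_hairpin_edge(self, mir125_model):
        assert str(locate_variant(mir125_model, -50, -40)) == "flank5p(a-50:41)"
        assert str(locate_variant(mir125_model, -150, -149)) == "upstream(a-150)"
        assert str(locate_variant(mir125_model, 86 + 187, 86 + 188)) == "downstream(a+188)"

    def test_insertion_annotated_at_following_base(self, mir125_model):
        assert str(locate_variant(mir125_model, 22, 22)) == "mature5p(a+8)"


class TestChooseReferenceBoundary:
    SEG = Segment("arm3p_upper", "arm3p", 52, 72,
                  (RefBoundary("l", 52, +1), RefBoundary("m", 72, -1)))

    def test_nearer_mature_boundary_wins(self):
        # position 5 nt before the mature, 15 nt after the loop
        ref = choose_reference_boundary(self.SEG, 67, 68)
        assert (ref.letter, ref.sign) == ("m", -1)

    def test_position_near_loop_counts_from_loop(self):
        ref = choose_reference_boundary(self.SEG, 58, 59)
        assert (ref.letter, ref.sign) == ("l", +1)

    def test_equidistant_tie_goes_upstream(self):
        seg = Segment("arm3p_upper", "arm3p", 0, 11,
                      (RefBoundary("l", 0, +1), RefBoundary("m", 11, -1)))
        ref = choose_reference_boundary(seg, 5, 6)  # 5 from each boundary
        assert ref.letter == "l"


class TestAnnotateChanges:
    def test_published_impact_string(self, mir125_model):
        runs = [(16, 17), (19, 20), (22, 24), (65, 67), (70, 72)]
        ann = annotate_changes(mir125_model, runs)
        assert str(ann) == "mature5p(a+2,5,8:9)seed&mature3p(a+14:15,19:20)"

    def test_flank_run_renders_range(self, mir125_model):
        ann = annotate_changes(mir125_model, [(-50, -39)])
        assert str(ann) == "flank5p(a-50:40)"

    def test_empty_diff_empty_string(self, mir125_model):
        assert str(annotate_changes(mir125_model, [])) == ""


class TestGrammarRoundTrip:
    CASES = [
        "mature5p(a+8)",
        "mature5p(a+2,5,8:9)seed&mature3p(a+14:15,19:20)",
        "mature3p(a+21:22e)&arm3p(m+1:3)",
        "flank5p(a-50:40)",
        "upstream(a-150)",
        "arm5p(m-10)",
        "arm3p(l+15)",
        "loop(a+6)",
        "downstream(a+88)",
        "mature5p(a+1e:4)seed",
    ]

    @pytest.mark.parametrize("text", CASES)
    def test_parse_format_identity(self, text):
        assert str(Annotation.parse(text)) == text

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            Annotation.parse("stem(x+1)")

    @given(st.lists(
        st.tuples(
            st.sampled_from(["flank5p", "arm5p", "mature5p", "loop", "mature3p",
                             "arm3p", "flank3p"]),
            st.sampled_from("aml"),
            st.sampled_from([+1, -1]),
            st.lists(st.tuples(st.integers(1, 99), st.integers(0, 30),
                               st.booleans(), st.booleans()),
                     min_size=1, max_size=4),
            st.booleans(),
        ), min_size=1, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_random_components_round_trip(self, comps):
        from mirimpact.annotate import AnnotationComponent, OffsetItem

        built = Annotation(tuple(
            AnnotationComponent(
                region, ref, sign,
                tuple(OffsetItem(a, a + d, ae and d > 0, se) if d > 0
                      else OffsetItem(a, a, ae or se, ae or se)
                      for a, d, ae, se in items),
                seed and region.startswith("mature"),
            )
            for region, ref, sign, items, seed in comps
        ))
        text = str(built)
        assert str(Annotation.parse(text)) == text


class TestDiffStructures:
    def test_identical_structures_empty(self):
        d = diff_structures("((((...))))", "((((...))))", tuple(range(11)))
        assert d.changed_positions == frozenset() and d.runs == ()

    def test_snp_changes_positions_3_and_9(self):
        d = diff_structures("((((...))))", "((.(...).))", tuple(range(11)))
        assert d.changed_positions == frozenset({2, 8})  # 1-based {3, 9}
        assert d.runs == ((2, 3), (8, 9))

    def test_bracket_flip_is_not_a_change(self):
        d = diff_structures("()", ")(", (0, 1))
        assert not d.changed_positions

    def test_deletion_compares_aligned_positions_only(self):
        ref, var = "(((...)))", "((....))"
        pmap = (0, 1, 2, None, 3, 4, 5, 6, 7)
        d = diff_structures(ref, var, pmap)
        brute = {i for i, j in enumerate(pmap) if j is not None
                 and (ref[i] in "()") != (var[j] in "()")}
        assert d.changed_positions == frozenset(brute) == {2, 6}

    def test_map_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="position_map"):
            diff_structures("...", "...", (0, 1))


class TestConservation:
    def test_identical_hairpin_substructure_conserved(self):
        assert conservation("..((((...))))..", "((((...))))", 2) == "conserved"

    def test_four_changed_hairpin_positions(self):
        flanked = ".." + "((((...))))" + ".."
        bare = "..((...)).."
        assert conservation(flanked, bare, 2) == "changed(4)"

    def test_zero_flanks_always_conserved(self):
        s = "((((...))))"
        assert conservation(s, s, 0) == "conserved"


class TestHighestImpact:
    @pytest.mark.parametrize("text,expected", [
        ("mature5p(a+2,5,8:9)seed&mature3p(a+14:15,19:20)", "seed"),
        ("loop(a+3)&flank5p(a-10)", "loop"),
        ("", "none"),
        ("mature3p(a+10)&arm5p(m-2)", "mature"),
        ("flank3p(a+4)", "flank"),
    ])
    def test_ordering(self, text, expected):
        assert highest_impact(Annotation.parse(text)) == expected

    def test_monotone_under_added_changes(self, mir125_model):
        runs = []
        best = "none"
        order = ["none", "flank", "loop", "arm", "mature", "seed"]
        for run in [(-20, -19), (43, 44), (7, 8), (30, 31), (16, 17)]:
            runs.append(run)
            now = highest_impact(annotate_changes(mir125_model, runs))
            assert order.index(now) >= order.index(best)
            best = now


class TestAnalyzeVariant:
    def test_beyond_flank_variant_has_location_only(self, fixture_set):
        db = fixture_set["db"]
        gene = db.genes[0]
        pos = gene.begin - 150
        genome = fixture_set["genome"]
        v = GenomicVariant(gene.chrom, pos, pos + 1, "snp",
                           genome[gene.chrom][pos], "G")
        backend = MockFold()  # must never be consulted
        rec = analyze_variant(v, gene, genome, 100, 100, backend)
        assert rec.mir_location == "upstream(a-150)"
        assert not rec.has_structure and rec.ref_mfefreq is None

    def test_variant_outside_window_yields_none(self, fixture_set):
        gene = fixture_set["db"].genes[0]
        genome = fixture_set["genome"]
        pos = gene.begin - 2100
        v = GenomicVariant(gene.chrom, pos, pos + 1, "snp",
                           genome[gene.chrom][pos], "G")
        assert analyze_variant(v, gene, genome, 100, 100, MockFold()) is None

    def test_stem_breaking_snp_impacts_hairpin(self, fixture_set, vienna):
        genome, db = fixture_set["genome"], fixture_set["db"]
        gene = db.genes[0]
        pos = gene.begin + 10  # lower 5p arm, within mature5p [4,26)
        v = GenomicVariant(gene.chrom, pos, pos + 1, "snp",
                           genome[gene.chrom][pos],
                           {"G": "C", "C": "A"}[genome[gene.chrom][pos]])
        rec = analyze_variant(v, gene, genome, 100, 100, vienna)
        assert rec.by_representation["MFE"].highest_impact in ("seed", "mature", "arm")
        assert rec.by_representation["MFE"].impact != ""

    def test_strand_mirror_symmetry_of_records(self, fixture_set, vienna):
        """Reverse-complementing the chromosome and flipping the gene's
        strand leaves every transcript-level output unchanged."""
        from mirimpact.seqtools import revcomp

        genome, db = fixture_set["genome"], fixture_set["db"]
        gene = db.genes[0]  # plus strand
        chrom_seq = genome[gene.chrom]
        L = len(chrom_seq)
        mirror_genome = {gene.chrom: revcomp(chrom_seq)}

        def flip_interval(b, e):
            return L - e, L - b

        mirror = MiRNAGene(
            gene.name, gene.chrom, "-", *flip_interval(gene.begin, gene.end),
            Mature(gene.mature5p.name, *flip_interval(gene.mature5p.begin,
                                                      gene.mature5p.end)),
            Mature(gene.mature3p.name, *flip_interval(gene.mature3p.begin,
                                                      gene.mature3p.end)),
            *flip_interval(gene.loop_begin, gene.loop_end),
        )
        for v, name, ann in fixture_set["expected"]:
            if name != gene.name or ann == "":
                continue
            mb, me = flip_interval(v.begin, v.end)
            mv = GenomicVariant(v.chrom, mb, me, v.type,
                                revcomp(v.ref), revcomp(v.alt))
            rec = analyze_variant(v, gene, genome, 100, 100, vienna)
            mrec = analyze_variant(mv, mirror, mirror_genome, 100, 100, vienna)
            assert mrec.mir_location == rec.mir_location == ann
            for rep in ("CEN", "MEA", "MFE"):
                p = rec.by_representation.get(rep)
                m = mrec.by_representation.get(rep)
                assert (p is None) == (m is None)
                if p is not None:
                    assert m.impact == p.impact
                    assert m.ref_deltaG == p.ref_deltaG
                    assert m.conservation == p.conservation
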