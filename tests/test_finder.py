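"""Search protocol: windows, mutant-exclusive qualification, ranking."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from snvpam.finder import (
    PamHit,
    ReferenceMismatchError,
    Variant,
    Window,
    build_window,
    classify_discrimination,
    find_pattern_placements,
    find_snv_derived_pams,
    pattern_qualifies,
    rank_hits,
)
from snvpam.iupac import reverse_complement
from snvpam.registry import PamPattern, load_registry, selectivity_score

from conftest import oracle_qualifying_placements, random_window_and_pattern


class TestVariant:
    def test_rejects_identical_alleles_and_non_bases(self):
        with pytest.raises(ValueError):
            Variant("chr1", 5, "A", "A")
        with pytest.raises(ValueError):
            Variant("chr1", 5, "AT", "A")
        with pytest.raises(ValueError):
            Variant("chr1", 0, "A", "G")

    def test_uppercases(self):
        v = Variant("chr1", 5, "a", "g")
        assert (v.ref, v.alt) == ("A", "G")


class TestBuildWindow:
    def test_centre_substitution(self):
        v = Variant("s", 5, "A", "G")
        w = build_window("AACTACCAA", v, 2)
        assert (w.wt_seq, w.mut_seq, w.centre_index) == ("CTACC", "CTGCC", 2)

    def test_clipped_at_sequence_start(self):
        v = Variant("s", 1, "A", "G")
        w = build_window("AACTACCAA", v, 2)
        assert w.wt_seq == "AAC" and w.centre_index == 0

    def test_clipped_at_sequence_end(self):
        v = Variant("s", 9, "A", "G")
        w = build_window("AACTACCAA", v, 3)
        assert w.wt_seq == "CCAA" and w.centre_index == 3

    def test_reference_mismatch_names_position(self):
        v = Variant("s", 5, "C", "G")
        with pytest.raises(ReferenceMismatchError, match="5"):
            build_window("AACTACCAA", v, 2)

    def test_window_type_enforces_single_difference(self):
        with pytest.raises(ValueError):
            Window(wt_seq="AAAA", mut_seq="ATTA", centre_index=1)


class TestQualification:
    def test_tg_creation_is_found_with_star(self, registry):
        # WT context 'TA', A->G creates a 'TG' readable by Cas12c1
        v = Variant("s", 5, "A", "G")
        hits = find_snv_derived_pams("AACTACCAA", v, registry)
        tg = [h for h in hits if h.enzyme_name == "Cas12c1"]
        assert len(tg) == 1
        hit = tg[0]
        assert hit.pattern.symbols == "TG"
        assert (hit.orientation, hit.offset) == ("forward", -1)
        assert hit.matched_sequence == "TG"
        assert hit.discriminating_specific

    def test_downstream_g_defeats_single_mismatch_motif(self, registry):
        # A->G with a G immediately downstream: NG sits with N on the variant
        # and matches both alleles, so the NG enzyme yields nothing.
        v = Variant("s", 3, "A", "G")
        hits = find_snv_derived_pams("CCAGC", v, registry)
        assert not any(h.pattern.symbols == "NG" for h in hits)

    def test_pattern_absent_from_both_alleles(self):
        # A->G in a poly-A context touches neither TG nor its complement CA
        v = Variant("s", 3, "A", "G")
        w = build_window("AAAAA", v, 2)
        assert pattern_qualifies("TG", w) == []

    def test_minus_strand_gain_counts_as_a_hit(self):
        # A->C in poly-A creates CA, i.e. a TG on the minus strand: matching
        # both orientations reports it as a reverse hit
        v = Variant("s", 3, "A", "C")
        w = build_window("AAAAA", v, 2)
        assert pattern_qualifies("TG", w) == [("reverse", 2)]

    def test_wildtype_match_in_reverse_orientation_disqualifies(self):
        # wt CTACA ends in CA = revcomp(TG); the A->G variant creates a
        # forward TG in the mutant, but the opposite-strand wild-type match
        # still defeats allele selectivity.
        v = Variant("s", 3, "A", "G")
        w = build_window("CTACA", v, 2)
        assert find_pattern_placements("TG", w.mut_seq) == [1]  # sanity
        assert pattern_qualifies("TG", w) == []

    def test_ambiguous_reference_characters_disqualify_and_warn(self):
        # the N at index 2 kills every placement covering it, on both alleles
        w = Window(wt_seq="CTNAC", mut_seq="CTNGC", centre_index=3)
        with pytest.warns(UserWarning, match="non-ACGT"):
            assert pattern_qualifies("TG", w) == []
        # a placement away from the ambiguity still works: GC sits at 3-4
        # (GC is self-complementary, so it matches on both strands there)
        with pytest.warns(UserWarning, match="non-ACGT"):
            assert sorted(pattern_qualifies("GC", w)) == [("forward", 3), ("reverse", 3)]

    def test_null_variant_yields_nothing(self):
        rng = random.Random(7)
        for _ in range(50):
            wt, _, _, pattern = random_window_and_pattern(rng)
            w = Window.__new__(Window)  # bypass the differing-centre invariant
            object.__setattr__(w, "wt_seq", wt)
            object.__setattr__(w, "mut_seq", wt)
            object.__setattr__(w, "centre_index", 0)
            assert pattern_qualifies(pattern, w) == []


class TestOracleEquivalence:
    def test_matcher_agrees_with_bruteforce_on_random_instances(self):
        rng = random.Random(2024)
        for _ in range(2000):
            wt, mut, centre, pattern = random_window_and_pattern(rng)
            w = Window(wt_seq=wt, mut_seq=mut, centre_index=centre)
            expected = sorted(oracle_qualifying_placements(pattern, wt, mut))
            assert sorted(pattern_qualifies(pattern, w)) == expected

    def test_every_hit_overlaps_the_variant(self, registry):
        rng = random.Random(99)
        for _ in range(60):
            seq = "".join(rng.choices("ACGT", k=31))
            pos = rng.randint(1, 31)
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = Variant("s", pos, ref, alt)
            for h in find_snv_derived_pams(seq, v, registry, include_less_preferred=True):
                # offset is relative to the variant: the placement covers it
                assert -len(h.pattern) < h.offset <= 0


@st.composite
def _random_case(draw):
    seq = draw(st.text(alphabet="ACGT", min_size=5, max_size=25))
    pos = draw(st.integers(min_value=1, max_value=len(seq)))
    ref = seq[pos - 1]
    alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
    return seq, Variant("s", pos, ref, alt)


class TestStrandSymmetry:
    @given(_random_case())
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_reverse_complementing_the_reference_preserves_hits(self, case):
        seq, v = case
        registry = load_registry()
        rc_seq = reverse_complement(seq)
        rc_v = Variant(
            "s",
            len(seq) - v.position + 1,
            reverse_complement(v.ref),
            reverse_complement(v.alt),
        )
        fwd = find_snv_derived_pams(seq, v, registry, include_less_preferred=True)
        rev = find_snv_derived_pams(rc_seq, rc_v, registry, include_less_preferred=True)

        def keyset(hits, flip):
            flipmap = {"forward": "reverse", "reverse": "forward"}
            return {
                (h.enzyme_name, h.pattern.symbols,
                 flipmap[h.orientation] if flip else h.orientation)
                for h in hits
            }

        assert keyset(fwd, flip=True) == keyset(rev, flip=False)


class TestDiscriminationFlag:
    def test_specific_base_on_variant_sets_flag(self):
        # C->G with motif 'G' directly on the variant
        assert classify_discrimination("forward", PamPattern("GG"), 0, "G")

    def test_degenerate_symbol_on_variant_clears_flag(self):
        # an R accepts the mutant G but cannot discriminate specifically
        assert not classify_discrimination("forward", PamPattern("RG"), 0, "G")

    def test_n_never_discriminates(self):
        assert not classify_discrimination("forward", PamPattern("NG"), 0, "G")

    def test_reverse_orientation_uses_complemented_symbol(self):
        # motif CA matched in reverse = TG on the forward strand; variant under
        # the G (revcomp index 1) with alt G discriminates
        assert classify_discrimination("reverse", PamPattern("CA"), -1, "G")

    def test_non_overlapping_placement_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            classify_discrimination("forward", PamPattern("TG"), 1, "G")


class TestRanking:
    @staticmethod
    def _hit(name, pattern, star=False, orientation="forward", offset=0):
        return PamHit(
            enzyme_name=name,
            pattern=PamPattern(pattern),
            less_preferred=False,
            orientation=orientation,
            offset=offset,
            matched_sequence="",
            discriminating_specific=star,
            score=selectivity_score(pattern),
        )

    def test_descending_score(self):
        hits = [self._hit("Cas12c2", "TN"), self._hit("SaCas9", "NNGRRT")]
        assert [h.enzyme_name for h in rank_hits(hits)] == ["SaCas9", "Cas12c2"]

    def test_star_flag_breaks_ties(self):
        hits = [self._hit("B", "TG"), self._hit("A", "TG", star=True)]
        assert [h.enzyme_name for h in rank_hits(hits)] == ["A", "B"]

    def test_alphabetical_last_resort(self):
        hits = [self._hit("Zeta", "TG"), self._hit("Alpha", "TG")]
        assert [h.enzyme_name for h in rank_hits(hits)] == ["Alpha", "Zeta"]

    def test_empty_input(self):
        assert rank_hits([]) == []

    def test_finder_output_is_ranked(self, registry):
        v = Variant("s", 5, "A", "G")
        hits = find_snv_derived_pams("AACTACCAA", v, registry, include_less_preferred=True)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)


class TestStrictPromiscuity:
    def test_alternate_wt_matching_motif_drops_enzyme(self, registry):
        # SpCas9 primary NGG; its less-preferred NAG/NGA may sit on wild type.
        # wt TATAGTA carries NAG at 'TAG' while the A->G mutant gains NGG at
        # 'TGG': the primary motif qualifies, but strict mode vetoes the
        # enzyme because its alternate motif would still cut the wild type.
        seq = "TATAGTA"
        v = Variant("s", 4, "A", "G")
        lax = find_snv_derived_pams(seq, v, registry)
        strict = find_snv_derived_pams(seq, v, registry, strict_promiscuity=True)
        assert any(h.enzyme_name == "SpCas9" for h in lax)
        assert not any(h.enzyme_name == "SpCas9" for h in strict)
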