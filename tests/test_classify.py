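"""Classification engine: copy counting, rules, curation heuristics."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from algatf.classify import (
    classify_myb,
    classify_protein,
    classify_proteome,
    count_copies,
    crosscheck_g2like,
    select_copies,
)
from algatf.records import BlastHit, DomainHit, EvidenceBundle, EvidenceSource, UNCLASSIFIED


def blast_hit(subject="s", query="p"):
    return BlastHit(
        query_id=query,
        subject_id=subject,
        percent_identity=50.0,
        alignment_length=150,
        mismatches=0,
        gap_opens=0,
        q_start=1,
        q_end=150,
        s_start=1,
        s_end=150,
        evalue=1e-20,
        bitscore=200.0,
    )


def hit(acc, start, end, score=30.0, pid="p", source=EvidenceSource.INTERPROSCAN):
    return DomainHit(
        protein_id=pid,
        source=source,
        domain_accession=acc,
        domain_name=acc,
        evalue=1e-9,
        score=score,
        ali_start=start,
        ali_end=end,
        significant=True,
    )


def bundle(*hits, pid="p", blast=None):
    return EvidenceBundle(protein_id=pid, best_blast=blast, domain_hits=list(hits))


# ---------------------------------------------------------------------------
# copy counting


def conflict(a, b):
    """Independent definition: two intervals are the same copy when their
    overlap exceeds half the shorter one."""
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return False
    return ov > 0.5 * min(a[1] - a[0] + 1, b[1] - b[0] + 1)


def brute_force_max_copies(intervals):
    """Maximum subset with no pairwise conflict (exhaustive oracle)."""
    best = 0
    for r in range(len(intervals), 0, -1):
        for combo in itertools.combinations(intervals, r):
            if all(not conflict(a, b) for a, b in itertools.combinations(combo, 2)):
                return r
    return best


class TestCountCopies:
    def test_disjoint_intervals_count_separately(self):
        hits = [hit("PF00847", 10, 60), hit("PF00847", 100, 150)]
        assert count_copies(hits, {"PF00847"}) == 2

    def test_near_duplicate_counts_once(self):
        hits = [hit("PF00847", 10, 60), hit("PF00847", 15, 65)]
        assert count_copies(hits, {"PF00847"}) == 1

    def test_chain_example_matches_brute_force(self):
        intervals = [(10, 60), (55, 110), (120, 170)]
        hits = [hit("PF00847", a, b) for a, b in intervals]
        expected = brute_force_max_copies(intervals)
        assert expected == 3  # 55-110 overlaps 10-60 by 6 < half of 51
        assert count_copies(hits, {"PF00847"}) == expected

    def test_other_accessions_ignored(self):
        hits = [hit("PF00847", 10, 60), hit("PF00249", 100, 150)]
        assert count_copies(hits, {"PF00847"}) == 1

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        st.lists(
            st.tuples(st.integers(1, 80), st.integers(5, 60)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=6,
        )
    )
    def test_greedy_never_exceeds_brute_force_and_is_monotone(self, intervals):
        hits = [hit("A", a, b) for a, b in intervals]
        n = count_copies(hits, {"A"})
        assert n <= brute_force_max_copies(intervals)
        if intervals:
            assert n >= 1
        # adding a far-away disjoint instance never decreases the count
        far = hit("A", 1000, 1040)
        assert count_copies(hits + [far], {"A"}) == n + 1


# ---------------------------------------------------------------------------
# generic rule engine


class TestClassifyProtein:
    def test_two_ap2_domains_give_ap2_subfamily(self, ruleset):
        a = classify_protein(bundle(hit("PF00847", 10, 60), hit("PF00847", 100, 150)), ruleset)
        assert (a.family, a.subfamily) == ("AP2/ERF", "AP2")
        assert "copy_number_checked" in a.curation_flags

    def test_single_ap2_domain_gives_erf_subfamily(self, ruleset):
        a = classify_protein(bundle(hit("PF00847", 10, 60)), ruleset)
        assert (a.family, a.subfamily) == ("AP2/ERF", "ERF")

    def test_single_bbox_is_not_dbb(self, ruleset):
        a = classify_protein(bundle(hit("PF00643", 10, 50)), ruleset)
        assert a.family != "DBB"

    def test_two_bboxes_give_dbb(self, ruleset):
        a = classify_protein(bundle(hit("PF00643", 10, 50), hit("PF00643", 80, 120)), ruleset)
        assert a.family == "DBB"

    def test_bbox_plus_cct_gives_co_like_not_dbb(self, ruleset):
        a = classify_protein(
            bundle(hit("PF00643", 10, 50), hit("PF00643", 80, 120), hit("PF06203", 200, 240)),
            ruleset,
        )
        assert a.family == "C2C2-CO-like"

    def test_no_matching_rule_is_unclassified(self, ruleset):
        a = classify_protein(bundle(hit("PF_UNKNOWN", 10, 50)), ruleset)
        assert a.family == UNCLASSIFIED

    def test_blast_only_candidate_inherits_subject_family(self, ruleset):
        b = bundle(blast=blast_hit(subject="HSF|at3g02990"))
        a = classify_protein(b, ruleset)
        assert a.family == "HSF"
        assert "blast_only" in a.curation_flags

    def test_strict_mode_disables_blast_fallback(self, ruleset):
        b = bundle(blast=blast_hit(subject="HSF|at3g02990"))
        assert classify_protein(b, ruleset, strict=True).family == UNCLASSIFIED

    def test_all_dbd_types_preserved_for_multi_dbd_protein(self, ruleset):
        a = classify_protein(bundle(hit("PF00170", 10, 60), hit("PF00447", 100, 160)), ruleset)
        assert a.all_dbd_types == {"PF00170", "PF00447"}


# ---------------------------------------------------------------------------
# MYB curation path

MYB_SEQ_PLAIN = "M" * 9 + "A" * 51 + "K" * 40  # repeat at 10..60, no motif
MYB_SEQ_MOTIF = "M" * 9 + "A" * 20 + "SHAQKY" + "A" * 25 + "K" * 40


class TestClassifyMyb:
    def test_three_disjoint_repeats_give_3r(self, ruleset):
        b = bundle(*[hit("PF00249", s, s + 47) for s in (10, 70, 130)])
        assert classify_myb(b, ruleset).label == "MYB (3R)"

    def test_two_repeats_give_2r(self, ruleset):
        b = bundle(hit("PF00249", 10, 57), hit("PF00249", 70, 117))
        assert classify_myb(b, ruleset).label == "MYB (2R)"

    def test_single_repeat_without_motif_is_myb_rel(self, ruleset):
        b = bundle(hit("PF00249", 10, 60))
        a = classify_myb(b, ruleset, sequence=MYB_SEQ_PLAIN)
        assert a.label == "MYB-rel"
        assert "myb_relaxed_path" in a.curation_flags

    def test_single_repeat_with_motif_is_shaqkyf(self, ruleset):
        import re

        assert re.search("SH[AL]QK[YF]", MYB_SEQ_MOTIF[9:60])  # motif inside repeat
        b = bundle(hit("PF00249", 10, 60))
        a = classify_myb(b, ruleset, sequence=MYB_SEQ_MOTIF)
        assert a.label == "MYB-SHAQKYF"
        assert "shaqkyf_motif" in a.curation_flags

    def test_raw_hits_bypass_the_evalue_filter(self, ruleset):
        weak = DomainHit(
            protein_id="p",
            source=EvidenceSource.INTERPROSCAN,
            domain_accession="PF00249",
            domain_name="Myb",
            evalue=0.5,  # fails the annotation filter
            score=10.0,
            ali_start=70,
            ali_end=117,
        )
        b = bundle(hit("PF00249", 10, 57))
        a = classify_myb(b, ruleset, raw_myb_hits=[weak])
        assert a.label == "MYB (2R)"


class TestG2likeCrosscheck:
    def _shaqkyf_assignment(self, ruleset, myb_score, g2_score):
        myb = hit("PF00249", 10, 60, score=myb_score)
        g2 = hit("ALG_G2LIKE", 10, 60, score=g2_score, source=EvidenceSource.HMMER_CUSTOM)
        b = bundle(myb, g2)
        a = classify_myb(b, ruleset, sequence=MYB_SEQ_MOTIF)
        return crosscheck_g2like([a], {"p": b}, ruleset)[0]

    def test_higher_g2like_score_wins(self, ruleset):
        a = self._shaqkyf_assignment(ruleset, myb_score=25.0, g2_score=40.0)
        assert a.label == "GARP-G2-like"
        assert "g2like_crosscheck" in a.curation_flags

    def test_higher_myb_score_keeps_shaqkyf(self, ruleset):
        a = self._shaqkyf_assignment(ruleset, myb_score=40.0, g2_score=25.0)
        assert a.label == "MYB-SHAQKYF"
        assert "g2like_crosscheck" in a.curation_flags

    def test_single_signal_left_unchanged(self, ruleset):
        b = bundle(hit("ALG_G2LIKE", 10, 60, source=EvidenceSource.HMMER_CUSTOM))
        a = classify_protein(b, ruleset)
        (out,) = crosscheck_g2like([a], {"p": b}, ruleset)
        assert out.label == "GARP-G2-like"
        assert "g2like_crosscheck" not in out.curation_flags


# ---------------------------------------------------------------------------
# proteome level


class TestClassifyProteome:
    def test_empty_bundle_set(self, ruleset):
        assert classify_proteome({}, ruleset) == []

    def test_one_assignment_per_bundle_sorted_and_order_invariant(self, ruleset):
        bundles = {
            "b": bundle(hit("PF00447", 10, 70, pid="b"), pid="b"),
            "a": bundle(hit("PF00170", 10, 70, pid="a"), pid="a"),
        }
        out = classify_proteome(bundles, ruleset)
        assert [a.protein_id for a in out] == ["a", "b"]
        shuffled = dict(reversed(list(bundles.items())))
        assert classify_proteome(shuffled, ruleset) == out

    def test_nfy_subunits_mutually_exclusive(self, ruleset):
        both = bundle(
            hit("ALG_NFYB", 10, 60, source=EvidenceSource.HMMER_CUSTOM),
            hit("ALG_NFYC", 100, 150, source=EvidenceSource.HMMER_CUSTOM),
        )
        a = classify_protein(both, ruleset)
        assert a.family not in {"NF-YB", "NF-YC"}  # forbidden sets block both
        for acc, fam in (("ALG_NFYB", "NF-YB"), ("ALG_NFYC", "NF-YC")):
            single = bundle(hit(acc, 10, 60, source=EvidenceSource.HMMER_CUSTOM))
            assert classify_protein(single, ruleset).family == fam
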