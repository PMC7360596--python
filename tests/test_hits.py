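"""Uniqueness filters: quoted boundary behavior and oracle equivalence."""

from hypothesis import given, strategies as st

from supergene.hits import (HitGroup, HitRecord, collect_region_queries,
                            filter_genome_scaffold, filter_rad_alignment)
from supergene.simulate import make_random_hit_groups

REGION = {"chr16_nr"}


def _group(*hitspecs, mode="genome"):
    hits = [HitRecord(query_id="q", **hs) for hs in hitspecs]
    return HitGroup.from_records("q", hits, mode=mode)


def _genome_hit(subject="chr16_nr", evalue=1e-9, matches=200, mm_pct=2.0):
    return dict(subject_id=subject, evalue=evalue, n_base_matches=matches,
                pct_mismatch=mm_pct)


class TestGenomeFilter:
    def test_good_top_hit_no_second_accepts(self):
        d = filter_genome_scaffold(_group(_genome_hit(evalue=1e-5)), REGION)
        assert d.accepted and d.reason == "ok"

    def test_top_evalue_boundary_is_inclusive(self):
        # exactly 1e-4 still satisfies "E value <= 1e-4" for the top hit
        d = filter_genome_scaffold(_group(_genome_hit(evalue=1e-4)), REGION)
        assert d.accepted
        d = filter_genome_scaffold(_group(_genome_hit(evalue=1.1e-4)), REGION)
        assert not d.accepted and d.reason == "top_evalue_above_threshold"

    def test_second_evalue_boundary_rejects(self):
        # a second hit at exactly 1e-4 disqualifies ("<= 1e-4" inclusive)
        d = filter_genome_scaffold(_group(
            _genome_hit(evalue=1e-5),
            _genome_hit(subject="chr3", evalue=1e-4, matches=10, mm_pct=50.0)),
            REGION)
        assert not d.accepted and d.reason == "second_evalue_significant"

    def test_second_matches_exactly_half_rejects(self):
        # "half the number of base matches ... or more" is inclusive
        d = filter_genome_scaffold(_group(
            _genome_hit(evalue=1e-6, matches=200),
            _genome_hit(subject="chr3", evalue=1e-2, matches=100,
                        mm_pct=50.0)), REGION)
        assert not d.accepted and d.reason == "second_matches_half_or_more"
        d = filter_genome_scaffold(_group(
            _genome_hit(evalue=1e-6, matches=200, mm_pct=4.0),
            _genome_hit(subject="chr3", evalue=1e-2, matches=99,
                        mm_pct=50.0)), REGION)
        assert d.accepted

    def test_second_mismatch_pct_exactly_half_rejects(self):
        # "half the percentage of mismatches ... or less" is inclusive
        d = filter_genome_scaffold(_group(
            _genome_hit(evalue=1e-6, matches=200, mm_pct=8.0),
            _genome_hit(subject="chr3", evalue=1e-2, matches=10, mm_pct=4.0)),
            REGION)
        assert not d.accepted and d.reason == "second_mismatch_pct_half_or_less"

    def test_outside_region_rejects_first(self):
        d = filter_genome_scaffold(_group(_genome_hit(subject="chr3")), REGION)
        assert not d.accepted and d.reason == "top_hit_outside_region"

    def test_zero_mismatch_top_hit_corner(self):
        # top hit with 0% mismatches: any 0% second hit is "half or less"
        d = filter_genome_scaffold(_group(
            _genome_hit(evalue=1e-9, matches=300, mm_pct=0.0),
            _genome_hit(subject="chr3", evalue=1e-2, matches=10, mm_pct=0.0)),
            REGION)
        assert not d.accepted and d.reason == "second_mismatch_pct_half_or_less"


class TestRadFilter:
    def test_top_within_four_second_clear(self):
        d = filter_rad_alignment(_group(
            dict(subject_id="a", n_mismatches=2),
            dict(subject_id="b", n_mismatches=5), mode="rad"))
        assert d.accepted  # 5 > 2*2

    def test_second_exactly_double_rejects(self):
        d = filter_rad_alignment(_group(
            dict(subject_id="a", n_mismatches=2),
            dict(subject_id="b", n_mismatches=4), mode="rad"))
        assert not d.accepted
        assert d.reason == "second_mismatches_within_double"

    def test_top_over_four_mismatches_rejects(self):
        d = filter_rad_alignment(_group(
            dict(subject_id="a", n_mismatches=5), mode="rad"))
        assert not d.accepted and d.reason == "top_mismatches_above_max"

    def test_zero_mismatch_top_corner(self):
        # top with 0 mismatches: only a 0-mismatch second hit disqualifies
        d = filter_rad_alignment(_group(
            dict(subject_id="a", n_mismatches=0),
            dict(subject_id="b", n_mismatches=0), mode="rad"))
        assert not d.accepted
        d = filter_rad_alignment(_group(
            dict(subject_id="a", n_mismatches=0),
            dict(subject_id="b", n_mismatches=1), mode="rad"))
        assert d.accepted


def naive_genome_decision(group, region):
    """Clause-by-clause re-statement of the scaffold rules (test oracle)."""
    top = group.hits[0]
    second = group.hits[1] if len(group.hits) > 1 else None
    if top.subject_id not in region:
        return False
    if not top.evalue <= 1e-4:
        return False
    if second is None:
        return True
    bad = (second.evalue <= 1e-4
           or second.n_base_matches >= 0.5 * top.n_base_matches
           or second.pct_mismatch <= 0.5 * top.pct_mismatch)
    return not bad


def naive_rad_decision(group):
    top = group.hits[0]
    second = group.hits[1] if len(group.hits) > 1 else None
    if top.n_mismatches > 4:
        return False
    return second is None or second.n_mismatches > 2 * top.n_mismatches


class TestSamIngest:
    SAM = (
        "@HD\tVN:1.6\tSO:unknown\n"
        "@SQ\tSN:chr16_nr\tLN:100000\n"
        "@SQ\tSN:chr3\tLN:100000\n"
        "r1\t0\tchr16_nr\t100\t42\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNM:i:1\n"
        "r1\t256\tchr3\t900\t0\t50M\t*\t0\t0\t*\t*\tNM:i:5\n"
        "r2\t0\tchr16_nr\t500\t42\t50M\t*\t0\t0\t" + "C" * 50 + "\t*\tNM:i:2\n"
        "r2\t256\tchr3\t700\t0\t50M\t*\t0\t0\t*\t*\tNM:i:3\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "G" * 50 + "\t*\n")

    def test_sam_hit_groups_and_filtering(self, tmp_path):
        from supergene.hits import read_sam_hits

        sam = tmp_path / "hits.sam"
        sam.write_text(self.SAM)
        groups = read_sam_hits(sam)
        assert [g.query_id for g in groups] == ["r1", "r2"]  # r3 unmapped
        assert groups[0].top.n_mismatches == 1
        assert filter_rad_alignment(groups[0]).accepted       # 5 > 2*1
        assert not filter_rad_alignment(groups[1]).accepted   # 3 <= 2*2


class TestOracleEquivalence:
    def test_genome_filter_matches_naive_oracle(self):
        groups = make_random_hit_groups(2000, seed=21)
        for g in groups:
            got = filter_genome_scaffold(g, REGION).accepted
            assert got == naive_genome_decision(g, REGION)

    def test_rad_filter_matches_naive_oracle(self):
        groups = make_random_hit_groups(2000, seed=22, mode="rad")
        for g in groups:
            assert filter_rad_alignment(g).accepted == naive_rad_decision(g)

    def test_collect_is_permutation_stable(self):
        groups = make_random_hit_groups(200, seed=23)
        d1 = collect_region_queries(groups, REGION)
        d2 = collect_region_queries(list(reversed(groups)), REGION)
        assert [(q, d.accepted) for q, d in d1.items()] == \
            [(q, d.accepted) for q, d in d2.items()]

    def test_all_rejected_gives_empty_accept_set(self):
        groups = [_group(_genome_hit(subject="chr3"))]
        d = collect_region_queries(groups, REGION)
        assert not any(x.accepted for x in d.values())


@given(
    top_e=st.floats(1e-12, 1e-5), top_m=st.integers(50, 400),
    top_pct=st.floats(0.5, 20.0),
    sec_e=st.floats(1.1e-4, 1e-1), sec_m=st.integers(0, 400),
    sec_pct=st.floats(0.0, 60.0),
    worse_e=st.floats(1.0, 100.0), worse_m=st.integers(0, 50),
    worse_pct=st.floats(0.0, 40.0))
def test_worsening_second_hit_never_flips_accept_to_reject(
        top_e, top_m, top_pct, sec_e, sec_m, sec_pct,
        worse_e, worse_m, worse_pct):
    """A strictly less competitive second hit can only help acceptance."""
    base = _group(
        _genome_hit(evalue=top_e, matches=top_m, mm_pct=top_pct),
        _genome_hit(subject="chr3", evalue=sec_e, matches=sec_m,
                    mm_pct=sec_pct))
    worse = _group(
        _genome_hit(evalue=top_e, matches=top_m, mm_pct=top_pct),
        _genome_hit(subject="chr3", evalue=sec_e * worse_e,
                    matches=max(sec_m - worse_m, 0),
                    mm_pct=min(sec_pct + worse_pct, 100.0)))
    if filter_genome_scaffold(base, REGION).accepted:
        assert filter_genome_scaffold(worse, REGION).accepted
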