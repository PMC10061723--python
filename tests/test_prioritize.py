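"""Prioritisation criteria, clumping against an independent greedy oracle,
and candidate assembly."""

import numpy as np
import pytest

from mirvar.io import GwasRecord, LdTable, Variant
from mirvar.prioritize import (
    BONFERRONI,
    KNOWN,
    LD,
    PrioritizationConfig,
    bonferroni_threshold,
    clump_independent,
    combine_candidates,
    criterion_bonferroni,
    criterion_known,
    criterion_ld,
    restrict_to_tested,
    union_independent,
)


def _rec(rsid, p=0.5, chrom="chr1", pos=None, ref="A", alt="G", odds=1.1):
    pos = pos if pos is not None else abs(hash(rsid)) % 10_000
    return GwasRecord(Variant(rsid, chrom, pos, ref, alt), p, odds)


class TestRestrictToTested:
    def test_no_overlap(self):
        assert restrict_to_tested([Variant("a", "chr1", 1, "A", "C")],
                                  [_rec("b", pos=99)]) == []

    def test_same_position_different_alt_not_matched(self):
        v = Variant("a", "chr1", 50, "A", "C")
        g = _rec("a", pos=50, ref="A", alt="G")
        assert restrict_to_tested([v], [g]) == []

    def test_allele_set_matching_is_order_free(self):
        v = Variant("a", "chr1", 50, "A", "C")
        g = _rec("a", pos=50, ref="C", alt="A")  # swapped effect/other
        assert restrict_to_tested([v], [g]) == [g]

    def test_rsid_fallback(self):
        v = Variant("a", "chr1", 50, "A", "C")
        g = _rec("a", pos=999)
        assert restrict_to_tested([v], [g], match_by_rsid=True) == [g]


class TestBonferroni:
    @pytest.mark.parametrize("n, expected", [
        (314, 0.05 / 314), (1, 0.05), (36841, 0.05 / 36841),
    ])
    def test_threshold_division(self, n, expected):
        assert bonferroni_threshold(0.05, n) == pytest.approx(expected)

    def test_zero_tests_is_hard_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_boundary_p_fails_strictly(self):
        tested = [_rec("a", p=0.05)]
        assert criterion_bonferroni(tested, alpha=0.05) == []

    def test_monotone_in_number_tested(self):
        rng = np.random.default_rng(23)
        ps = rng.uniform(0, 1, size=50) ** 4
        recs = [_rec(f"rs{i}", p=float(p), pos=i) for i, p in enumerate(ps)]
        prev = None
        for n in (10, 25, 50):
            passed = {g.rsid for g in criterion_bonferroni(recs[:n])
                      if g.rsid in {r.rsid for r in recs[:10]}}
            if prev is not None:
                assert passed <= prev
            prev = passed

    def test_null_false_positive_rate_matches_binomial(self):
        """Uniform nulls, n=300, 200 replicates: mean passer count within
        three standard errors of alpha."""
        rng = np.random.default_rng(2023)
        n, reps, alpha = 300, 200, 0.05
        counts = []
        for _ in range(reps):
            ps = 1.0 - rng.random(n)
            recs = [_rec(f"rs{i}", p=float(p), pos=i) for i, p in enumerate(ps)]
            counts.append(len(criterion_bonferroni(recs, alpha)))
        q = alpha / n
        se = np.sqrt(n * q * (1 - q) / reps)
        assert abs(np.mean(counts) - alpha) <= 3 * se


class TestKnownAndLd:
    def test_empty_susceptibility_set(self):
        assert criterion_known([_rec("a")], set()) == []

    def test_duplicates_collapse(self):
        recs = [_rec("a"), _rec("b")]
        assert [g.rsid for g in criterion_known(recs, ["a", "a"])] == ["a"]

    def test_high_ld_retained_with_anchor(self):
        ld = LdTable([("rs1414273", "rs10801908", 0.97)])
        out = criterion_ld([_rec("rs1414273")], {"rs10801908"}, ld, 0.8)
        assert out == [(out[0][0], "rs10801908", 0.97)]

    def test_below_threshold_and_no_data_excluded(self):
        ld = LdTable([("a", "s", 0.5)])
        assert criterion_ld([_rec("a"), _rec("b")], {"s"}, ld, 0.8) == []

    def test_known_snps_excluded_from_ld_branch(self):
        ld = LdTable([("a", "s", 0.99)])
        assert criterion_ld([_rec("a")], {"s", "a"}, ld, 0.8) == []


def oracle_clump(gwas, ld, r2_min, window):
    """Independent greedy re-implementation used as the clumping oracle."""
    remaining = sorted(gwas, key=lambda g: (g.p_value, g.variant.chrom,
                                            g.variant.pos))
    leads = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead.rsid)
        keep = []
        for g in remaining:
            r2 = ld.get(lead.rsid, g.rsid)
            close = (g.variant.chrom == lead.variant.chrom
                     and abs(g.variant.pos - lead.variant.pos) <= window)
            if not ((r2 is not None and r2 >= r2_min) or close):
                keep.append(g)
        remaining = keep
    return leads


class TestClumping:
    def test_high_ld_pair_keeps_smaller_p(self):
        ld = LdTable([("a", "b", 0.9)])
        recs = [_rec("a", p=0.5, pos=10), _rec("b", p=0.01, pos=900_000)]
        assert clump_independent(recs, ld) == ["b"]

    def test_different_chromosomes_both_survive(self):
        recs = [_rec("a", chrom="chr1", pos=10), _rec("b", chrom="chr2", pos=10)]
        assert sorted(clump_independent(recs, LdTable())) == ["a", "b"]

    def test_three_planted_blocks_give_three_leads(self):
        rng = np.random.default_rng(31)
        cfg = PrioritizationConfig()
        recs, ld = [], LdTable()
        for b in range(3):
            block = [f"b{b}s{i}" for i in range(10)]
            for i, rsid in enumerate(block):
                recs.append(_rec(rsid, p=float(rng.uniform(1e-6, 1e-2)),
                                 chrom="chr1", pos=b * 1_000_000 + i * 100))
                for j in range(i):
                    ld.add(rsid, block[j], float(rng.uniform(0.7, 0.99)))
        leads = clump_independent(recs, ld, cfg)
        assert len(leads) == 3
        assert leads == oracle_clump(recs, ld, cfg.r2_clump, cfg.clump_window_bp)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(97)
        cfg = PrioritizationConfig(clump_window_bp=500)
        for _ in range(20):
            recs = [_rec(f"rs{i}", p=float(1 - rng.random()),
                         chrom=f"chr{rng.integers(1, 3)}",
                         pos=int(rng.integers(0, 5000))) for i in range(30)]
            ld = LdTable()
            for _ in range(40):
                i, j = rng.integers(0, 30, size=2)
                if i != j:
                    ld.add(f"rs{i}", f"rs{j}", float(rng.random()))
            got = clump_independent(recs, ld, cfg)
            assert got == oracle_clump(recs, ld, cfg.r2_clump, cfg.clump_window_bp)

    def test_leads_mutually_independent(self):
        rng = np.random.default_rng(3)
        cfg = PrioritizationConfig(clump_window_bp=200)
        recs = [_rec(f"rs{i}", p=float(1 - rng.random()), pos=int(rng.integers(0, 3000)))
                for i in range(25)]
        ld = LdTable()
        leads = clump_independent(recs, ld, cfg)
        by_rsid = {g.rsid: g for g in recs}
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                close = abs(by_rsid[a].variant.pos - by_rsid[b].variant.pos) \
                    <= cfg.clump_window_bp
                assert not close


class TestUnionIndependent:
    def test_paper_style_counts(self):
        a = {f"a{i}" for i in range(11)} | {"x", "y"}
        b = {f"b{i}" for i in range(6)} | {"x", "y"}
        union, overlap = union_independent(a, b)
        assert (len(a), len(b), overlap, len(union)) == (13, 8, 2, 19)

    def test_disjoint_and_idempotent(self):
        assert union_independent({"a", "b", "c"}, {"d", "e", "f", "g"})[0] == \
            {"a", "b", "c", "d", "e", "f", "g"}
        s = {"a", "b"}
        union, overlap = union_independent(s, s)
        assert union == s and overlap == 2


class TestCombineCandidates:
    def test_flags_union_on_one_record(self):
        g = _rec("rs1414273", p=8.48e-16)
        out = combine_candidates(
            ld_flagged=[(g, "rs10801908", 0.97)], bonferroni=[g],
        )
        (c,) = out
        assert c.criteria == {LD, BONFERRONI}
        assert c.ld_anchor == ("rs10801908", 0.97)

    def test_no_flags_no_candidates(self):
        assert combine_candidates() == []

    def test_conflicting_records_hard_error(self):
        g1 = _rec("a", p=0.1, pos=5)
        g2 = _rec("a", p=0.2, pos=5)
        with pytest.raises(ValueError, match="conflicting"):
            combine_candidates(known=[g1], bonferroni=[g2])

    def test_branches_are_independent(self):
        """Removing one criterion's input never changes another's flags."""
        ld = LdTable([("b", "s", 0.95)])
        recs = [_rec("a", p=1e-9, pos=1), _rec("b", p=0.5, pos=2),
                _rec("c", p=0.4, pos=3)]
        known = criterion_known(recs, {"c"})
        ldf = criterion_ld(recs, {"s"}, ld, 0.8)
        bonf = criterion_bonferroni(recs)
        full = {c.rsid: c.criteria for c in combine_candidates(
            known=known, ld_flagged=ldf, bonferroni=bonf)}
        no_ld = {c.rsid: c.criteria for c in combine_candidates(
            known=known, bonferroni=bonf)}
        for rsid in no_ld:
            assert no_ld[rsid] == full[rsid] - {LD}
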