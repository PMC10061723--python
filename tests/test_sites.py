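"""Seed-pattern derivation and canonical-site scanning, checked against an
independent sliding-window oracle and Biopython's reverse complement."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mirvar.sites import (
    PredictionRecord,
    SiteType,
    filter_best_predictions,
    scan_sites,
    seed_and_site_patterns,
)

MIR21_LIKE = "UAGCUUAUCAGACUGAUGUUGA"


def bio_revcomp(rna: str) -> str:
    """Independent reverse-complement route via Biopython."""
    return str(Seq(rna).reverse_complement_rna())


def oracle_patterns(mirna: str) -> dict[SiteType, str]:
    seed7, core6 = mirna[1:8], mirna[1:7]
    return {
        SiteType.EIGHT_MER: bio_revcomp(seed7) + "A",
        SiteType.SEVEN_MER_M8: bio_revcomp(seed7),
        SiteType.SEVEN_MER_A1: bio_revcomp(core6) + "A",
        SiteType.SIX_MER: bio_revcomp(core6),
    }


def oracle_scan(utr: str, mirna: str, include_six_mer: bool):
    """Brute force: find every pattern occurrence at every offset, then
    suppress sites nested in a longer site at the same seed-pairing locus."""
    pats = oracle_patterns(mirna)

    def occurrences(pattern):
        return {
            i for i in range(len(utr) - len(pattern) + 1)
            if utr[i : i + len(pattern)] == pattern
        }

    occ = {st: occurrences(p) for st, p in pats.items()}
    sites = set()
    for s in occ[SiteType.EIGHT_MER]:
        sites.add((SiteType.EIGHT_MER, s + 1))
    for s in occ[SiteType.SEVEN_MER_M8]:
        if s not in occ[SiteType.EIGHT_MER]:
            sites.add((SiteType.SEVEN_MER_M8, s + 1))
    for s in occ[SiteType.SEVEN_MER_A1]:
        if s - 1 not in occ[SiteType.EIGHT_MER]:
            sites.add((SiteType.SEVEN_MER_A1, s + 1))
    if include_six_mer:
        for s in occ[SiteType.SIX_MER]:
            if (s - 1 not in occ[SiteType.SEVEN_MER_M8]
                    and s not in occ[SiteType.SEVEN_MER_A1]
                    and s - 1 not in occ[SiteType.EIGHT_MER]):
                sites.add((SiteType.SIX_MER, s + 1))
    return sites


def _as_tuples(matches):
    return {(m.site_type, m.utr_start) for m in matches}


class TestSeedPatterns:
    def test_patterns_match_independent_revcomp(self):
        _, pats = seed_and_site_patterns(MIR21_LIKE)
        assert pats == oracle_patterns(MIR21_LIKE)
        assert pats[SiteType.EIGHT_MER] == "AUAAGCUA"
        assert pats[SiteType.SEVEN_MER_M8] == "AUAAGCU"
        assert pats[SiteType.SEVEN_MER_A1] == "UAAGCUA"

    def test_length_eight_mirna_accepted_seven_rejected(self):
        seed7, _ = seed_and_site_patterns("UAGCUUAU")
        assert seed7 == "AGCUUAU"
        with pytest.raises(ValueError, match="shorter"):
            seed_and_site_patterns("UAGCUUA")


class TestScanSites:
    def test_eight_mer_suppresses_nested_sevens(self):
        matches = scan_sites("CCAUAAGCUACC", MIR21_LIKE)
        assert [(m.site_type, m.utr_start, m.utr_end) for m in matches] == [
            (SiteType.EIGHT_MER, 3, 10)
        ]

    def test_empty_utr(self):
        assert scan_sites("", MIR21_LIKE) == []

    def test_seven_mer_m8_without_downstream_a(self):
        _, pats = seed_and_site_patterns(MIR21_LIKE)
        utr = pats[SiteType.SEVEN_MER_M8] + "C"
        matches = scan_sites(utr, MIR21_LIKE)
        assert [m.site_type for m in matches] == [SiteType.SEVEN_MER_M8]

    @pytest.mark.parametrize("include_six_mer", [False, True])
    def test_matches_brute_force_on_random_pairs(self, include_six_mer):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGU"))
        for _ in range(250):
            mirna = "".join(rng.choice(bases, size=rng.integers(18, 25)))
            utr = "".join(rng.choice(bases, size=rng.integers(0, 80)))
            # bias half the UTRs towards containing a site
            if rng.random() < 0.5 and len(utr) > 10:
                _, pats = seed_and_site_patterns(mirna)
                pat = pats[list(SiteType)[int(rng.integers(4))]]
                at = int(rng.integers(0, len(utr) - len(pat) + 1)) \
                    if len(utr) >= len(pat) else 0
                utr = utr[:at] + pat + utr[at + len(pat):]
            got = _as_tuples(scan_sites(utr, mirna, include_six_mer=include_six_mer))
            assert got == oracle_scan(utr, mirna, include_six_mer)

    def test_dna_and_rna_inputs_equivalent(self):
        utr_rna = "CCAUAAGCUACC"
        utr_dna = utr_rna.replace("U", "T")
        assert scan_sites(utr_rna, MIR21_LIKE) == scan_sites(utr_dna, MIR21_LIKE)

    def test_same_seed_same_sites_family_property(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGU"))
        for _ in range(30):
            utr = "".join(rng.choice(bases, size=60))
            m1 = "".join(rng.choice(bases, size=22))
            m2 = m1[:8] + "".join(rng.choice(bases, size=14))  # same positions 1-8
            assert _as_tuples(scan_sites(utr, m1)) == _as_tuples(scan_sites(utr, m2))


class TestFilterBestPredictions:
    def test_minimum_p_per_pair_survives(self):
        recs = [
            PredictionRecord("m1", "t1", 0.01),
            PredictionRecord("m1", "t1", 0.02),
            PredictionRecord("m2", "t1", 0.05),
        ]
        assert filter_best_predictions(recs) == [PredictionRecord("m1", "t1", 0.01)]

    def test_threshold_is_strict(self):
        assert filter_best_predictions([PredictionRecord("m", "t", 0.0314)]) == []
        assert filter_best_predictions([PredictionRecord("m", "t", 0.0313)]) != []

    def test_empty_input(self):
        assert filter_best_predictions([]) == []

    def test_tie_broken_by_smallest_site_start(self):
        recs = [
            PredictionRecord("m", "t", 0.01, site_start=50, site_end=60),
            PredictionRecord("m", "t", 0.01, site_start=10, site_end=20),
        ]
        (kept,) = filter_best_predictions(recs)
        assert kept.site_start == 10


class TestPatternProperties:
    """Structural invariants of the derived site patterns."""

    from hypothesis import given, settings, strategies as st

    rna = st.text(alphabet="ACGU", min_size=8, max_size=30)

    @given(mirna=rna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pattern_lengths_and_nesting(self, mirna):
        seed7, pats = seed_and_site_patterns(mirna)
        assert len(seed7) == 7
        assert {st: len(p) for st, p in pats.items()} == {
            SiteType.EIGHT_MER: 8, SiteType.SEVEN_MER_M8: 7,
            SiteType.SEVEN_MER_A1: 7, SiteType.SIX_MER: 6,
        }
        # the shorter canonical patterns are substrings of the 8mer
        p8 = pats[SiteType.EIGHT_MER]
        assert p8.startswith(pats[SiteType.SEVEN_MER_M8])
        assert p8.endswith(pats[SiteType.SEVEN_MER_A1])
        assert pats[SiteType.SEVEN_MER_M8].endswith(pats[SiteType.SIX_MER])
        assert p8.endswith("A")

    @given(mirna=rna)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pattern_complementarity(self, mirna):
        _, pats = seed_and_site_patterns(mirna)
        assert pats[SiteType.SEVEN_MER_M8] == bio_revcomp(mirna[1:8])
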