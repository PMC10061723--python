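"""Allele substitution and differential binding (gain/loss) behaviour."""

import numpy as np
import pytest

from mirvar.alleles import apply_allele, seed_gain_loss, utr_gain_loss
from mirvar.io import Variant
from mirvar.sites import seed_and_site_patterns, SiteType


class TestApplyAllele:
    def test_forward_substitution(self):
        assert apply_allele("ACGU", 2, "C", "G") == "AGGU"

    def test_reverse_strand_complements_alleles(self):
        # genomic G reads as transcript C; genomic alt A reads as U
        assert apply_allele("ACGU", 2, "G", "A", on_reverse_strand=True) == "AUGU"

    def test_reference_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="expected A.*observed C"):
            apply_allele("ACGU", 2, "A", "G")

    def test_exactly_one_position_changes(self):
        rng = np.random.default_rng(3)
        bases = "ACGU"
        to_dna = {"A": "A", "C": "C", "G": "G", "U": "T"}
        for _ in range(50):
            seq = "".join(rng.choice(list(bases), size=30))
            pos = int(rng.integers(1, 31))
            ref = to_dna[seq[pos - 1]]
            alt = ref
            while alt == ref:
                alt = "ACGT"[int(rng.integers(4))]
            out = apply_allele(seq, pos, ref, alt)
            diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
            assert diffs == [pos - 1]


def _rand_panel(rng, n=4):
    return {f"miR-{i}": "".join(rng.choice(list("ACGU"), size=22))
            for i in range(n)}


def _snp_for(seq, pos_1based, alt_rna):
    to_dna = {"A": "A", "C": "C", "G": "G", "U": "T"}
    return Variant("rs", "chr1", 0, to_dna[seq[pos_1based - 1]], to_dna[alt_rna])


class TestUtrGainLoss:
    def test_disruption_plus_creation_nets_zero(self):
        """A SNP destroying family A's 8mer while creating family B's
        7mer-A1 yields lost={A}, gained={B}, net 0."""
        mir_a = "UAGCUUAUCAGACUGAUGUUGA"
        _, pats_a = seed_and_site_patterns(mir_a)
        p8 = pats_a[SiteType.EIGHT_MER]  # AUAAGCUA
        utr_ref = "CC" + p8 + "CCCCCCCCCC"
        # SNP at core position 4 of the site (UTR position 6)
        pos = 6
        alt = "G" if utr_ref[pos - 1] != "G" else "C"
        utr_alt = utr_ref[:pos - 1] + alt + utr_ref[pos:]
        # family B built so that its 7mer-A1 equals the mutated window
        window = utr_alt[3:10]  # 7 nt ending in the literal A at position 10
        assert window.endswith("A")
        core6_revcomp = window[:6]
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        seed_core = "".join(comp[c] for c in core6_revcomp[::-1])
        mir_b = "A" + seed_core + "A" + "ACGUACGUACGUAC"
        panel = {"famA": mir_a, "famB": mir_b}
        res = utr_gain_loss(utr_ref, _snp_for(utr_ref, pos, alt), pos, False, panel)
        assert res.lost_families == {mir_a[1:8]}
        assert res.gained_families == {mir_b[1:8]}
        assert res.net_change == 0

    def test_snp_outside_all_sites_changes_nothing(self):
        rng = np.random.default_rng(11)
        panel = _rand_panel(rng)
        utr = "".join(rng.choice(list("ACGU"), size=60))
        res = utr_gain_loss(utr, _snp_for(utr, 1, "A" if utr[0] != "A" else "C"),
                            1, False, panel)
        # position 1 can affect at most a site starting there; property holds
        # whenever the diff sets are empty, which antisymmetry covers; here we
        # assert the invariant directly
        assert res.gained_families.isdisjoint(res.lost_families)

    def test_antisymmetry_over_random_scenarios(self):
        """Swapping ref and alt mirrors gained/lost and negates the net
        change (100 scenarios)."""
        rng = np.random.default_rng(5)
        to_dna = {"A": "A", "C": "C", "G": "G", "U": "T"}
        for _ in range(100):
            panel = _rand_panel(rng, n=5)
            utr = "".join(rng.choice(list("ACGU"), size=50))
            # half the time embed a site so changes actually happen
            if rng.random() < 0.6:
                _, pats = seed_and_site_patterns(panel["miR-0"])
                p = pats[SiteType.EIGHT_MER]
                at = int(rng.integers(0, len(utr) - 8))
                utr = utr[:at] + p + utr[at + 8:]
            pos = int(rng.integers(1, len(utr) + 1))
            ref_rna = utr[pos - 1]
            alt_rna = ref_rna
            while alt_rna == ref_rna:
                alt_rna = "ACGU"[int(rng.integers(4))]
            snp = Variant("rs", "chr1", 0, to_dna[ref_rna], to_dna[alt_rna])
            fwd = utr_gain_loss(utr, snp, pos, False, panel)
            utr_alt = apply_allele(utr, pos, snp.ref_allele, snp.alt_allele)
            back = Variant("rs", "chr1", 0, to_dna[alt_rna], to_dna[ref_rna])
            rev = utr_gain_loss(utr_alt, back, pos, False, panel)
            assert rev.gained_families == fwd.lost_families
            assert rev.lost_families == fwd.gained_families
            assert rev.net_change == -fwd.net_change

    def test_distant_snp_yields_empty_result(self):
        """A SNP farther than 8 nt from every site never changes binding."""
        rng = np.random.default_rng(9)
        for _ in range(40):
            panel = _rand_panel(rng, n=3)
            utr = "".join(rng.choice(list("ACGU"), size=60))
            sites = []
            from mirvar.sites import scan_sites
            for seq in panel.values():
                sites.extend(scan_sites(utr, seq))
            far = [
                p for p in range(1, 61)
                if all(abs(p - s.utr_start) > 8 and abs(p - s.utr_end) > 8
                       for s in sites)
            ]
            if not far:
                continue
            pos = far[0]
            alt = "A" if utr[pos - 1] != "A" else "C"
            res = utr_gain_loss(utr, _snp_for(utr, pos, alt), pos, False, panel)
            assert not res.changed

    def test_duplicate_panel_member_does_not_change_family_sets(self):
        rng = np.random.default_rng(13)
        panel = _rand_panel(rng, n=3)
        _, pats = seed_and_site_patterns(panel["miR-1"])
        utr = "GG" + pats[SiteType.EIGHT_MER] + "GGGGGG"
        pos, alt = 5, ("A" if utr[4] != "A" else "C")
        snp = _snp_for(utr, pos, alt)
        res1 = utr_gain_loss(utr, snp, pos, False, panel)
        panel2 = dict(panel, extra_copy=panel["miR-1"])
        res2 = utr_gain_loss(utr, snp, pos, False, panel2)
        assert res1.gained_families == res2.gained_families
        assert res1.lost_families == res2.lost_families

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError, match="panel"):
            utr_gain_loss("ACGUACGU", Variant("rs", "c", 0, "A", "C"),
                          1, False, {})


class TestSeedGainLoss:
    def test_position_one_snp_changes_no_target(self):
        """miRNA position 1 is outside the seed and the site's A1 adenine is
        a UTR literal, so no target changes state."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            mirna = "".join(rng.choice(list("ACGU"), size=22))
            _, pats = seed_and_site_patterns(mirna)
            utrs = {
                "with_site": "CC" + pats[SiteType.EIGHT_MER] + "CC",
                "random": "".join(rng.choice(list("ACGU"), size=30)),
            }
            ref = {"A": "A", "C": "C", "G": "G", "U": "T"}[mirna[0]]
            alt = "A" if ref != "A" else "G"
            res = seed_gain_loss(mirna, 1, ref, alt, False, utrs)
            assert all(before == after for before, after in res.values())

    def test_seed_position_snp_loses_matching_sites(self):
        mirna = "UAGCUUAUCAGACUGAUGUUGA"
        _, pats = seed_and_site_patterns(mirna)
        utrs = {"target": "CC" + pats[SiteType.EIGHT_MER] + "CC"}
        ref = {"A": "A", "C": "C", "G": "G", "U": "T"}[mirna[4]]
        res = seed_gain_loss(mirna, 5, ref, "G" if ref != "G" else "C",
                             False, utrs)
        assert res["target"] == (True, False)

    def test_empty_utr_panel(self):
        assert seed_gain_loss("UAGCUUAUCAGACUGAUGUUGA", 5, "T", "G", False, {}) == {}
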