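"""Deterministic generator of a complete toy cohort with planted ground truth.

The generator emulates the statistical structure the analysis assumes —
miRNA hairpins with 5p/3p arms on both strands, SNPs in every hairpin
region class, GWAS p-values that are uniform nulls plus a handful of
planted signals below the class-specific Bonferroni threshold, block LD
with one pair above the strong-LD threshold anchored to a planted
susceptibility SNP, 3'UTRs carrying verified seed-match sites with
site-disrupting (and site-creating) alleles, and tissue-stratified
evidence tables that give exactly the planted prioritised candidates all
three validation criteria. It writes the same external formats the readers
consume (GFF3, VCF, FASTA, TSVs) plus a YAML manifest of the planted
truth, against which pipeline recovery can be asserted exactly.

Each output table draws from its own pseudo-random stream derived from the
master seed, so adding a table never perturbs earlier ones. Identical
seeds give byte-identical files.

In planted-truth mode (the default), null p-values are uniform(0, 1]
conditioned on lying at or above their class's Bonferroni threshold, so the
manifest's candidate set is exact by construction;
``exclude_null_significants=False`` gives the unconditioned uniform null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from mirvar.alleles import transcript_base
from mirvar.io import normalise_rna
from mirvar.sites import scan_sites, seed_and_site_patterns, seed_family, SiteType

logger = logging.getLogger(__name__)

_RNA = "ACGU"

# inverse of transcript_base: the genomic-forward DNA allele showing a given
# transcript-sense RNA base
_FROM_FORWARD = {"A": "A", "C": "C", "G": "G", "U": "T"}
_FROM_REVERSE = {"U": "A", "G": "C", "C": "G", "A": "T"}


def _genomic_allele(transcript: str, on_reverse_strand: bool) -> str:
    return (_FROM_REVERSE if on_reverse_strand else _FROM_FORWARD)[transcript]


def _t2g(start: int, end: int, strand: str, offset: int) -> int:
    """Genomic position of 0-based transcript offset in [start, end)."""
    return start + offset if strand == "+" else end - 1 - offset


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_mirnas: int = 8
    n_snps: int = 80           # background SNPs in hairpin flanks
    n_utrs: int = 6
    fraction_tested: float = 0.8
    n_planted_per_criterion: int = 2
    planted_p_range: tuple[float, float] = (1e-12, 1e-9)
    planted_or_range: tuple[float, float] = (1.1, 1.6)
    independent_p_range: tuple[float, float] = (1e-6, 1e-4)
    r2_within_block_range: tuple[float, float] = (0.8, 0.99)
    flank_bp: int = 5000
    alpha: float = 0.05
    r2_strong_ld: float = 0.8
    utr_length: int = 300
    hairpin_length: int = 100
    exclude_null_significants: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_mirnas, self.n_utrs) < 1 or self.n_snps < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fraction_tested <= 1.0:
            raise ValueError("fraction_tested must be in [0, 1]")
        for lo, hi in (self.planted_p_range, self.independent_p_range,
                       self.r2_within_block_range, self.planted_or_range):
            if not lo <= hi:
                raise ValueError("invalid range in generator config")


@dataclass
class SyntheticTruth:
    """Manifest of everything the generator planted.

    ``planted_candidates`` maps rsid to the sorted criteria the pipeline is
    expected to flag; ``planted_region_classes`` maps rsid to its region
    label; ``planted_sites`` lists the seed-match sites present on the
    reference UTRs; ``planted_gainloss`` gives the expected gained/lost
    family-seed sets per UTR SNP; ``evidence_counts`` the expected number of
    satisfied validation criteria.
    """

    planted_candidates: dict[str, list[str]] = field(default_factory=dict)
    planted_region_classes: dict[str, str] = field(default_factory=dict)
    planted_sites: dict[str, list[list]] = field(default_factory=dict)
    planted_gainloss: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    ld_blocks: list[list[str]] = field(default_factory=list)
    tested_subset: list[str] = field(default_factory=list)
    tested_by_class: dict[str, list[str]] = field(default_factory=dict)
    susceptibility: list[str] = field(default_factory=list)
    consortium_independent: list[str] = field(default_factory=list)
    utr_snp_positions: dict[str, list] = field(default_factory=dict)
    evidence_counts: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_RNA[int(i)] for i in rng.integers(0, 4, size=n))


def _null_p(rng: np.random.Generator, floor: float | None) -> float:
    """Uniform(0, 1] null; with a floor, conditioned on p >= floor."""
    while True:
        p = 1.0 - float(rng.random())  # (0, 1]
        if floor is None or p >= floor:
            return p


class _Cohort:
    """Mutable assembly state; ``build`` drives generation."""

    def __init__(self, cfg: GeneratorConfig, outdir: Path):
        self.cfg = cfg
        self.outdir = outdir
        self.truth = SyntheticTruth()
        self.rsid_counter = 0
        self.used_positions: set[tuple[str, int]] = set()
        # rsid -> (chrom, pos0, ref, alt)
        self.variants: dict[str, tuple[str, int, str, str]] = {}
        # class name -> list of rsid for GWAS emission
        self.tested: dict[str, list[str]] = {"mir": [], "flank": [], "utr": []}
        self.p_values: dict[str, float] = {}
        self.odds_ratios: dict[str, float] = {}
        self.ld_rows: list[tuple[str, str, float]] = []
        self.mirnas: list[dict] = []
        self.utrs: list[dict] = []
        self.mature_seqs: dict[str, str] = {}
        self.hairpin_seqs: dict[str, str] = {}

    def _stream(self, idx: int) -> np.random.Generator:
        return np.random.default_rng([self.cfg.seed % (2**31), idx])

    def new_rsid(self) -> str:
        self.rsid_counter += 1
        return f"rs{self.rsid_counter:05d}"

    def add_variant(self, chrom: str, pos0: int, ref: str, alt: str) -> str:
        if (chrom, pos0) in self.used_positions:
            raise ValueError(f"position {chrom}:{pos0} already used")
        self.used_positions.add((chrom, pos0))
        rsid = self.new_rsid()
        self.variants[rsid] = (chrom, pos0, ref, alt)
        return rsid

    # -- miRNA annotations and hairpin-region SNPs --------------------------

    _ARM_5P = (10, 32)
    _ARM_3P = (60, 82)

    def make_mirnas(self) -> None:
        cfg = self.cfg
        rng = self._stream(1)
        per_chrom = [0] * cfg.n_chroms
        seeds_seen: set[str] = set()
        for i in range(cfg.n_mirnas):
            chrom = f"chr{(i % cfg.n_chroms) + 1}"
            idx_on_chrom = per_chrom[i % cfg.n_chroms]
            per_chrom[i % cfg.n_chroms] += 1
            start = 50_000 + idx_on_chrom * 20_000
            end = start + cfg.hairpin_length
            if end + cfg.flank_bp > cfg.chrom_length:
                raise ValueError("chrom_length too short for the miRNA layout")
            strand = "+" if i % 2 == 0 else "-"
            for _ in range(200):
                seq = _rand_seq(rng, cfg.hairpin_length)
                s5 = seed_family(seq[slice(*self._ARM_5P)])
                s3 = seed_family(seq[slice(*self._ARM_3P)])
                if s5 != s3 and not {s5, s3} & seeds_seen:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not draw distinct family seeds")
            seeds_seen |= {s5, s3}
            name = f"syn-mir-{i + 1}"
            self.mirnas.append({
                "name": name, "accession": f"MI{i + 1:07d}", "chrom": chrom,
                "start": start, "end": end, "strand": strand,
            })
            self.hairpin_seqs[name] = seq
            self.mature_seqs[f"syn-miR-{i + 1}-5p"] = seq[slice(*self._ARM_5P)]
            self.mature_seqs[f"syn-miR-{i + 1}-3p"] = seq[slice(*self._ARM_3P)]

    def _arm_interval(self, m: dict, arm: tuple[int, int]) -> tuple[int, int]:
        lo, hi = arm
        if m["strand"] == "+":
            return m["start"] + lo, m["start"] + hi
        return m["end"] - hi, m["end"] - lo

    def plant_hairpin_snp(self, m: dict, t_offset: int, rng,
                          label: str) -> str:
        """SNP at a transcript offset of a hairpin, ref matching the sequence."""
        reverse = m["strand"] == "-"
        pos0 = _t2g(m["start"], m["end"], m["strand"], t_offset)
        tbase = self.hairpin_seqs[m["name"]][t_offset]
        ref = _genomic_allele(tbase, reverse)
        alt = ref
        while alt == ref:
            alt = "ACGT"[int(rng.integers(4))]
        rsid = self.add_variant(m["chrom"], pos0, ref, alt)
        self.truth.planted_region_classes[rsid] = label
        return rsid

    def plant_flank_snp(self, m: dict, genomically_before: bool, dist: int,
                        rng) -> str:
        pos0 = m["start"] - dist if genomically_before else m["end"] + dist - 1
        ref = "ACGT"[int(rng.integers(4))]
        alt = ref
        while alt == ref:
            alt = "ACGT"[int(rng.integers(4))]
        rsid = self.add_variant(m["chrom"], pos0, ref, alt)
        plus = m["strand"] == "+"
        upstream = genomically_before if plus else not genomically_before
        self.truth.planted_region_classes[rsid] = (
            "Flank_Upstream" if upstream else "Flank_Downstream"
        )
        return rsid

    #: transcript offsets exercising every within-hairpin region class
    _REGION_OFFSETS = [
        (12, "5p_Seed"),       # mature position 3 on the 5p arm
        (30, "5p_Mature"),     # mature position 21
        (45, "Precursor_Loop"),
        (61, "3p_Seed"),       # mature position 2 on the 3p arm
        (70, "3p_Mature"),
        (4, "Precursor_5PrimeEnd"),
        (90, "Precursor_3PrimeEnd"),
    ]

    def make_region_snps(self) -> None:
        """One tested SNP per region class, cycling over the miRNA set."""
        rng = self._stream(2)
        for k, (t_off, label) in enumerate(self._REGION_OFFSETS):
            m = self.mirnas[k % len(self.mirnas)]
            rsid = self.plant_hairpin_snp(m, t_off, rng, label)
            self.tested["mir"].append(rsid)
        for k in range(2):
            m = self.mirnas[k % len(self.mirnas)]
            rsid = self.plant_flank_snp(m, genomically_before=(k % 2 == 0),
                                        dist=100 + 37 * k, rng=rng)
            self.tested["flank"].append(rsid)

    def make_criterion_snps(self) -> None:
        """Planted KNOWN / LD / BONFERRONI candidates (miR and flank classes)."""
        cfg = self.cfg
        rng = self._stream(3)
        n = cfg.n_planted_per_criterion
        if n > len(self.mirnas):
            raise ValueError("more planted SNPs per criterion than miRNAs")
        # KNOWN: flank SNPs listed in the susceptibility table
        for k in range(n):
            m = self.mirnas[k]
            rsid = self.plant_flank_snp(m, genomically_before=(k % 2 == 1),
                                        dist=900 + 13 * k, rng=rng)
            self.tested["flank"].append(rsid)
            self.truth.susceptibility.append(rsid)
            self.truth.planted_candidates[rsid] = ["KNOWN"]
        # LD: hairpin SNPs in strong LD with an (external) susceptibility SNP
        for k in range(n):
            m = self.mirnas[(k + 1) % len(self.mirnas)]
            rsid = self.plant_hairpin_snp(m, t_offset=14 + k, rng=rng,
                                          label="5p_Seed")
            self.tested["mir"].append(rsid)
            anchor = f"rsSUS{k + 1:03d}"
            self.truth.susceptibility.append(anchor)
            r2 = float(rng.uniform(max(cfg.r2_strong_ld + 0.05, 0.85), 0.99))
            self.ld_rows.append((rsid, anchor, round(r2, 4)))
            self.truth.planted_candidates[rsid] = ["LD"]
        # BONFERRONI: hairpin and flank SNPs with planted small p-values
        lo, hi = cfg.planted_p_range
        for k in range(n):
            m = self.mirnas[(k + 3) % len(self.mirnas)]
            rsid = self.plant_hairpin_snp(m, t_offset=46 + k, rng=rng,
                                          label="Precursor_Loop")
            self.tested["mir"].append(rsid)
            self.p_values[rsid] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
            self.truth.planted_candidates[rsid] = ["BONFERRONI"]
        for k in range(n):
            m = self.mirnas[(k + 2) % len(self.mirnas)]
            rsid = self.plant_flank_snp(m, genomically_before=(k % 2 == 0),
                                        dist=2500 + 11 * k, rng=rng)
            self.tested["flank"].append(rsid)
            self.p_values[rsid] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
            self.truth.planted_candidates[rsid] = ["BONFERRONI"]

    def make_background_snps(self) -> None:
        """Null SNPs in hairpin flanks, a fraction of them tested; three
        LD blocks among the tested ones."""
        cfg = self.cfg
        rng = self._stream(4)
        tested_flank: list[str] = []
        made = 0
        attempts = 0
        while made < cfg.n_snps and attempts < cfg.n_snps * 50:
            attempts += 1
            m = self.mirnas[int(rng.integers(len(self.mirnas)))]
            before = bool(rng.integers(2))
            dist = int(rng.integers(1, cfg.flank_bp))
            pos0 = m["start"] - dist if before else m["end"] + dist - 1
            if (m["chrom"], pos0) in self.used_positions:
                continue
            ref = "ACGT"[int(rng.integers(4))]
            alt = ref
            while alt == ref:
                alt = "ACGT"[int(rng.integers(4))]
            rsid = self.add_variant(m["chrom"], pos0, ref, alt)
            made += 1
            if rng.random() < cfg.fraction_tested:
                self.tested["flank"].append(rsid)
                tested_flank.append(rsid)
        if made < cfg.n_snps:
            raise ValueError("could not place the requested background SNPs")
        # three LD blocks over the first tested background SNPs
        lo, hi = cfg.r2_within_block_range
        block_size = max(2, min(10, len(tested_flank) // 3))
        for b in range(3):
            block = tested_flank[b * block_size : (b + 1) * block_size]
            if len(block) < 2:
                break
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    r2 = round(float(rng.uniform(lo, hi)), 4)
                    self.ld_rows.append((block[i], block[j], r2))
            self.truth.ld_blocks.append(block)

    # -- UTRs with planted sites and site SNPs ------------------------------

    def _clean_background(self, rng, length: int, panel: list[str]) -> str:
        """A UTR background with no canonical site for any panel family."""
        for _ in range(500):
            seq = _rand_seq(rng, length)
            if not any(scan_sites(seq, self.mature_seqs[m]) for m in panel):
                return seq
        raise RuntimeError("could not draw a site-free UTR background")

    def _site_is_clean(self, fam: str, panel: list[str]) -> bool:
        """True when the family's embedded 8mer binds no other panel family
        (two families can share most of a site pattern by chance)."""
        seed, pats = seed_and_site_patterns(self.mature_seqs[fam])
        probe = "C" * 12 + pats[SiteType.EIGHT_MER] + "C" * 12
        return self._bound_families(probe, panel) == {seed}

    def _bound_families(self, seq: str, panel: list[str]) -> set[str]:
        return {
            seed_family(self.mature_seqs[m])
            for m in panel
            if scan_sites(seq, self.mature_seqs[m])
        }

    def _plant_site(self, rng, utr_len: int, fam_a: str, want_gain: bool,
                    panel: list[str], at: int):
        """Plant an 8mer of family ``fam_a`` at 0-based offset ``at`` with a
        SNP in its seed core destroying it; with ``want_gain``, the
        alternative allele simultaneously creates a site of some other panel
        family (the created site necessarily overlaps the destroyed one, so
        the two patterns must agree over the overlap — all families, site
        types and alignments are searched). Returns the verified
        (ref_seq, snp_offset0, alt_transcript_base, gained, lost) tuple."""
        seed_a, pat_a = seed_and_site_patterns(self.mature_seqs[fam_a])
        p8 = pat_a[SiteType.EIGHT_MER]
        others = [
            m for m in panel
            if seed_family(self.mature_seqs[m]) != seed_a
        ]
        b_types = (SiteType.EIGHT_MER, SiteType.SEVEN_MER_M8,
                   SiteType.SEVEN_MER_A1)
        for _ in range(100):
            base = list(self._clean_background(rng, utr_len, panel))
            base[at : at + 8] = p8
            for d in (1, 2, 3, 4, 5, 6):  # SNP inside the 8mer seed core
                snp_off = at + d
                ref_base = p8[d]
                if want_gain:
                    for fam_b in others:
                        seed_b, pat_b = seed_and_site_patterns(
                            self.mature_seqs[fam_b]
                        )
                        for st in b_types:
                            pb = pat_b[st]
                            for shift in range(len(pb)):
                                s0 = snp_off - shift
                                if s0 < 0 or s0 + len(pb) > utr_len:
                                    continue
                                if pb[shift] == ref_base:
                                    continue
                                trial = list(base)
                                trial[s0 : s0 + len(pb)] = pb
                                trial[snp_off] = ref_base
                                if "".join(trial[at : at + 8]) != p8:
                                    continue
                                got = self._verify_plant(
                                    "".join(trial), snp_off, pb[shift],
                                    panel, seed_a, {seed_b},
                                )
                                if got is not None:
                                    return got
                else:
                    for alt_base in _RNA:
                        if alt_base == ref_base:
                            continue
                        got = self._verify_plant(
                            "".join(base), snp_off, alt_base, panel,
                            seed_a, set(),
                        )
                        if got is not None:
                            return got
        if want_gain:  # pragma: no cover - search above essentially never fails
            return self._plant_site(rng, utr_len, fam_a, False, panel, at)
        raise RuntimeError("could not construct the planted UTR site")

    def _verify_plant(self, ref_seq: str, snp_off: int, alt_base: str,
                      panel: list[str], seed_a: str, gained: set[str]):
        alt_seq = ref_seq[:snp_off] + alt_base + ref_seq[snp_off + 1 :]
        if (self._bound_families(ref_seq, panel) == {seed_a}
                and self._bound_families(alt_seq, panel) == gained):
            return ref_seq, snp_off, alt_base, gained, {seed_a}
        return None

    def make_utrs(self) -> None:
        cfg = self.cfg
        rng = self._stream(5)
        panel = sorted(self.mature_seqs)
        fams_5p = [m for m in panel if m.endswith("5p")]
        for u in range(cfg.n_utrs):
            chrom = f"chr{(u % cfg.n_chroms) + 1}"
            start = 800_000 + (u // cfg.n_chroms) * 400_000
            end = start + cfg.utr_length
            if end > cfg.chrom_length:
                raise ValueError("chrom_length too short for the UTR layout")
            strand = "+" if u % 2 == 0 else "-"
            gene = f"GENE{u + 1}"
            name = f"utr-{gene}"
            candidates_a = [
                fams_5p[(u + k) % len(fams_5p)] for k in range(len(fams_5p))
            ]
            fam_a = next(
                (f for f in candidates_a if self._site_is_clean(f, panel)),
                candidates_a[0],
            )
            ref_seq, snp_off, alt_base, gained, lost = self._plant_site(
                rng, cfg.utr_length, fam_a, u % 2 == 0, panel, at=100
            )
            reverse = strand == "-"
            pos0 = _t2g(start, end, strand, snp_off)
            ref = _genomic_allele(ref_seq[snp_off], reverse)
            alt = _genomic_allele(alt_base, reverse)
            rsid = self.add_variant(chrom, pos0, ref, alt)
            self.tested["utr"].append(rsid)
            self.truth.planted_candidates[rsid] = ["INDEPENDENT"]
            self.truth.planted_gainloss[rsid] = {
                "gained": sorted(gained), "lost": sorted(lost),
            }
            self.truth.utr_snp_positions[rsid] = [name, snp_off + 1, strand]
            for match in scan_sites(ref_seq, self.mature_seqs[fam_a],
                                    mirna_name=fam_a):
                self.truth.planted_sites.setdefault(name, []).append(
                    [match.family_seed, match.site_type.value,
                     match.utr_start, match.utr_end]
                )
            self.utrs.append({
                "name": name, "gene": gene, "chrom": chrom, "start": start,
                "end": end, "strand": strand, "seq": ref_seq,
            })
        # a second, consortium-listed site SNP in the first UTR
        self._add_second_utr_snp(rng)
        # one clump lead also appears on the consortium list, so the
        # independent-set union has a non-empty overlap
        if len(self.tested["utr"]) > 2:
            self.truth.consortium_independent.append(self.tested["utr"][1])

    def _add_second_utr_snp(self, rng) -> None:
        """Plant a second disrupting SNP in UTR 0 at a distant locus; it is
        claimed by the first SNP's clump and re-enters through the
        consortium independent list (exercising the union)."""
        utr = self.utrs[0]
        panel = sorted(self.mature_seqs)
        first_rsid = self.tested["utr"][0]
        gl0 = self.truth.planted_gainloss[first_rsid]
        in_play = set(gl0["gained"]) | set(gl0["lost"])
        fam_c = next(
            m for m in panel
            if m.endswith("3p")
            and seed_family(self.mature_seqs[m]) not in in_play
            and self._site_is_clean(m, panel)
        )
        seed_c, pat_c = seed_and_site_patterns(self.mature_seqs[fam_c])
        p8 = pat_c[SiteType.EIGHT_MER]
        base = utr["seq"]
        prior = self._bound_families(base, panel)
        # the first SNP's planted gain/loss must survive this second edit
        first_pos0 = self.truth.utr_snp_positions[first_rsid][1] - 1
        first_alt = None
        for r, (_c, _p, _ref, alt) in self.variants.items():
            if r == first_rsid:
                first_alt = transcript_base(alt, utr["strand"] == "-")
        expected_alt1 = (
            (prior | {seed_c}) - set(gl0["lost"]) | set(gl0["gained"])
        )
        for _ in range(200):
            at = 160 + 8 * int(rng.integers(0, (self.cfg.utr_length - 170) // 8))
            seq = list(base)
            seq[at : at + 8] = p8
            snp_off = at + int(rng.integers(1, 6))
            ref_base = seq[snp_off]
            alt_base = ref_base
            while alt_base == ref_base:
                alt_base = _RNA[int(rng.integers(4))]
            ref_seq = "".join(seq)
            alt_seq = ref_seq[:snp_off] + alt_base + ref_seq[snp_off + 1 :]
            alt1_seq = (ref_seq[:first_pos0] + first_alt
                        + ref_seq[first_pos0 + 1 :])
            if (self._bound_families(ref_seq, panel) == prior | {seed_c}
                    and self._bound_families(alt_seq, panel) == prior
                    and self._bound_families(alt1_seq, panel) == expected_alt1):
                break
        else:
            raise RuntimeError("could not plant the second UTR site")
        utr["seq"] = ref_seq
        reverse = utr["strand"] == "-"
        pos0 = _t2g(utr["start"], utr["end"], utr["strand"], snp_off)
        rsid = self.add_variant(
            utr["chrom"], pos0,
            _genomic_allele(ref_base, reverse), _genomic_allele(alt_base, reverse),
        )
        self.tested["utr"].append(rsid)
        self.truth.planted_candidates[rsid] = ["INDEPENDENT"]
        self.truth.planted_gainloss[rsid] = {"gained": [], "lost": [seed_c]}
        self.truth.utr_snp_positions[rsid] = [utr["name"], snp_off + 1,
                                              utr["strand"]]
        self.truth.consortium_independent.append(rsid)
        self.utr0_secondary = rsid
        for match in scan_sites(ref_seq, self.mature_seqs[fam_c],
                                mirna_name=fam_c):
            self.truth.planted_sites.setdefault(utr["name"], []).append(
                [match.family_seed, match.site_type.value,
                 match.utr_start, match.utr_end]
            )

    # -- GWAS statistics, evidence, manifest --------------------------------

    def assign_statistics(self) -> None:
        cfg = self.cfg
        rng = self._stream(6)
        thresholds = {
            "mir": cfg.alpha / len(self.tested["mir"]) if self.tested["mir"] else None,
            "flank": cfg.alpha / len(self.tested["flank"]) if self.tested["flank"] else None,
            "utr": None,  # the UTR class is not Bonferroni-screened
        }
        ind_lo, ind_hi = cfg.independent_p_range
        or_lo, or_hi = cfg.planted_or_range
        for cls in ("mir", "flank", "utr"):
            floor = thresholds[cls] if cfg.exclude_null_significants else None
            for rsid in self.tested[cls]:
                if rsid not in self.p_values:
                    if cls == "utr":
                        self.p_values[rsid] = float(
                            10 ** rng.uniform(np.log10(ind_lo), np.log10(ind_hi))
                        )
                    else:
                        self.p_values[rsid] = _null_p(rng, floor)
                self.odds_ratios[rsid] = round(float(rng.uniform(or_lo, or_hi)), 4)
        # the second UTR-0 SNP shares a clump with that UTR's primary site
        # SNP and must not lead it, or the truth tables would disagree
        second = getattr(self, "utr0_secondary", None)
        if second is not None:
            primary = self.tested["utr"][0]
            if self.p_values[second] <= self.p_values[primary]:
                self.p_values[primary], self.p_values[second] = (
                    self.p_values[second], self.p_values[primary],
                )

    def make_evidence(self) -> None:
        """Give the first planted UTR candidates full evidence (all three
        criteria), one an out-of-whitelist eQTL, the rest nothing."""
        self.eqtl_rows: list[tuple[str, str, str, str]] = []
        self.expr_rows: list[tuple[str, str, float]] = []
        whitelist_tissue = "monocytes"
        utr_rsids = self.tested["utr"]
        gene_of = {}
        for rsid in utr_rsids:
            name = self.truth.utr_snp_positions[rsid][0]
            gene_of[rsid] = next(u["gene"] for u in self.utrs if u["name"] == name)
        members = {
            seed_family(seq): name for name, seq in sorted(self.mature_seqs.items())
        }
        n_full = min(self.cfg.n_planted_per_criterion, len(utr_rsids))
        for k, rsid in enumerate(utr_rsids):
            gl = self.truth.planted_gainloss[rsid]
            changed = sorted(set(gl["gained"]) | set(gl["lost"]))
            if k < n_full:
                self.eqtl_rows.append((rsid, gene_of[rsid], whitelist_tissue, "down"))
                for seed in changed:
                    self.expr_rows.append((members[seed], whitelist_tissue, 25.0))
                count = 3
            elif k == n_full:
                self.eqtl_rows.append((rsid, gene_of[rsid], "skin", "up"))
                count = 1
            else:
                count = 1
            self.truth.planted_candidates[rsid] = sorted(
                set(self.truth.planted_candidates[rsid])
            )
            self.truth.evidence_counts[rsid] = count

    # -- writers ------------------------------------------------------------

    def write_all(self) -> None:
        out = self.outdir
        out.mkdir(parents=True, exist_ok=True)
        files = {}

        gff = out / "mirnas.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, m in enumerate(self.mirnas):
                fh.write("\t".join([
                    m["chrom"], "mirvar_sim", "miRNA_primary_transcript",
                    str(m["start"] + 1), str(m["end"]), ".", m["strand"], ".",
                    f"ID={m['accession']};Name={m['name']}",
                ]) + "\n")
                for arm, span in (("5p", self._ARM_5P), ("3p", self._ARM_3P)):
                    a0, a1 = self._arm_interval(m, span)
                    fh.write("\t".join([
                        m["chrom"], "mirvar_sim", "miRNA",
                        str(a0 + 1), str(a1), ".", m["strand"], ".",
                        f"ID=MIMAT{i + 1:06d}{arm};"
                        f"Name=syn-miR-{i + 1}-{arm};"
                        f"Derives_from={m['accession']}",
                    ]) + "\n")
        files["mirna_gff3"] = str(gff)

        vcf = out / "variants.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in range(self.cfg.n_chroms):
                fh.write(f"##contig=<ID=chr{c + 1},length={self.cfg.chrom_length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            rows = sorted(
                ((chrom, pos0, rsid, ref, alt)
                 for rsid, (chrom, pos0, ref, alt) in self.variants.items()),
                key=lambda r: (r[0], r[1], r[4]),
            )
            for chrom, pos0, rsid, ref, alt in rows:
                fh.write(f"{chrom}\t{pos0 + 1}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\n")
        files["variants_vcf"] = str(vcf)

        gwas = out / "gwas.tsv"
        with open(gwas, "w") as fh:
            fh.write("chrom\tpos\trsid\tallele1\tallele2\tp\tOR\n")
            rows = []
            for cls in ("mir", "flank", "utr"):
                for rsid in self.tested[cls]:
                    chrom, pos0, ref, alt = self.variants[rsid]
                    rows.append((chrom, pos0 + 1, rsid, alt, ref,
                                 f"{self.p_values[rsid]:.6E}",
                                 f"{self.odds_ratios[rsid]:.4f}"))
            rows.sort()
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
        files["gwas_tsv"] = str(gwas)

        ld = out / "ld.tsv"
        with open(ld, "w") as fh:
            fh.write("rsid_a\trsid_b\tr2\n")
            for a, b, r2 in sorted(self.ld_rows):
                fh.write(f"{a}\t{b}\t{r2}\n")
        files["ld_tsv"] = str(ld)

        sus = out / "susceptibility.tsv"
        with open(sus, "w") as fh:
            fh.write("rsid\n")
            for rsid in sorted(set(self.truth.susceptibility)):
                fh.write(rsid + "\n")
        files["susceptibility_tsv"] = str(sus)

        ind = out / "independent_list.tsv"
        with open(ind, "w") as fh:
            fh.write("rsid\n")
            for rsid in sorted(set(self.truth.consortium_independent)):
                fh.write(rsid + "\n")
        files["independent_tsv"] = str(ind)

        hp = out / "hairpins.fasta"
        with open(hp, "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m['name']}\n{self.hairpin_seqs[m['name']]}\n")
        files["hairpins_fasta"] = str(hp)

        mat = out / "matures.fasta"
        with open(mat, "w") as fh:
            for name in sorted(self.mature_seqs):
                fh.write(f">{name}\n{self.mature_seqs[name]}\n")
        files["matures_fasta"] = str(mat)

        utr_fa = out / "utrs.fasta"
        utr_tsv = out / "utr_regions.tsv"
        with open(utr_fa, "w") as fa, open(utr_tsv, "w") as tv:
            tv.write("utr_name\tchrom\tstart\tend\tstrand\ttarget_gene\n")
            for u in self.utrs:
                fa.write(f">{u['name']}\n{u['seq']}\n")
                tv.write(f"{u['name']}\t{u['chrom']}\t{u['start']}\t{u['end']}\t"
                         f"{u['strand']}\t{u['gene']}\n")
        files["utrs_fasta"] = str(utr_fa)
        files["utr_regions_tsv"] = str(utr_tsv)

        eq = out / "eqtl.tsv"
        with open(eq, "w") as fh:
            fh.write("rsid\ttarget_gene\ttissue\tdirection\n")
            for row in sorted(self.eqtl_rows):
                fh.write("\t".join(row) + "\n")
        files["eqtl_tsv"] = str(eq)

        ex = out / "mirna_expression.tsv"
        with open(ex, "w") as fh:
            fh.write("mirna_name\ttissue\ttpm\n")
            for name, tissue, tpm in sorted(set(self.expr_rows)):
                fh.write(f"{name}\t{tissue}\t{tpm}\n")
        files["expression_tsv"] = str(ex)

        self.truth.tested_by_class = {
            cls: sorted(self.tested[cls]) for cls in self.tested
        }
        self.truth.tested_subset = sorted(
            r for lst in self.tested.values() for r in lst
        )
        self.truth.files = files
        manifest = out / "manifest.yaml"
        self.truth.to_yaml(manifest)
        self.truth.files["manifest"] = str(manifest)


def generate_cohort(
    cfg: GeneratorConfig, outdir: str | Path
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write a complete synthetic cohort to ``outdir``.

    Returns the mapping of logical file names to paths and the ground-truth
    manifest. Identical configurations produce byte-identical files.
    """
    cohort = _Cohort(cfg, Path(outdir))
    cohort.make_mirnas()
    cohort.make_region_snps()
    cohort.make_criterion_snps()
    cohort.make_background_snps()
    cohort.make_utrs()
    cohort.assign_statistics()
    cohort.make_evidence()
    cohort.write_all()
    return cohort.truth.files, cohort.truth
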