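"""Canonical seed-match target-site prediction on 3'UTR sequences.

A miRNA recognises a site through its seed (positions 2-8 from the 5' end).
The canonical site types on the UTR, written 5'->3' in UTR sense, are

* 8mer:     reverse complement of seed positions 2-8, followed by an A
* 7mer-m8:  reverse complement of positions 2-8
* 7mer-A1:  reverse complement of positions 2-7, followed by an A
* 6mer:     reverse complement of positions 2-7

The position-1 A is a literal adenine in the UTR regardless of the miRNA's
first base. Matching is strict Watson-Crick (no G:U wobble), and the longest
site at a given seed-pairing locus wins: an 8mer suppresses the nested
7mers, and each 7mer suppresses its nested 6mer. miRNAs with identical
positions 2-8 form a family and bind identical site sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from mirvar.io import normalise_rna

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp_rna(seq: str) -> str:
    """Strict Watson-Crick reverse complement on the RNA alphabet."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


class SiteType(Enum):
    EIGHT_MER = "8mer"
    SEVEN_MER_M8 = "7mer-m8"
    SEVEN_MER_A1 = "7mer-A1"
    SIX_MER = "6mer"


SITE_LENGTH = {
    SiteType.EIGHT_MER: 8,
    SiteType.SEVEN_MER_M8: 7,
    SiteType.SEVEN_MER_A1: 7,
    SiteType.SIX_MER: 6,
}


@dataclass(frozen=True, order=True)
class SiteMatch:
    """One canonical site occurrence; UTR positions are 1-based inclusive."""

    mirna_name: str
    family_seed: str
    site_type: SiteType
    utr_start: int
    utr_end: int

    def __post_init__(self) -> None:
        if self.utr_end - self.utr_start + 1 != SITE_LENGTH[self.site_type]:
            raise ValueError(
                f"{self.site_type.value} site must span "
                f"{SITE_LENGTH[self.site_type]} nt"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """An externally predicted miRNA-target site with its prediction p-value."""

    mirna_name: str
    target_name: str
    p_value: float
    site_start: int = 0
    site_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("prediction p-value must be in (0, 1]")


def seed_family(mirna_seq: str) -> str:
    """The 7-nt family seed: miRNA positions 2-8 in the RNA alphabet."""
    seq = normalise_rna(mirna_seq)
    if len(seq) < 8:
        raise ValueError(f"miRNA shorter than 8 nt ({len(seq)} nt)")
    return seq[1:8]


def seed_and_site_patterns(mirna_seq: str) -> tuple[str, dict[SiteType, str]]:
    """Derive the family seed and the UTR-sense site patterns for one miRNA."""
    seed7 = seed_family(mirna_seq)
    core6 = seed7[:-1]  # positions 2-7
    patterns = {
        SiteType.EIGHT_MER: revcomp_rna(seed7) + "A",
        SiteType.SEVEN_MER_M8: revcomp_rna(seed7),
        SiteType.SEVEN_MER_A1: revcomp_rna(core6) + "A",
        SiteType.SIX_MER: revcomp_rna(core6),
    }
    return seed7, patterns


def scan_sites(
    utr_seq: str,
    mirna_seq: str,
    *,
    include_six_mer: bool = False,
    mirna_name: str = "",
) -> list[SiteMatch]:
    """All canonical sites of one miRNA on one UTR, longest match first.

    At each locus where the 6-nt seed core (positions 2-7) pairs, the site is
    typed by whether the flanking UTR bases extend the match: pairing at m8
    and a downstream A give an 8mer; m8 alone a 7mer-m8; the A alone a
    7mer-A1; neither a 6mer (reported only with ``include_six_mer``). This
    reproduces longest-match precedence exactly: nested shorter sites at the
    same locus are never double-reported. DNA input is accepted (T == U).
    """
    utr = normalise_rna(utr_seq)
    seed7, _ = seed_and_site_patterns(mirna_seq)
    core = revcomp_rna(seed7[:-1])      # pairs miRNA positions 2-7
    m8_base = revcomp_rna(seed7[-1])    # UTR base pairing miRNA position 8
    name = mirna_name
    out: list[SiteMatch] = []
    for i in range(len(utr) - len(core) + 1):
        if utr[i : i + len(core)] != core:
            continue
        has_m8 = i > 0 and utr[i - 1] == m8_base
        has_a1 = i + len(core) < len(utr) and utr[i + len(core)] == "A"
        if has_m8 and has_a1:
            out.append(SiteMatch(name, seed7, SiteType.EIGHT_MER, i, i + 7))
        elif has_m8:
            out.append(SiteMatch(name, seed7, SiteType.SEVEN_MER_M8, i, i + 6))
        elif has_a1:
            out.append(SiteMatch(name, seed7, SiteType.SEVEN_MER_A1, i + 1, i + 7))
        elif include_six_mer:
            out.append(SiteMatch(name, seed7, SiteType.SIX_MER, i + 1, i + 6))
    return sorted(out, key=lambda s: (s.utr_start, s.site_type.value))


def filter_best_predictions(
    records: list[PredictionRecord],
    p_max: float = 0.0314,
) -> list[PredictionRecord]:
    """Keep, per (miRNA, target) pair, the single most significant prediction.

    The surviving record is kept only if its p-value is strictly below
    ``p_max``. Ties on the minimum p are broken by smallest site start, then
    lexicographically on the site interval.
    """
    best: dict[tuple[str, str], PredictionRecord] = {}
    for rec in records:
        key = (rec.mirna_name, rec.target_name)
        cur = best.get(key)
        rank = (rec.p_value, rec.site_start, rec.site_end)
        if cur is None or rank < (cur.p_value, cur.site_start, cur.site_end):
            best[key] = rec
    return [best[k] for k in sorted(best) if best[k].p_value < p_max]
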