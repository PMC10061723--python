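"""Allele-swap construction of variant sequences and gain/loss analysis.

A SNP in a 3'UTR can destroy or create canonical miRNA binding sites; a SNP
in a miRNA seed changes which UTRs the miRNA recognises. Both directions are
analysed by substituting the alternative allele into the transcript-sense
sequence and comparing the canonical-site scans of the two alleles.

Alleles are stored genomic-forward. When the transcript lies on the reverse
strand, the complement of the stored alleles is what appears in (and is
substituted into) the transcript-sense sequence.

Binding is compared at seed-family granularity: miRNAs sharing positions 2-8
bind identical canonical sites, so a panel is collapsed by family seed and
the member miRNA names are carried along, giving both a per-family and a
per-miRNA view of the change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from mirvar.io import Variant, normalise_rna
from mirvar.sites import scan_sites, seed_family

#: transcript-sense RNA base observed when the genomic-forward allele is on
#: the reverse strand
_GENOMIC_TO_REVERSE_TRANSCRIPT = {"A": "U", "C": "G", "G": "C", "T": "A"}
_GENOMIC_TO_FORWARD_TRANSCRIPT = {"A": "A", "C": "C", "G": "G", "T": "U"}


def transcript_base(genomic_allele: str, on_reverse_strand: bool) -> str:
    """The RNA base a genomic-forward allele shows in transcript sense."""
    table = (
        _GENOMIC_TO_REVERSE_TRANSCRIPT
        if on_reverse_strand
        else _GENOMIC_TO_FORWARD_TRANSCRIPT
    )
    return table[genomic_allele]


def apply_allele(
    seq: str,
    pos_1based: int,
    ref: str,
    alt: str,
    on_reverse_strand: bool = False,
) -> str:
    """Substitute an allele into a transcript-sense RNA sequence.

    ``ref``/``alt`` are genomic-forward DNA bases; on the reverse strand
    their complements are matched and substituted. The sequence base at the
    given position must equal the (possibly complemented) reference allele,
    else a hard error reports expected vs observed.
    """
    seq = normalise_rna(seq)
    if ref == alt:
        raise ValueError(f"reference and alternative alleles are both {ref!r}")
    if not 1 <= pos_1based <= len(seq):
        raise ValueError(f"position {pos_1based} outside sequence of {len(seq)} nt")
    expected = transcript_base(ref, on_reverse_strand)
    observed = seq[pos_1based - 1]
    if observed != expected:
        raise ValueError(
            f"reference mismatch at position {pos_1based}: expected {expected} "
            f"(genomic {ref}{' on reverse strand' if on_reverse_strand else ''}), "
            f"observed {observed}"
        )
    new = transcript_base(alt, on_reverse_strand)
    return seq[: pos_1based - 1] + new + seq[pos_1based:]


def _families(mirna_panel: Mapping[str, str]) -> dict[str, tuple[str, ...]]:
    """Collapse a miRNA panel by family seed; values are member names."""
    fams: dict[str, list[str]] = {}
    for name in sorted(mirna_panel):
        fams.setdefault(seed_family(mirna_panel[name]), []).append(name)
    return {seed: tuple(names) for seed, names in fams.items()}


@dataclass(frozen=True)
class GainLossResult:
    """Differential binding between the two alleles of one SNP.

    ``gained_families`` bind only the alternative sequence, ``lost_families``
    only the reference; ``net_change = n_alt - n_ref`` counts families, and
    the miRNA-level counterpart is available through ``net_change_mirnas``.
    ``alt_is_risk`` records the orientation when the caller aligned the
    alternative allele with the GWAS risk allele.
    """

    snp: Variant
    gained_families: frozenset[str]
    lost_families: frozenset[str]
    n_ref: int
    n_alt: int
    net_change: int
    family_members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    alt_is_risk: bool | None = None

    def __post_init__(self) -> None:
        if self.gained_families & self.lost_families:
            raise ValueError("a family cannot be both gained and lost")

    def _members(self, seeds: frozenset[str]) -> tuple[str, ...]:
        out: list[str] = []
        for seed in sorted(seeds):
            out.extend(self.family_members.get(seed, (seed,)))
        return tuple(out)

    @property
    def gained_mirnas(self) -> tuple[str, ...]:
        return self._members(self.gained_families)

    @property
    def lost_mirnas(self) -> tuple[str, ...]:
        return self._members(self.lost_families)

    @property
    def net_change_mirnas(self) -> int:
        return len(self.gained_mirnas) - len(self.lost_mirnas)

    @property
    def changed(self) -> bool:
        return bool(self.gained_families or self.lost_families)


def utr_gain_loss(
    utr_ref: str,
    snp: Variant,
    pos_in_utr: int,
    on_reverse_strand: bool,
    mirna_panel: Mapping[str, str],
    *,
    include_six_mer: bool = False,
    alt_is_risk: bool | None = None,
) -> GainLossResult:
    """Which miRNA families bind the reference vs the alternative 3'UTR.

    Scans every panel family against both alleles of the UTR (``pos_in_utr``
    is 1-based in transcript sense) and reports gained/lost families and the
    net change in the number of binding families.
    """
    if not mirna_panel:
        raise ValueError("miRNA panel is empty")
    utr_ref = normalise_rna(utr_ref)
    utr_alt = apply_allele(
        utr_ref, pos_in_utr, snp.ref_allele, snp.alt_allele, on_reverse_strand
    )
    fams = _families(mirna_panel)
    bound_ref: set[str] = set()
    bound_alt: set[str] = set()
    for seed, members in fams.items():
        probe = mirna_panel[members[0]]
        if scan_sites(utr_ref, probe, include_six_mer=include_six_mer):
            bound_ref.add(seed)
        if scan_sites(utr_alt, probe, include_six_mer=include_six_mer):
            bound_alt.add(seed)
    return GainLossResult(
        snp=snp,
        gained_families=frozenset(bound_alt - bound_ref),
        lost_families=frozenset(bound_ref - bound_alt),
        n_ref=len(bound_ref),
        n_alt=len(bound_alt),
        net_change=len(bound_alt) - len(bound_ref),
        family_members=fams,
        alt_is_risk=alt_is_risk,
    )


def seed_gain_loss(
    mirna_ref_seq: str,
    snp_pos_in_mirna: int,
    ref: str,
    alt: str,
    on_reverse_strand: bool,
    utr_panel: Mapping[str, str],
    *,
    include_six_mer: bool = False,
) -> dict[str, tuple[bool, bool]]:
    """Which panel UTRs are bound by the reference vs the variant miRNA.

    The SNP (1-based position within the mature miRNA sequence) is swapped
    into the miRNA; each UTR's binding status under both miRNA alleles is
    returned as ``target -> (bound_by_ref, bound_by_alt)``. Targets lost are
    those bound by the reference only; gains are symmetric.
    """
    mirna_ref = normalise_rna(mirna_ref_seq)
    mirna_alt = apply_allele(mirna_ref, snp_pos_in_mirna, ref, alt, on_reverse_strand)
    out: dict[str, tuple[bool, bool]] = {}
    for target in sorted(utr_panel):
        utr = utr_panel[target]
        by_ref = bool(scan_sites(utr, mirna_ref, include_six_mer=include_six_mer))
        by_alt = bool(scan_sites(utr, mirna_alt, include_six_mer=include_six_mer))
        out[target] = (by_ref, by_alt)
    return out
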