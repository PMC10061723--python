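"""Coordinate arithmetic on miRNA annotations.

Flank extension, SNP-interval intersection, and per-base classification of a
hairpin into seed / mature / loop / precursor-end / flank regions with the
precedence seed > mature > loop > precursor ends > flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from mirvar.io import GenomicInterval, MirnaAnnotation, Variant


class RegionClass(Enum):
    SEED = "Seed"
    MATURE = "Mature"
    LOOP = "Precursor_Loop"
    PRECURSOR_5PRIME_END = "Precursor_5PrimeEnd"
    PRECURSOR_3PRIME_END = "Precursor_3PrimeEnd"
    FLANK_UPSTREAM = "Flank_Upstream"
    FLANK_DOWNSTREAM = "Flank_Downstream"


_ARM_CLASSES = (RegionClass.SEED, RegionClass.MATURE)


@dataclass(frozen=True)
class Region:
    """A region class plus the mature arm it belongs to (seed/mature only)."""

    cls: RegionClass
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.cls in _ARM_CLASSES:
            if self.arm is None:
                raise ValueError(f"{self.cls.name} requires an arm label")
        elif self.arm is not None:
            raise ValueError(f"{self.cls.name} must not carry an arm label")

    @property
    def label(self) -> str:
        if self.cls in _ARM_CLASSES and self.arm != "unlabelled":
            return f"{self.arm}_{self.cls.value}"
        return self.cls.value


@dataclass(frozen=True)
class FlankConfig:
    """Width of the hairpin flanking windows, in bp (0 disables flanks)."""

    flank_bp: int = 5000

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")


def extend_flanks(
    mirna: MirnaAnnotation,
    cfg: FlankConfig = FlankConfig(),
    chrom_length: int | None = None,
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Flanking windows abutting (and excluding) the hairpin body.

    Returned in genomic orientation: the first interval lies at lower
    coordinates than the hairpin, the second at higher ones; both carry the
    hairpin's strand so transcriptional orientation can be recovered.
    Windows are clamped to ``[0, chrom_length)``; an empty window (flank_bp
    of 0, or a hairpin starting at the chromosome edge) is returned as
    ``None``.
    """
    h = mirna.hairpin
    if chrom_length is not None and chrom_length < h.end:
        raise ValueError(f"{mirna.name}: chrom_length shorter than hairpin end")
    up_start = max(0, h.start - cfg.flank_bp)
    down_end = h.end + cfg.flank_bp
    if chrom_length is not None:
        down_end = min(down_end, chrom_length)
    upstream = (
        GenomicInterval(h.chrom, up_start, h.start, h.strand)
        if up_start < h.start
        else None
    )
    downstream = (
        GenomicInterval(h.chrom, h.end, down_end, h.strand)
        if h.end < down_end
        else None
    )
    return upstream, downstream


def intersect_variants(
    intervals: Sequence[GenomicInterval],
    variants: Iterable[Variant],
) -> list[tuple[Variant, GenomicInterval]]:
    """All (variant, interval) pairs with interval.start <= pos < interval.end.

    Each pair is emitted once, ordered by (chrom, pos, interval, alt).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    hits: set[tuple[Variant, GenomicInterval]] = set()
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for node in tree.at(v.pos):
            hits.add((v, node.data))
    return sorted(hits, key=lambda p: (p[0].chrom, p[0].pos, p[1], p[0].alt_allele))


def _mature_offset(pos: int, arm: GenomicInterval) -> int:
    """1-based offset of a genomic position from the mature 5' end."""
    if arm.strand == "+":
        return pos - arm.start + 1
    return arm.end - pos


def annotate_snp_region(
    variant: Variant,
    mirna: MirnaAnnotation,
    cfg: FlankConfig = FlankConfig(),
    *,
    seed_span: tuple[int, int] = (2, 8),
) -> Region:
    """Classify a SNP position relative to one miRNA annotation.

    Precedence: seed > mature > loop > precursor ends > flanks. The seed is
    mature positions ``seed_span`` (default 2-8, 1-based from the mature 5'
    end, strand-aware: on the minus strand the 5' end is the higher genomic
    coordinate). The loop is the hairpin region strictly between two mature
    arms; hairpin bases outside the arms belong to the precursor end on
    their transcriptional side. Hairpins with fewer than two annotated arms
    have no loop; with none at all, bases are split into precursor ends by
    transcriptional half. Flank classes are likewise assigned
    transcriptionally (upstream = 5' of the hairpin), making the
    classification invariant under strand mirroring.
    """
    h = mirna.hairpin
    pos = variant.pos
    lo, hi = max(0, h.start - cfg.flank_bp), h.end + cfg.flank_bp
    if variant.chrom != h.chrom or not lo <= pos < hi:
        raise ValueError(
            f"{variant.rsid} at {variant.chrom}:{pos} is outside "
            f"{mirna.name} +/- {cfg.flank_bp} bp"
        )
    plus = h.strand == "+"
    if pos < h.start or pos >= h.end:
        before = pos < h.start  # genomically before the hairpin
        upstream = before if plus else not before
        return Region(
            RegionClass.FLANK_UPSTREAM if upstream else RegionClass.FLANK_DOWNSTREAM
        )

    arms = sorted((iv for _, iv in mirna.matures), key=lambda iv: iv.start)
    labels = {iv: arm for arm, iv in mirna.matures}
    for iv in arms:
        if iv.start <= pos < iv.end:
            off = _mature_offset(pos, iv)
            if seed_span[0] <= off <= seed_span[1]:
                return Region(RegionClass.SEED, labels[iv])
            return Region(RegionClass.MATURE, labels[iv])

    if len(arms) >= 2 and arms[0].end <= pos < arms[-1].start:
        return Region(RegionClass.LOOP)

    # hairpin base outside every arm: precursor end on its transcriptional side
    if arms:
        genomically_before = pos < arms[0].start
    else:
        genomically_before = pos - h.start < h.end - 1 - pos
    five_prime = genomically_before if plus else not genomically_before
    return Region(
        RegionClass.PRECURSOR_5PRIME_END
        if five_prime
        else RegionClass.PRECURSOR_3PRIME_END
    )
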