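"""Prioritisation criteria, independence machinery, and candidate assembly.

A collated miRNA-associated SNP becomes a candidate if it

* KNOWN       — is itself among the known susceptibility SNPs,
* LD          — is in strong linkage disequilibrium (r² >= threshold) with
                one, or
* BONFERRONI  — has an association p-value strictly below the class-specific
                Bonferroni threshold alpha / n_tested, where n_tested is the
                per-run count of tested SNPs in that class,

while 3'UTR binding-site SNPs are additionally screened through an
INDEPENDENT branch: greedy LD clumping of the summary statistics plus a
consortium-supplied independent/suggestive list, combined by set union.
The three criteria are computed independently of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mirvar.alleles import GainLossResult
from mirvar.io import GwasRecord, LdTable, Variant
from mirvar.regions import Region

logger = logging.getLogger(__name__)

KNOWN = "KNOWN"
LD = "LD"
BONFERRONI = "BONFERRONI"
INDEPENDENT = "INDEPENDENT"


@dataclass(frozen=True)
class PrioritizationConfig:
    alpha: float = 0.05
    r2_strong_ld: float = 0.8
    r2_clump: float = 0.6
    clump_window_bp: int = 250_000
    genome_wide_p: float = 5e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("r2_strong_ld", "r2_clump"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.clump_window_bp < 0:
            raise ValueError("clump_window_bp must be non-negative")


@dataclass(frozen=True)
class CandidateRecord:
    """One prioritised SNP with its criteria and downstream annotations."""

    gwas: GwasRecord
    region: Region | str
    criteria: frozenset[str]
    ld_anchor: tuple[str, float] | None = None
    gainloss: GainLossResult | None = None
    stability: float | None = None
    evidence_count: int = 0

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("a candidate must satisfy at least one criterion")
        if (LD in self.criteria) != (self.ld_anchor is not None):
            raise ValueError("ld_anchor must be present iff the LD criterion is")

    @property
    def rsid(self) -> str:
        return self.gwas.rsid

    @property
    def region_label(self) -> str:
        return self.region if isinstance(self.region, str) else self.region.label


def restrict_to_tested(
    variants: Sequence[Variant],
    gwas: Sequence[GwasRecord],
    *,
    match_by_rsid: bool = False,
) -> list[GwasRecord]:
    """The subset of GWAS records whose variant matches a collated variant.

    The default join key is (chrom, pos, allele set); rsid-only matching is
    a configurable fallback. rsid disagreements under the positional key are
    logged as a cross-check. Output preserves summary-statistics order.
    """
    if match_by_rsid:
        wanted = {v.rsid for v in variants}
        out = [g for g in gwas if g.rsid in wanted]
    else:
        by_key = {v.allele_key: v for v in variants}
        out = []
        for g in gwas:
            hit = by_key.get(g.variant.allele_key)
            if hit is None:
                continue
            if hit.rsid != g.rsid:
                logger.warning(
                    "rsid mismatch at %s:%d: collated %s vs tested %s",
                    g.variant.chrom, g.variant.pos, hit.rsid, g.rsid,
                )
            out.append(g)
    logger.info("restrict_to_tested: %d of %d tested records match", len(out), len(gwas))
    return out


def bonferroni_threshold(alpha: float, n_tested: int) -> float:
    """Family-wise threshold alpha / n_tested."""
    if n_tested < 1:
        raise ValueError("n_tested must be at least 1")
    return alpha / n_tested


def criterion_known(
    tested: Sequence[GwasRecord], susceptibility: Iterable[str]
) -> list[GwasRecord]:
    """Tested SNPs that are themselves known susceptibility SNPs."""
    wanted = set(susceptibility)
    seen: set[str] = set()
    out = []
    for g in tested:
        if g.rsid in wanted and g.rsid not in seen:
            out.append(g)
            seen.add(g.rsid)
    return out


def criterion_ld(
    tested: Sequence[GwasRecord],
    susceptibility: Iterable[str],
    ld: LdTable,
    r2_min: float = 0.8,
) -> list[tuple[GwasRecord, str, float]]:
    """Tested SNPs in strong LD with a susceptibility SNP.

    Returns (record, anchor rsid, r²) with the best anchor per SNP; SNPs
    that are themselves in the susceptibility set are excluded (they belong
    to the KNOWN branch). Absent LD data excludes a pair.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError("r2_min must be in (0, 1]")
    sus = set(susceptibility)
    out = []
    for g in tested:
        if g.rsid in sus:
            continue
        best: tuple[str, float] | None = None
        for anchor in sorted(sus):
            r2 = ld.get(g.rsid, anchor)
            if r2 is not None and r2 >= r2_min:
                if best is None or r2 > best[1]:
                    best = (anchor, r2)
        if best is not None:
            out.append((g, best[0], best[1]))
    return out


def criterion_bonferroni(
    tested: Sequence[GwasRecord], alpha: float = 0.05
) -> list[GwasRecord]:
    """Tested SNPs with p strictly below alpha / (number tested)."""
    if not tested:
        raise ValueError("criterion_bonferroni requires a non-empty tested set")
    threshold = bonferroni_threshold(alpha, len(tested))
    return [g for g in tested if g.p_value < threshold]


def clump_independent(
    gwas: Sequence[GwasRecord],
    ld: LdTable,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> list[str]:
    """Greedy clumping: rank by p, claim LD partners and positional neighbours.

    SNPs are sorted by ascending p (ties: chrom, pos); the best unclaimed
    SNP becomes an independent lead and claims every SNP with r² >= r2_clump
    to it or lying within clump_window_bp on the same chromosome. Leads are
    returned in selection order.
    """
    ranked = sorted(gwas, key=lambda g: (g.p_value, g.variant.chrom, g.variant.pos))
    claimed: set[str] = set()
    leads: list[str] = []
    for g in ranked:
        if g.rsid in claimed:
            continue
        leads.append(g.rsid)
        claimed.add(g.rsid)
        for other in ranked:
            if other.rsid in claimed:
                continue
            r2 = ld.get(g.rsid, other.rsid)
            in_ld = r2 is not None and r2 >= cfg.r2_clump
            in_window = (
                other.variant.chrom == g.variant.chrom
                and abs(other.variant.pos - g.variant.pos) <= cfg.clump_window_bp
            )
            if in_ld or in_window:
                claimed.add(other.rsid)
    return leads


def union_independent(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[set[str], int]:
    """Union of two independent-SNP lists, reporting the overlap size."""
    a, b = set(set_a), set(set_b)
    return a | b, len(a & b)


def combine_candidates(
    known: Sequence[GwasRecord] = (),
    ld_flagged: Sequence[tuple[GwasRecord, str, float]] = (),
    bonferroni: Sequence[GwasRecord] = (),
    independent: Sequence[GwasRecord] = (),
    *,
    regions: Mapping[str, Region | str] | None = None,
    gainloss: Mapping[str, GainLossResult] | None = None,
    stability: Mapping[str, float] | None = None,
    evidence_counts: Mapping[str, int] | None = None,
) -> list[CandidateRecord]:
    """Assemble one record per SNP with the union of its criteria flags.

    Downstream annotations (region class, gain/loss, stability delta,
    evidence count) are attached by rsid. Two different GwasRecords for the
    same matching key are a hard error; SNPs with no flags are never
    emitted. Output is sorted by (chrom, pos, alt).
    """
    regions = regions or {}
    gainloss = gainloss or {}
    stability = stability or {}
    evidence_counts = evidence_counts or {}

    flags: dict[str, set[str]] = {}
    records: dict[str, GwasRecord] = {}
    anchors: dict[str, tuple[str, float]] = {}

    def register(g: GwasRecord, flag: str) -> None:
        prev = records.get(g.rsid)
        if prev is not None and prev != g:
            raise ValueError(f"conflicting GWAS records for {g.rsid}")
        records[g.rsid] = g
        flags.setdefault(g.rsid, set()).add(flag)

    for g in known:
        register(g, KNOWN)
    for g, anchor, r2 in ld_flagged:
        register(g, LD)
        anchors[g.rsid] = (anchor, r2)
    for g in bonferroni:
        register(g, BONFERRONI)
    for g in independent:
        register(g, INDEPENDENT)

    out = [
        CandidateRecord(
            gwas=records[rsid],
            region=regions.get(rsid, "."),
            criteria=frozenset(crit),
            ld_anchor=anchors.get(rsid),
            gainloss=gainloss.get(rsid),
            stability=stability.get(rsid),
            evidence_count=evidence_counts.get(rsid, 0),
        )
        for rsid, crit in flags.items()
    ]
    out.sort(
        key=lambda c: (c.gwas.variant.chrom, c.gwas.variant.pos,
                       c.gwas.variant.alt_allele)
    )
    return out
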