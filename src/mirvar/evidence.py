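"""Functional-evidence scoring of candidate 3'UTR SNPs.

A candidate is scored against three adapted miRNA-target validation
criteria: (1) it changes miRNA-target interactions at the binding site
(non-empty gain/loss), (2) it acts as an eQTL for the target gene in a
disease-relevant tissue, and (3) the gained/lost miRNAs are expressed in
that same tissue. A candidate meeting all three is flagged as prioritised.

Expression is banded on TPM anchors 0.5 / 10 / 1000 with left-closed
boundaries, and "expressed" means at least the LOW band (TPM >= 0.5).
eQTL direction is recorded but never used as a gate, because public MS and
non-MS eQTL datasets disagree on direction for some targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable

from mirvar.alleles import GainLossResult


class ExpressionBand(IntEnum):
    NOT_EXPRESSED = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3


def categorize_expression(tpm: float) -> ExpressionBand:
    """Band a TPM value on the 0.5 / 10 / 1000 anchors (left-closed)."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if tpm < 0.5:
        return ExpressionBand.NOT_EXPRESSED
    if tpm < 10:
        return ExpressionBand.LOW
    if tpm < 1000:
        return ExpressionBand.MEDIUM
    return ExpressionBand.HIGH


@dataclass(frozen=True)
class EqtlRow:
    rsid: str
    target_gene: str
    tissue: str
    direction: str  # "up" or "down"; recorded, not gated on


@dataclass(frozen=True)
class ExpressionRow:
    mirna_name: str
    tissue: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"{self.mirna_name}: negative TPM")


@dataclass(frozen=True)
class EvidenceTables:
    """eQTL hits, miRNA expression, and the disease-relevant tissue whitelist.

    Tissue names are free text and matched case-insensitively against the
    whitelist.
    """

    eqtl: tuple[EqtlRow, ...] = ()
    mirna_expression: tuple[ExpressionRow, ...] = ()
    tissue_whitelist: frozenset[str] = frozenset()

    def _whitelist(self) -> frozenset[str]:
        return frozenset(t.lower() for t in self.tissue_whitelist)


@dataclass(frozen=True)
class EvidenceFlags:
    interaction_change: bool
    eqtl_in_tissue: bool
    mirna_expressed_same_tissue: bool

    @property
    def count(self) -> int:
        return sum(
            (self.interaction_change, self.eqtl_in_tissue,
             self.mirna_expressed_same_tissue)
        )

    @property
    def prioritized(self) -> bool:
        return self.count == 3


def evaluate_criteria(
    rsid: str,
    target_gene: str | None,
    gainloss: GainLossResult | None,
    tables: EvidenceTables,
    *,
    require_same_tissue: bool = True,
) -> EvidenceFlags:
    """Score one candidate against the three validation criteria.

    ``interaction_change`` holds iff the gain/loss result is non-empty;
    ``eqtl_in_tissue`` iff an eQTL row links the SNP to the target in a
    whitelisted tissue; ``mirna_expressed_same_tissue`` iff some gained or
    lost family member has TPM >= 0.5 in a tissue that also carries such an
    eQTL signal (with ``require_same_tissue=False``, any whitelisted tissue
    suffices).
    """
    whitelist = tables._whitelist()
    interaction = gainloss is not None and gainloss.changed

    eqtl_tissues = {
        row.tissue.lower()
        for row in tables.eqtl
        if row.rsid == rsid
        and (target_gene is None or row.target_gene == target_gene)
        and row.tissue.lower() in whitelist
    }
    eqtl_in_tissue = bool(eqtl_tissues)

    changed_mirnas: set[str] = set()
    if gainloss is not None:
        changed_mirnas = set(gainloss.gained_mirnas) | set(gainloss.lost_mirnas)
    allowed_tissues = eqtl_tissues if require_same_tissue else whitelist
    expressed = any(
        row.mirna_name in changed_mirnas
        and row.tissue.lower() in allowed_tissues
        and categorize_expression(row.tpm) >= ExpressionBand.LOW
        for row in tables.mirna_expression
    )
    return EvidenceFlags(interaction, eqtl_in_tissue, expressed)


def read_evidence_tables(
    eqtl_path, expression_path, tissue_whitelist: Iterable[str]
) -> EvidenceTables:
    """Load evidence TSVs (rsid/target_gene/tissue/direction and
    mirna_name/tissue/tpm) into an EvidenceTables bundle."""
    import pandas as pd

    eq = pd.read_csv(eqtl_path, sep="\t", dtype=str)
    ex = pd.read_csv(expression_path, sep="\t", dtype={"tpm": float})
    return EvidenceTables(
        eqtl=tuple(
            EqtlRow(r.rsid, r.target_gene, r.tissue, r.direction)
            for r in eq.itertuples(index=False)
        ),
        mirna_expression=tuple(
            ExpressionRow(r.mirna_name, r.tissue, float(r.tpm))
            for r in ex.itertuples(index=False)
        ),
        tissue_whitelist=frozenset(tissue_whitelist),
    )
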