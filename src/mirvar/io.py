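"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are converted to one internal convention at the
boundary: 0-based, half-open, per chromosome. GFF3 (1-based closed) and VCF
(1-based) are converted on read and back-converted on write. Sequences are
held in the RNA alphabet (T is normalised to U on read).

One genome build per run is assumed; no liftover is performed here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_BASES = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGUN")

#: typographic minus sign, as printed in some summary-statistics exports
_MINUS_SIGN = "−"


def _parse_float(text: str) -> float:
    """Parse a float accepting the typographic minus sign in exponents."""
    return float(str(text).strip().replace(_MINUS_SIGN, "-"))


def normalise_rna(seq: str, *, record: str = "") -> str:
    """Upper-case a nucleotide string and rewrite T as U (RNA alphabet)."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        where = f" in record {record!r}" if record else ""
        raise ValueError(f"non-nucleotide characters {sorted(bad)}{where}")
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class MirnaAnnotation:
    """A miRNA hairpin plus its mature-arm sub-intervals.

    ``matures`` maps arm labels (``"5p"``, ``"3p"`` or ``"unlabelled"``) to
    genomic intervals. Every mature arm must be contained in the hairpin,
    share its chromosome and strand, and arms must not overlap each other.
    """

    name: str
    accession: str
    hairpin: GenomicInterval
    matures: tuple[tuple[str, GenomicInterval], ...] = ()

    def __post_init__(self) -> None:
        seen: list[GenomicInterval] = []
        for arm, iv in self.matures:
            if arm not in ("5p", "3p", "unlabelled"):
                raise ValueError(f"{self.name}: bad arm label {arm!r}")
            if iv.strand != self.hairpin.strand or iv.chrom != self.hairpin.chrom:
                raise ValueError(f"{self.name}: mature arm not on hairpin strand/chrom")
            if not self.hairpin.contains_interval(iv):
                raise ValueError(f"{self.name}: mature arm outside hairpin")
            for prev in seen:
                if iv.start < prev.end and prev.start < iv.end:
                    raise ValueError(f"{self.name}: overlapping mature arms")
            seen.append(iv)

    @property
    def strand(self) -> str:
        return self.hairpin.strand

    def arm(self, label: str) -> GenomicInterval | None:
        for arm, iv in self.matures:
            if arm == label:
                return iv
        return None


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic SNV; ``pos`` is the 0-based offset of the substituted base."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele not in DNA_BASES or self.alt_allele not in DNA_BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single DNA bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: negative position")

    @property
    def allele_key(self) -> tuple[str, int, frozenset[str]]:
        """Matching key: (chrom, pos, unordered allele set)."""
        return (self.chrom, self.pos, frozenset((self.ref_allele, self.alt_allele)))


@dataclass(frozen=True)
class GwasRecord:
    """One tested association: a variant with its p-value and odds ratio."""

    variant: Variant
    p_value: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.variant.rsid}: p-value out of (0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.variant.rsid}: odds ratio must be positive")

    @property
    def rsid(self) -> str:
        return self.variant.rsid


class LdTable:
    """Symmetric rsid-pair -> r-squared lookup.

    Absent pairs return ``None`` ("no data"), which is distinct from an
    observed r² of 0.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0, 1] for pair ({a}, {b}): {r2}")
        self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float | None:
        return self._r2.get(self._key(a, b))

    def partners(self, rsid: str) -> list[tuple[str, float]]:
        out = []
        for (a, b), r2 in self._r2.items():
            if a == rsid:
                out.append((b, r2))
            elif b == rsid:
                out.append((a, r2))
        return sorted(out)

    def __len__(self) -> int:
        return len(self._r2)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GFF3_HAIRPIN = "miRNA_primary_transcript"
_GFF3_MATURE = "miRNA"
_ARM_SUFFIX = re.compile(r"-(5p|3p)$")


def _gff3_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_mirbase_gff3(path: str | Path) -> list[MirnaAnnotation]:
    """Read a miRBase-dialect GFF3 file into hairpin + mature annotations.

    Hairpins are ``miRNA_primary_transcript`` features; matures are ``miRNA``
    features linked to their hairpin by a ``Derives_from`` attribute. GFF3
    1-based closed coordinates are converted to 0-based half-open. The arm
    label is taken from a ``-5p``/``-3p`` suffix on the mature name, else
    ``"unlabelled"``.
    """
    hairpins: dict[str, dict] = {}  # accession -> fields
    matures: list[tuple[str, str, GenomicInterval, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(
                    f"{path}: line {lineno}: start > end ({start_i} > {end_i})"
                )
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            a = _gff3_attributes(attrs)
            name = a.get("Name", a.get("ID", ""))
            if ftype == _GFF3_HAIRPIN:
                acc = a.get("ID", name)
                hairpins[acc] = {"name": name, "accession": acc, "hairpin": iv,
                                 "matures": []}
            elif ftype == _GFF3_MATURE:
                parent = a.get("Derives_from")
                if parent is None:
                    raise ValueError(
                        f"{path}: line {lineno}: miRNA feature without Derives_from"
                    )
                m = _ARM_SUFFIX.search(name)
                arm = m.group(1) if m else "unlabelled"
                matures.append((parent, arm, iv, lineno))
    for parent, arm, iv, lineno in matures:
        if parent not in hairpins:
            raise ValueError(
                f"mature feature at line {lineno} derives from unknown "
                f"hairpin accession {parent!r}"
            )
        hairpins[parent]["matures"].append((arm, iv))
    return [
        MirnaAnnotation(
            name=h["name"],
            accession=h["accession"],
            hairpin=h["hairpin"],
            matures=tuple(h["matures"]),
        )
        for h in hairpins.values()
    ]


def _split_alts(rsid: str, chrom: str, pos0: int, ref: str,
                alts: Iterable[str], stats: dict) -> list[Variant]:
    """Split one (possibly multi-allelic) row into biallelic SNV records."""
    out = []
    ref = ref.upper()
    if len(ref) != 1 or ref not in DNA_BASES:
        if len(ref) != 1:
            stats["skipped_indel"] += 1
        else:
            stats["rejected_allele"] += 1
        return out
    for alt in alts:
        alt = alt.upper()
        if len(alt) != 1:
            stats["skipped_indel"] += 1
            continue
        if alt not in DNA_BASES or alt == ref:
            stats["rejected_allele"] += 1
            continue
        out.append(Variant(rsid, chrom, pos0, ref, alt))
    return out


def read_variant_table(
    path: str | Path,
    dialect: str = "vcf",
    *,
    return_stats: bool = False,
) -> list[Variant] | tuple[list[Variant], dict]:
    """Read a variant table as biallelic SNVs.

    ``dialect="vcf"`` reads a (sites-only sufficient) VCF via pysam, 1-based
    positions converted to 0-based. ``dialect="bed_tsv"`` reads a BED-like
    TSV with columns chrom, start (0-based), rsid, ref, alt. Multi-allelic
    rows are split into one record per alternative allele; indels/MNVs are
    skipped and counted; rows with non-ACGT alleles are rejected and counted.
    """
    stats = {"skipped_indel": 0, "rejected_allele": 0}
    variants: list[Variant] = []
    if dialect == "vcf":
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                rsid = rec.id or f"{rec.chrom}:{rec.pos}"
                alts = rec.alts or ()
                variants.extend(
                    _split_alts(rsid, rec.chrom, rec.start, rec.ref or "", alts, stats)
                )
    elif dialect == "bed_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         names=["chrom", "start", "rsid", "ref", "alt"])
        for row in df.itertuples(index=False):
            alts = str(row.alt).split(",")
            variants.extend(
                _split_alts(str(row.rsid), str(row.chrom), int(row.start),
                            str(row.ref), alts, stats)
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if stats["skipped_indel"] or stats["rejected_allele"]:
        logger.info(
            "%s: skipped %d indel/MNV alleles, rejected %d malformed alleles",
            path, stats["skipped_indel"], stats["rejected_allele"],
        )
    if return_stats:
        return variants, stats
    return variants


DEFAULT_SUMSTATS_COLUMNS = {
    "chrom": "chrom",
    "pos": "pos",
    "rsid": "rsid",
    "effect_allele": "allele1",
    "other_allele": "allele2",
    "p": "p",
    "odds_ratio": "OR",
}


def read_summary_stats(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[GwasRecord]:
    """Read GWAS summary statistics from a TSV.

    Positions in the file are 1-based (the usual summary-statistics
    convention) and converted to 0-based internally. p-values are parsed
    exactly from scientific notation, accepting the typographic minus sign.
    The effect allele is stored as the variant's alternative allele and the
    other allele as the reference. Rows with p outside (0, 1] are rejected
    with a warning; a missing mandatory column is a hard error.
    """
    cols = dict(DEFAULT_SUMSTATS_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records: list[GwasRecord] = []
    for row in df.itertuples(index=False):
        get = lambda key: str(getattr(row, cols[key]))
        p = _parse_float(get("p"))
        if not 0.0 < p <= 1.0:
            logger.warning("%s: rejecting %s with p=%r", path, get("rsid"), p)
            continue
        variant = Variant(
            rsid=get("rsid"),
            chrom=get("chrom"),
            pos=int(get("pos")) - 1,
            ref_allele=get("other_allele").upper(),
            alt_allele=get("effect_allele").upper(),
        )
        records.append(GwasRecord(variant, p, _parse_float(get("odds_ratio"))))
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> RNA-alphabet sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record name {rec.id!r}")
        out[rec.id] = normalise_rna(str(rec.seq), record=rec.id)
    return out


def read_ld_table(path: str | Path) -> LdTable:
    """Read a TSV of (rsid_a, rsid_b, r2) into a symmetric lookup.

    Rows with r² outside [0, 1] are rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str,
                                            "r2": float})
    table = LdTable()
    for row in df.itertuples(index=False):
        if not 0.0 <= row.r2 <= 1.0:
            logger.warning("%s: rejecting LD row (%s, %s) with r2=%s",
                           path, row.rsid_a, row.rsid_b, row.r2)
            continue
        table.add(row.rsid_a, row.rsid_b, float(row.r2))
    return table


# ---------------------------------------------------------------------------
# candidate report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt", "region_class", "p", "OR",
    "criteria", "ld_anchor", "ld_anchor_r2", "gained_families",
    "lost_families", "net_change", "stability_delta", "evidence_count",
]


def write_candidate_report(candidates: Iterable, path: str | Path) -> None:
    """Write prioritised candidates as a TSV with a stable column and row order.

    Positions are written 1-based. Rows are sorted by (chrom, pos, alt).
    Empty optional fields are written as ``.``.
    """
    rows = []
    for c in candidates:
        gw = c.gwas
        v = gw.variant
        gl = c.gainloss
        rows.append({
            "rsid": v.rsid,
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "region_class": c.region_label,
            "p": repr(gw.p_value),
            "OR": repr(gw.odds_ratio),
            "criteria": ",".join(sorted(c.criteria)),
            "ld_anchor": c.ld_anchor[0] if c.ld_anchor else ".",
            "ld_anchor_r2": repr(c.ld_anchor[1]) if c.ld_anchor else ".",
            "gained_families": ",".join(sorted(gl.gained_families)) if gl else ".",
            "lost_families": ",".join(sorted(gl.lost_families)) if gl else ".",
            "net_change": gl.net_change if gl else ".",
            "stability_delta": repr(c.stability) if c.stability is not None else ".",
            "evidence_count": c.evidence_count,
        })
    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["alt"]))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_candidate_report(path: str | Path) -> pd.DataFrame:
    """Read a candidate report back as a DataFrame (strings preserved)."""
    return pd.read_csv(path, sep="\t", dtype=str)
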