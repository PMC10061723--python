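"""End-to-end orchestration: collate -> restrict -> criteria -> annotate ->
gain/loss -> stability -> evidence -> report.

Collated SNPs fall into three exclusive classes, each Bonferroni-corrected
(where applicable) against its own per-run tested count:

* ``mir``   — inside a hairpin body (seed/mature/loop/precursor ends),
* ``utr``   — inside a predicted canonical binding site on a 3'UTR,
* ``flank`` — within the hairpin flanking windows and in neither class
  above (a binding-site SNP that also lies in a flank is analysed through
  the UTR branch).

The KNOWN / LD / BONFERRONI criteria are computed independently; the
INDEPENDENT branch (greedy clumping united with a consortium-supplied
list) applies to the UTR class. Every stage writes an intermediate TSV to
the output directory and reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from mirvar import io
from mirvar.alleles import GainLossResult, utr_gain_loss
from mirvar.evidence import EvidenceTables, evaluate_criteria, read_evidence_tables
from mirvar.fold import stability_delta
from mirvar.io import GenomicInterval, GwasRecord, LdTable, Variant
from mirvar.prioritize import (
    CandidateRecord,
    PrioritizationConfig,
    clump_independent,
    combine_candidates,
    criterion_bonferroni,
    criterion_known,
    criterion_ld,
    restrict_to_tested,
    union_independent,
)
from mirvar.regions import FlankConfig, annotate_snp_region, extend_flanks, \
    intersect_variants
from mirvar.sites import scan_sites

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths, thresholds and switches for one pipeline run."""

    mirna_gff3: str
    variants_vcf: str
    gwas_tsv: str
    susceptibility_tsv: str
    outdir: str
    ld_tsv: str | None = None
    independent_tsv: str | None = None
    hairpins_fasta: str | None = None
    matures_fasta: str | None = None
    utrs_fasta: str | None = None
    utr_regions_tsv: str | None = None
    eqtl_tsv: str | None = None
    expression_tsv: str | None = None
    flank: FlankConfig = field(default_factory=FlankConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    include_six_mer: bool = False
    tissue_whitelist: tuple[str, ...] = ("PBMC", "monocytes", "T-cells",
                                         "lymphocytes")
    require_same_tissue: bool = True
    engine: str = "builtin"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "flank_bp" in raw:
            raw["flank"] = FlankConfig(raw.pop("flank_bp"))
        prio_keys = {
            k: raw.pop(k)
            for k in ("alpha", "r2_strong_ld", "r2_clump", "clump_window_bp",
                      "genome_wide_p")
            if k in raw
        }
        if prio_keys:
            raw["prioritization"] = PrioritizationConfig(**prio_keys)
        if "tissue_whitelist" in raw:
            raw["tissue_whitelist"] = tuple(raw["tissue_whitelist"])
        return cls(**raw)

    @classmethod
    def from_cohort(cls, files: dict[str, str], outdir: str | Path,
                    **overrides) -> "PipelineConfig":
        """Wire up a configuration from a synthetic cohort's file mapping."""
        cfg = cls(
            mirna_gff3=files["mirna_gff3"],
            variants_vcf=files["variants_vcf"],
            gwas_tsv=files["gwas_tsv"],
            susceptibility_tsv=files["susceptibility_tsv"],
            ld_tsv=files.get("ld_tsv"),
            independent_tsv=files.get("independent_tsv"),
            hairpins_fasta=files.get("hairpins_fasta"),
            matures_fasta=files.get("matures_fasta"),
            utrs_fasta=files.get("utrs_fasta"),
            utr_regions_tsv=files.get("utr_regions_tsv"),
            eqtl_tsv=files.get("eqtl_tsv"),
            expression_tsv=files.get("expression_tsv"),
            outdir=str(outdir),
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PipelineResult:
    candidates: list[CandidateRecord]
    counts: dict[str, int | float]
    report_path: str


def _read_rsid_column(path: str) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(df["rsid"])


def _utr_offset(pos0: int, start: int, end: int, strand: str) -> int:
    """1-based transcript-sense offset of a genomic position in a UTR."""
    return pos0 - start + 1 if strand == "+" else end - pos0


def _write_variant_class(path: Path, variants: list[Variant]) -> None:
    rows = sorted(
        (v.chrom, v.pos + 1, v.rsid, v.ref_allele, v.alt_allele) for v in variants
    )
    with open(path, "w") as fh:
        fh.write("chrom\tpos\trsid\tref\talt\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the candidate report.

    Raises on any stage error; a missing LD table only disables the LD
    criterion (with a warning) and leaves the other branches untouched.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float] = {}

    # -- collation ----------------------------------------------------------
    annotations = io.read_mirbase_gff3(cfg.mirna_gff3)
    variants = io.read_variant_table(cfg.variants_vcf, dialect="vcf")
    gwas = io.read_summary_stats(cfg.gwas_tsv)

    hairpin_of: dict[GenomicInterval, str] = {}
    hairpin_ivs: list[GenomicInterval] = []
    flank_ivs: list[GenomicInterval] = []
    flank_of: dict[GenomicInterval, str] = {}
    by_name = {a.name: a for a in annotations}
    for a in sorted(annotations, key=lambda a: a.name):
        hairpin_ivs.append(a.hairpin)
        hairpin_of[a.hairpin] = a.name
        for iv in extend_flanks(a, cfg.flank):
            if iv is not None:
                flank_ivs.append(iv)
                flank_of[iv] = a.name

    mir_pairs = intersect_variants(hairpin_ivs, variants)
    mir_variants = sorted({v for v, _ in mir_pairs})
    mirna_of_variant = {v.rsid: hairpin_of[iv] for v, iv in mir_pairs}

    # 3'UTR binding-site SNPs: sites are predicted on the reference UTRs
    utr_seqs: dict[str, str] = {}
    utr_meta: dict[str, dict] = {}
    utr_variants: list[Variant] = []
    utr_of_variant: dict[str, str] = {}
    panel: dict[str, str] = {}
    if cfg.utrs_fasta and cfg.utr_regions_tsv and cfg.matures_fasta:
        utr_seqs = io.read_fasta(cfg.utrs_fasta)
        panel = io.read_fasta(cfg.matures_fasta)
        meta = pd.read_csv(cfg.utr_regions_tsv, sep="\t", dtype={
            "utr_name": str, "chrom": str, "start": int, "end": int,
            "strand": str, "target_gene": str,
        })
        site_ivs: list[GenomicInterval] = []
        site_of: dict[GenomicInterval, str] = {}
        for row in meta.itertuples(index=False):
            utr_meta[row.utr_name] = row._asdict()
            seq = utr_seqs[row.utr_name]
            for mirna in sorted(panel):
                for site in scan_sites(seq, panel[mirna],
                                       include_six_mer=cfg.include_six_mer):
                    if row.strand == "+":
                        g0 = row.start + site.utr_start - 1
                        g1 = row.start + site.utr_end
                    else:
                        g0 = row.end - site.utr_end
                        g1 = row.end - site.utr_start + 1
                    iv = GenomicInterval(row.chrom, g0, g1, row.strand)
                    if iv not in site_of:
                        site_ivs.append(iv)
                        site_of[iv] = row.utr_name
        mir_rsids = {v.rsid for v in mir_variants}
        seen: set[str] = set()
        for v, iv in intersect_variants(site_ivs, variants):
            if v.rsid in mir_rsids or v.rsid in seen:
                continue
            seen.add(v.rsid)
            utr_variants.append(v)
            utr_of_variant[v.rsid] = site_of[iv]

    claimed = {v.rsid for v in mir_variants} | {v.rsid for v in utr_variants}
    flank_pairs = intersect_variants(flank_ivs, variants)
    flank_variants = sorted({v for v, _ in flank_pairs if v.rsid not in claimed})
    flank_mirna = {}
    for v, iv in flank_pairs:
        if v.rsid not in claimed and v.rsid not in flank_mirna:
            flank_mirna[v.rsid] = flank_of[iv]

    for name, var_list in (("mir", mir_variants), ("flank", flank_variants),
                           ("utr", utr_variants)):
        _write_variant_class(outdir / f"collated_{name}.tsv", list(var_list))
        counts[f"n_collated_{name}"] = len(var_list)

    # -- restriction to tested SNPs ----------------------------------------
    tested = {
        "mir": restrict_to_tested(mir_variants, gwas),
        "flank": restrict_to_tested(flank_variants, gwas),
        "utr": restrict_to_tested(utr_variants, gwas),
    }
    for cls, recs in tested.items():
        counts[f"n_tested_{cls}"] = len(recs)
        logger.info("%s class: %d tested SNPs", cls, len(recs))

    # -- three criteria + independent branch --------------------------------
    prio = cfg.prioritization
    susceptibility = _read_rsid_column(cfg.susceptibility_tsv)
    ld: LdTable | None = None
    if cfg.ld_tsv and Path(cfg.ld_tsv).exists():
        ld = io.read_ld_table(cfg.ld_tsv)
    else:
        logger.warning("no LD table: the LD criterion is skipped")

    known: list[GwasRecord] = []
    ld_flagged: list[tuple[GwasRecord, str, float]] = []
    bonferroni: list[GwasRecord] = []
    for cls in ("mir", "flank", "utr"):
        known.extend(criterion_known(tested[cls], susceptibility))
        if ld is not None:
            ld_flagged.extend(
                criterion_ld(tested[cls], susceptibility, ld, prio.r2_strong_ld)
            )
    for cls in ("mir", "flank"):
        if tested[cls]:
            threshold = prio.alpha / len(tested[cls])
            counts[f"bonferroni_threshold_{cls}"] = threshold
            bonferroni.extend(criterion_bonferroni(tested[cls], prio.alpha))

    independent: list[GwasRecord] = []
    if tested["utr"]:
        leads = clump_independent(tested["utr"], ld or LdTable(), prio)
        consortium = (
            _read_rsid_column(cfg.independent_tsv)
            if cfg.independent_tsv and Path(cfg.independent_tsv).exists()
            else set()
        )
        union, overlap = union_independent(leads, consortium)
        counts["n_clump_leads"] = len(leads)
        counts["n_independent_union"] = len(union)
        counts["n_independent_overlap"] = overlap
        independent = [g for g in tested["utr"] if g.rsid in union]
        with open(outdir / "independent_snps.tsv", "w") as fh:
            fh.write("rsid\tsource\n")
            for rsid in sorted(union):
                src = ("both" if rsid in consortium and rsid in set(leads)
                       else "consortium" if rsid in consortium else "clump")
                fh.write(f"{rsid}\t{src}\n")

    # -- region annotation ---------------------------------------------------
    regions = {}
    with open(outdir / "region_annotation.tsv", "w") as fh:
        fh.write("rsid\tmirna\tregion_class\n")
        rows = []
        for v in list(mir_variants) + list(flank_variants):
            name = mirna_of_variant.get(v.rsid, flank_mirna.get(v.rsid))
            region = annotate_snp_region(v, by_name[name], cfg.flank)
            regions[v.rsid] = region
            rows.append((v.rsid, name, region.label))
        for r in sorted(rows):
            fh.write("\t".join(r) + "\n")
    for rsid, utr in utr_of_variant.items():
        regions[rsid] = f"3UTR_site:{utr_meta[utr]['target_gene']}"

    # -- gain/loss on UTR candidates ----------------------------------------
    flagged_rsids = (
        {g.rsid for g in known}
        | {g.rsid for g, _, _ in ld_flagged}
        | {g.rsid for g in bonferroni}
        | {g.rsid for g in independent}
    )
    gainloss: dict[str, GainLossResult] = {}
    with open(outdir / "gainloss.tsv", "w") as fh:
        fh.write("rsid\tutr\tgained\tlost\tnet_change\n")
        for g in sorted(tested["utr"], key=lambda g: g.rsid):
            if g.rsid not in flagged_rsids or g.rsid not in utr_of_variant:
                continue
            utr = utr_of_variant[g.rsid]
            m = utr_meta[utr]
            v = g.variant
            result = utr_gain_loss(
                utr_seqs[utr], v,
                _utr_offset(v.pos, m["start"], m["end"], m["strand"]),
                m["strand"] == "-", panel,
                include_six_mer=cfg.include_six_mer,
                alt_is_risk=g.odds_ratio > 1.0,
            )
            gainloss[g.rsid] = result
            fh.write(
                f"{g.rsid}\t{utr}\t{','.join(sorted(result.gained_families)) or '.'}"
                f"\t{','.join(sorted(result.lost_families)) or '.'}"
                f"\t{result.net_change}\n"
            )

    # -- hairpin stability for miR-body candidates ---------------------------
    stability: dict[str, float] = {}
    if cfg.hairpins_fasta:
        hairpins = io.read_fasta(cfg.hairpins_fasta)
        with open(outdir / "stability.tsv", "w") as fh:
            fh.write("rsid\tmirna\tscore_ref\tscore_alt\tdelta\tengine\n")
            for v in sorted(mir_variants):
                if v.rsid not in flagged_rsids:
                    continue
                name = mirna_of_variant[v.rsid]
                h = by_name[name].hairpin
                t_pos = (v.pos - h.start if h.strand == "+" else h.end - 1 - v.pos) + 1
                delta = stability_delta(
                    hairpins[name], t_pos, v.ref_allele, v.alt_allele,
                    engine=cfg.engine, on_reverse_strand=h.strand == "-",
                )
                stability[v.rsid] = delta.delta
                fh.write(f"{v.rsid}\t{name}\t{delta.score_ref}\t{delta.score_alt}"
                         f"\t{delta.delta}\t{delta.engine}\n")

    # -- functional evidence --------------------------------------------------
    tables = EvidenceTables(tissue_whitelist=frozenset(cfg.tissue_whitelist))
    if cfg.eqtl_tsv and cfg.expression_tsv:
        tables = read_evidence_tables(cfg.eqtl_tsv, cfg.expression_tsv,
                                      cfg.tissue_whitelist)
    evidence_counts: dict[str, int] = {}
    with open(outdir / "evidence.tsv", "w") as fh:
        fh.write("rsid\tinteraction_change\teqtl_in_tissue\t"
                 "mirna_expressed_same_tissue\tcount\tprioritized\n")
        for rsid in sorted(gainloss):
            target = utr_meta[utr_of_variant[rsid]]["target_gene"]
            flags = evaluate_criteria(
                rsid, target, gainloss[rsid], tables,
                require_same_tissue=cfg.require_same_tissue,
            )
            evidence_counts[rsid] = flags.count
            fh.write(f"{rsid}\t{int(flags.interaction_change)}"
                     f"\t{int(flags.eqtl_in_tissue)}"
                     f"\t{int(flags.mirna_expressed_same_tissue)}"
                     f"\t{flags.count}\t{int(flags.prioritized)}\n")

    # -- assembly -------------------------------------------------------------
    candidates = combine_candidates(
        known=known, ld_flagged=ld_flagged, bonferroni=bonferroni,
        independent=independent, regions=regions, gainloss=gainloss,
        stability=stability, evidence_counts=evidence_counts,
    )
    counts["n_candidates"] = len(candidates)
    report_path = outdir / "candidates.tsv"
    io.write_candidate_report(candidates, report_path)
    with open(outdir / "counts.yaml", "w") as fh:
        yaml.safe_dump(counts, fh, sort_keys=True)
    logger.info("pipeline finished: %d candidates", len(candidates))
    return PipelineResult(candidates, counts, str(report_path))
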