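# Methods

## Coordinate and sequence conventions

All genomic coordinates are 0-based half-open internally; GFF3 (1-based
closed) and VCF (1-based) are converted at the read boundary and written
back in their native conventions. Reports print 1-based positions.
Sequences are held in the RNA alphabet (T→U on read), always in transcript
sense; alleles are stored genomic-forward, so on a reverse-strand
transcript their complements are matched and substituted. One genome build
per run is assumed — liftover is outside the package's scope.

Variants and summary statistics are joined on (chromosome, position,
unordered allele set); rsid disagreements under that key are logged, and an
rsid-only join is available as a fallback for inputs without reliable
positions. Only biallelic SNVs flow through the pipeline: multi-allelic
rows are split into one record per alternative allele, and indels/MNVs are
skipped with a logged count. The typographic minus sign ("−") is accepted
in numeric fields because public summary-statistics exports sometimes
contain it.

## Region model

A hairpin is partitioned with precedence seed > mature > loop > precursor
ends; flanks surround it. The seed is mature positions 2–8, 1-based from
the mature 5′ end and strand-aware (on the minus strand the 5′ end is the
higher genomic coordinate). The span is configurable (`seed_span`) because
annotation traditions differ between 2–7 and 2–8; 2–8 is the default so the
region model and the site types refer to the same positions. The loop is
the hairpin region strictly between two annotated arms. Hairpins with a
single annotated arm get no inferred loop — the unannotated side is
precursor end — because inventing an arm would fabricate loop boundaries;
hairpins with no annotated arm are split into precursor ends by
transcriptional half.

Flank windows default to 5000 bp, clamped to the chromosome, and abut the
hairpin without including it. `extend_flanks` reports them in genomic
orientation (lower/higher coordinates) with the strand attached;
`annotate_snp_region` labels flank SNPs transcriptionally
(`Flank_Upstream` = 5′ of the hairpin) so that the per-base classification
is invariant under mirroring coordinates and flipping strand — a property
the test suite asserts base by base.

## Site model

Canonical sites only, strict Watson–Crick, no G:U wobble in seed matching,
no context scoring or conservation: presence/absence of a predicted
interaction is the unit of comparison throughout, which is also why
gain/loss is reported at seed-family granularity (identical positions 2–8
⇒ identical site sets). Member miRNA names are carried with each family so
both family-level and miRNA-level net changes are available; the two can
differ when families have multiple members, so both are emitted. The 6mer
type is recognised but disabled by default (`include_six_mer`): 6mers are
weak and inflate gain/loss counts, so enabling them is an explicit choice.
The scanner classifies each seed-core locus by its flanking bases (m8
pairing, literal A opposite position 1), which yields longest-match
precedence exactly; an independent sliding-window oracle confirms this on
randomised inputs.

Externally predicted sites (pattern-discovery tools that report a
prediction p per site) are reduced per (miRNA, target) pair to the single
most significant record, kept only if p < 0.0314 (strict), with ties broken
by site position.

## Allele-swap gain/loss

For a UTR SNP, both alleles of the UTR are scanned against the whole miRNA
panel; families binding only the alternative are "gained", only the
reference "lost", and `net_change = n_alt − n_ref` counts binding families.
Swapping ref/alt mirrors the result exactly (tested over 100 random
scenarios). Only the ±8-nt window around the SNP can change, but results
are always computed by full-sequence rescans — the window argument is an
optimisation opportunity, not a semantic, and the equality is asserted in
tests. The result records whether the alternative allele is the GWAS risk
allele (OR > 1) so the sign of `net_change` can be read as
regulation-of-risk-allele without ambiguity. The symmetric analysis
(`seed_gain_loss`) swaps an allele into the miRNA and reports each panel
UTR's binding state under both miRNA versions.

## Hairpin stability

The built-in folder maximises base-pair count over non-crossing structures
with a minimum hairpin loop of 3 unpaired bases, via the classic quadratic-
table recursion; allowed pairs are A:U, G:C and G:U (N never pairs), and
each pair scores −1, so more negative = more paired = "more stable". This
is deliberately not a nearest-neighbour free-energy model: it is exact,
dependency-free, and verifiable by exhaustive enumeration, which the tests
do for random short sequences. Published free-energy deltas (kcal/mol from
thermodynamic engines) are not comparable to these scores; an external
engine can be plugged in as a callable `seq -> FoldResult`, and the engine
name is recorded in every result and report so scores from different
models are never mixed silently. Wobble pairing can be disabled
(`allow_wobble=False`), under which the score is exactly invariant to
reverse-complementing the sequence (with wobble it is not, since G:U maps
to the non-pairing A:C). Traceback ties prefer pairing the interval ends,
then leaving an end unpaired, then the smallest bifurcation split, making
dot-bracket output reproducible. `stability_delta` reports
`score_alt − score_ref` (negative = alternative allele stabilises) plus
both structures and the 1-based positions whose pairing status changed.
Input length is capped at 2000 nt, the window within which variant effects
on structure are predicted.

## Prioritisation

Defaults: α = 0.05; strong LD r² ≥ 0.8 (a community convention for
"strong"; the threshold is configurable and any published example pair at
r² ≈ 0.97 comfortably clears it); clumping r² ≥ 0.6 within 250-kb windows
(standard clumping defaults for independent significant SNPs); genome-wide
p = 5·10⁻⁸. All threshold comparisons are strict (<, or ≥ for r²). The
Bonferroni divisor is always the per-run count of tested SNPs in the
relevant class — hairpin body and flank classes are corrected separately,
the UTR class goes through the independence branch instead. Absent LD data
for a pair is "no data", never r² = 0, and never satisfies a threshold. The
three criteria are computed independently, so disabling one (e.g. no LD
table) cannot change another's membership. Clumping is greedy on ascending
p (ties by position), each lead claiming LD partners and positional
neighbours; the emitted independent set is the union of clump leads with
the consortium list, with the overlap size reported.

## Functional evidence

Three adapted miRNA–target validation criteria: (1) the SNP changes
predicted interactions (non-empty gain/loss); (2) it is an eQTL for the
target in a whitelisted disease-relevant tissue; (3) a gained or lost
family member is expressed (TPM ≥ 0.5) in a tissue that carries that eQTL
signal. The same-tissue reading of (3) is the default, with
`require_same_tissue=False` relaxing it to any whitelisted tissue, because
public annotations often name tissues inconsistently. TPM bands are
left-closed on the anchors 0.5/10/1000 (NOT_EXPRESSED/LOW/MEDIUM/HIGH);
"expressed" means ≥ LOW. eQTL direction is recorded but not gated on:
public MS and non-MS eQTL datasets disagree in direction for some targets,
so direction is information for the reader, not a filter. A candidate
meeting all three criteria is flagged prioritised; protein-level gain/loss
experiments are inherently out of reach of a summary-statistics pipeline
and are never required.

## Synthetic cohorts

The generator builds a toy genome (2 chromosomes of 2 Mb by default) with
8 hairpins of 100 nt on alternating strands, each with 22-nt 5p/3p arms
(transcript offsets 10–31 and 60–81), so every region class exists on both
strands. It plants: one tested SNP per region class; per criterion
(default 2 each) KNOWN flank SNPs listed in the susceptibility table, LD
hairpin SNPs anchored at r² ∈ [0.85, 0.99] to susceptibility rsids,
BONFERRONI hairpin and flank SNPs with p ∈ [10⁻¹², 10⁻⁹]; ~80 background
flank SNPs (80 % tested) carrying three LD blocks with r² ∈ [0.8, 0.99];
and 6 UTRs of 300 nt, each with a planted 8mer site whose core SNP
destroys it — on alternating UTRs the alternative allele simultaneously
creates a site of another family, which forces the two patterns to agree
over their overlap, so families, site types and alignments are searched
constructively. One UTR carries a second site SNP that is claimed by its
clump and re-enters through the consortium list, exercising the union.
Evidence tables give the first planted UTR candidates all three criteria
(eQTL + expression in "monocytes"), one an out-of-whitelist ("skin") eQTL,
the rest nothing. Every planted construct is verified at generation time
by running the package's own scanner on the generated sequences, and the
manifest records the verified truth; generation fails loudly rather than
emit an inconsistent manifest.

Each table draws from its own pseudo-random stream derived from the master
seed, so adding a table never perturbs earlier ones; identical seeds give
byte-identical files. Null p-values are uniform(0, 1]; in planted-truth
mode (default) they are conditioned to lie at or above their class's
Bonferroni threshold so the manifest's candidate set is exact by
construction — the unconditioned null (`exclude_null_significants=False`)
is the right setting for calibration experiments, and the false-positive
calibration in the acceptance script draws unconditioned uniform nulls
directly. Problem sizes (8 miRNAs, ~100 SNPs, 6 UTRs, 20-seed replication;
300 tests × 200 replicates for the null calibration) were chosen as the
smallest sizes at which every region class, criterion and branch is
exercised and binomial expectations are testable.

What the cohorts do **not** emulate: realistic LD decay or allele-frequency
spectra, MHC-scale long-range LD, overlapping genes/UTRs, multi-member
miRNA families (every synthetic family has one member), measurement error
in OR, or genomic sequence outside hairpins and UTRs. Passing recovery
tests therefore demonstrates correctness of the collation/criteria/effect
machinery under the stated statistical structure, not performance on real
cohorts — on real data the thresholds, LD reference and annotation
completeness dominate.

## Numerical and degenerate-input choices

Exact float parsing from scientific notation; p ∈ (0, 1] closed above, open
below. Empty flank windows are `None` sentinels rather than zero-length
intervals. Deterministic orderings everywhere (reports by chromosome,
position, allele; clump leads in selection order; ties documented) make
pipeline reruns byte-identical, which is asserted in the tests. Hairpins
shorter than min_loop + 2 fold to the empty structure; empty UTRs scan to
empty site lists; an empty miRNA panel is an error rather than a silent
empty result.

## Known limitations

No wobble or 3′-supplementary pairing in site prediction; no context++/
conservation scoring; the built-in folder's scores are pair counts, not
free energies; clumping uses summary statistics only (no conditional
regression); flank SNPs are attributed to their nearest hairpin only;
evidence matching is by exact gene/miRNA name. The CLI stage commands
cover the common paths of each stage; the full orchestration (class
exclusivity, per-class thresholds, report assembly) lives in `run-all`.
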