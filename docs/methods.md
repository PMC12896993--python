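# Methods

## Study design emulated by the simulator

The synthetic generator reproduces, at the called-variant level, a
two-genotype replication-stress experiment: an ERCC6/TC-NER-proficient line
(`WT`) and an ERCC6-null line (`K337X`), each sampled at time zero (`T0`),
after 4 h of hydroxyurea (`HU4h`) with matched control (`Ctrl4h`), and after
72 h of recovery from the 4 h exposure (`Rec72h`) with matched late control
(`Ctrl72h`). Simulation starts at the variant-call level: there is no read
simulation, no sequencing-error model, and no caller emulation.

### Gene model

`n_genes` non-overlapping genes are placed on `n_chromosomes` chromosomes of
`chrom_length` bp (defaults: 500 genes, 2 × 10 Mb, mean gene length 8 kb, so
~80% of the genome stays intergenic). Inter-gene gaps follow a symmetric
Dirichlet–multinomial split of the free space. Each coding gene is tiled
UTR5 / (exon, intron)×k / UTR3 (k = `exons_per_gene`, UTRs a fixed fraction
`utr_fraction` of the span, strand-aware order); a fraction `ncrna_fraction`
(default 0.1) is non-coding with exon/intron structure only. A configuration
whose expected genic span exceeds half the genome is rejected up front.

### Expression

FPKM is log-normal — the standard heavy-tailed model for expression, which
also populates all quartiles. The log-variance (default sd 0.9) is split
into a stable per-gene level plus condition-specific noise of sd
`fpkm_condition_sd` (default 0.25), so a gene's expression correlates across
conditions (log-scale r ≈ 0.92 at the defaults) while every condition still
gets its own table. This matters: the recovery analysis references the
acute-stress transcriptome, which is only informative because real FPKMs are
strongly correlated across states. The marginal distribution keeps
sd = `fpkm_log_sd` exactly, so the zero-variance limit and
distribution-calibration checks hold regardless of the split.

### Variants

Per sample, the variant count is Poisson(`baseline_rate`), resolved per
genotype × condition (defaults: 500 for controls/T0, 1000 at `HU4h`, 800 at
`Rec72h` — HU roughly doubles the burden and recovery partially resolves
it). Each mutation is genic with probability `tier1_fraction`
(defaults: 0.5 basally; 0.8 vs 0.3 at `HU4h` for WT vs K337X — the
genotype-dependent redistribution; 0.9 at `Rec72h`, where surviving
populations retain gene-proximal mutations). Genic placement weights gene g
by (FPKM_g + 1)^β, so β = 0 recovers uniform genic placement; β defaults to
0 except K337X under and after stress (β = 2). Recovery-sample placement is
weighted by the `HU4h` expression state, where the retained mutations were
established. Intergenic placement is uniform over the gene-free space; note
that intergenic draws landing within 1 kb of a gene annotate as
upstream/downstream (tier 1), so the *annotated* tier-1 fraction slightly
exceeds `tier1_fraction` (~5% of intergenic space is flank at the defaults).

Latent VAFs come from per-genotype Beta mixtures:
WT 0.45·Beta(50,50) + 0.35·Beta(45,5) + 0.20·Beta(5,45) (clonal ~0.5 peak
plus high- and low-frequency shoulders), K337X 0.8·Beta(3,3) + 0.2·Beta(30,30)
(broad 0.2–0.8, sub-clonal diversification). Observed support is
depth ~ Poisson(`mean_depth` = 80) floored at `min_depth` = 10 — the floor
keeps the ≥5-read filter exercised but not dominant — and
alt_reads ~ Binomial(depth, VAF); the recorded VAF is alt/depth, so file
round trips are exact. Indels (fraction 0.15) are 1–5 bp insertions or
deletions with uniform length; no empirical indel length spectrum is
modelled. Rates were fixed from the design constraints above — in
particular, the recovery settings put roughly 50–60 Q4 genes past the
Δ ≥ 3 gain filter, the intended operating point of the recovery coupling
analysis — and were not revisited per analysis.

Every random draw derives from `SimConfig.seed` plus a purpose token
(CRC-32 of strings like `("variants", genotype, condition)`), giving
independent, reproducible streams; identical configs yield byte-identical
output files. The absolute per-sample burden (~500) is a desk-scale choice,
not an empirical value.

## Analysis conventions

- **Read-support filter.** "Supported by a minimum of five reads" is applied
  to alt-allele supporting reads (inclusive boundary), the common somatic
  reading; a `on="depth"` switch applies it to total depth instead.
  Multi-allelic records are split per ALT and treated independently; no
  indel left-alignment is attempted (normalization is upstream of this
  package).
- **Annotation.** One category per variant by the precedence
  exonic > splicing > UTR5 > UTR3 > intronic > ncRNA > upstream >
  downstream > intergenic; flank 1000 bp and splice window 2 intronic bases
  (the conventional refGene-annotator defaults); ties across overlapping
  genes break on precedence then lexicographic gene id. Indels are scanned
  over every affected reference base and take the highest-precedence hit.
  Unknown chromosomes classify as intergenic with a logged warning
  (configurable to a hard error).
- **Tiers.** Tier 1 = every gene-associated category, tier 2 = intergenic.
  A stricter variant (tier 1 = transcribed sequence only: exonic, UTRs,
  ncRNA) is available via `tier1_strict` since the two readings of
  "gene-proximal" differ; the broader one is the default.
- **VAF bins.** <0.1; 0.1–0.4; 0.4–0.6; 0.6–0.85; >0.85, left-closed /
  right-open with the last bin closed at 1, so a shared endpoint (0.4)
  belongs to the upper bin; centralized in `burden.vaf_bin`.
- **Burden deltas.** Counted per variant locus. Negative deltas are retained
  (recovery reduces burden); only the recovery-by-category view clips at
  zero and restricts to {downstream, exonic, UTR3, UTR5}. SNVs and indels
  are always tabulated separately; callers may sum.
- **KS test.** Two-sided; exact null distribution when min(n) ≤ 25, else
  asymptotic (scipy). Ties follow the standard ECDF convention — VAFs are
  ratios of small integers, so ties are expected and harmless for D.
- **Spearman coupling.** ρ on mid-ranks of (log10(FPKM+1),
  log10(count+1)) — the transform never changes ρ (rank statistic) and is
  kept for effect-size comparability with scatter-plot conventions.
  Quartiles use linear-interpolation percentiles over the full gene
  universe; boundary ties fall to the lower quartile (fully tied input
  collapses into Q1). The Δ ≥ 3 gain gate applies to per-gene
  treated − matched-control deltas; the correlated count is the treated
  count (axis convention), with `correlate="delta"` as an alternative.
  p-values: full enumeration of rank pairings for n ≤ 9 (9! permutations,
  vectorized; beyond that enumeration grows factorially with little
  accuracy gain), t-approximation otherwise. Fewer than 3 genes after
  filtering is an error naming the filter that emptied the set.
- **Recovery coupling.** Gains are `Rec72h` − `Ctrl72h`; FPKM values *and*
  quartile membership come from the `HU4h` expression state.
- **Expressed-variant proxy.** Tier-1 variants whose host gene has
  FPKM ≥ 1 — a deliberate gene-overlap simplification standing in for
  RNA-level variant calling, which is out of scope.

## What the simulator does and does not establish

Passing tests show the pipeline recovers planted structure (tier bias signs,
VAF-mixture contrasts, β > 0 coupling) and is calibrated under the null
(type-I error of the KS and Spearman paths ≈ 5%). They do not validate
caller artefacts, mapping bias, contamination, ploidy, mutational signatures,
or real refGene complexity (isoforms, overlapping transcripts) — none of
which the generator models. Absolute burden numbers are configuration, not
predictions.

## Test and acceptance problem sizes

Unit tests run on a 50-gene, 2 × 300 kb toy genome; calibration suites use
the full default geometry with 100–500 replicates (KS null 500 × n = 300;
coupling type-I 200 replicates; recovery power and the β ∈ {0, 0.5, 1, 2}
monotonicity grid 100 seeds each; tier-bias recovery 100 seeds). The whole
suite completes in about a minute on one CPU.

## Known limitations

- Gene placement is uniform; no clustering, gene deserts, or chromosome-arm
  structure.
- The coupling functional form (FPKM + 1)^β is a modelling convenience; only
  the existence and direction of coupling, not its shape, is asserted
  anywhere.
- Condition-to-condition expression changes are undirected noise; there is
  no differential-expression program, and DE analysis is out of scope.
- `VariantSet` keys variants by (chrom, pos, ref, alt) within a sample;
  cross-sample germline/somatic subtraction beyond treated − control deltas
  is not implemented.
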