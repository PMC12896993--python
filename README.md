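# rsmutscape

Analysis toolkit for the mutational landscape of replication-stress-induced
variants in paired treated/control samples, with a synthetic-data simulator
that makes every stage verifiable end to end.

## The problem

Hydroxyurea (HU) stalls replication forks and provokes
transcription–replication conflicts. How the resulting damage is converted
into mutations — and *where* those mutations land in the genome — depends on
transcription-coupled repair (TC-NER): cells proficient for the TC-NER factor
ERCC6 (CSB) retain stress-induced mutations preferentially in gene-associated
("tier 1") regions of transcriptionally active loci, while ERCC6-deficient
(K337X) cells accumulate variants in intergenic ("tier 2") space and show
broader, sub-clonal variant-allele-frequency (VAF) spectra. This package
implements the downstream analysis of that design for called variants
(VCF level), plus a generator of synthetic studies with the same statistical
structure:

- **Ingestion** — VCF 4.x reading (pysam), multi-allelic splitting,
  VAF = AD/DP, and the ≥5-supporting-read filter.
- **Annotation** — refGene-style categories (exonic, splicing, UTR5, UTR3,
  intronic, ncRNA, upstream, downstream, intergenic) by precedence against a
  gene model, and the tier 1 / tier 2 grouping.
- **Burden** — Δ mutation counts (treated − control) stratified by tier or
  category, variant type, and the VAF bins <0.1; 0.1–0.4; 0.4–0.6; 0.6–0.85;
  >0.85, with a positive-Δ recovery view over {Downstream, Exonic, UTR3, UTR5}.
- **VAF statistics** — two-sample Kolmogorov–Smirnov comparison
  (D = sup|ECDF₁ − ECDF₂|, exact null for small n) and VAF histograms.
- **Coupling** — per-gene mutation counts, FPKM quartiles, the Δ ≥ 3
  stress-induced-gain filter, and Spearman ρ between log₁₀(FPKM + 1) and
  log₁₀(mutation count + 1) on top-quartile (Q4) genes, including the
  recovery analysis where gains are referenced to the late control while
  expression is taken from the acute-stress state.

## Worked example

```python
import rsmutscape as rs

cfg = rs.SimConfig(seed=1)                      # two genotypes x five conditions
genes, expression, sets = rs.simulate_study(cfg)

# ingest + annotate the K337X recovery pair
rec  = rs.annotate_set(rs.filter_min_support(sets[rs.SampleLabel("K337X", "Rec72h")]), genes)
ctl  = rs.annotate_set(rs.filter_min_support(sets[rs.SampleLabel("K337X", "Ctrl72h")]), genes)

res = rs.recovery_coupling(rec, ctl, expression["K337X"], genes)
print(res.n_genes, round(res.rho, 3), res.p_value)
```

prints

```
59 0.818 2.525000515632213e-15
```

i.e. 59 top-quartile genes gained ≥3 mutations over the matched 72 h control,
and their mutation counts correlate strongly with the acute-stress expression
level (ρ = 0.82) — the signature of transcription-coupled mutagenesis that the
ERCC6-deficient genotype is simulated with. The same analysis on WT samples
(expression-independent placement) yields a weak, non-significant ρ, and both
genotypes are null under basal conditions.

A thin CLI wraps the same functions:

```bash
rsmutscape simulate --seed 1 --out study/
rsmutscape ingest --vcf study/WT_HU4h.vcf --genotype WT --condition HU4h \
    --genes study/genes.gff --min-alt-reads 5 --out wt_hu4h.tsv
rsmutscape vafcompare --a study/WT_HU4h.vcf --b study/K337X_HU4h.vcf --type SNV
```

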