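"""Synthetic gene models, expression tables, and called-variant sets.

The generator works at the *called variant* level (no reads, no sequencing
error model) and encodes the study design it emulates: two genotypes of a
TC-NER model system (ERCC6-proficient ``WT`` and ERCC6-null ``K337X``) across
five conditions (``T0``, ``Ctrl4h``, ``HU4h``, ``Ctrl72h``, ``Rec72h``).
Hydroxyurea (HU) adds excess mutations whose genomic placement is genotype
dependent: the WT excess is gene-proximal while the K337X excess is
intergenic, and in K337X cells genic placement is additionally weighted by
transcriptional activity, ``w_g ∝ (FPKM_g + 1)^β``.

Every random draw comes from a stream derived from ``SimConfig.seed`` plus a
purpose token, so a fixed config reproduces identical objects and
byte-identical files.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, RsMutError
from .model import (
    CONDITIONS,
    GENOTYPES,
    GeneFeature,
    GeneModel,
    SampleLabel,
    VariantRecord,
    VariantSet,
    genes_by_chrom,
)
from .simconfig import SimConfig

_BASES = np.array(list("ACGT"))
_MAX_INDEL = 5  # simulated indels are 1-5 bp


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def generate_gene_model(config: SimConfig) -> list[GeneModel]:
    """Place non-overlapping genes with UTR5/exon/intron/UTR3 substructure.

    Genes are distributed round-robin over chromosomes; per chromosome, gaps
    between genes are drawn from a symmetric Dirichlet-multinomial over the
    free (non-genic) space, so intergenic spacing is random but the layout is
    deterministic for a fixed seed.
    """
    if config.n_genes == 0:
        return []
    genome = config.n_chromosomes * config.chrom_length
    if config.n_genes * config.gene_length_mean > 0.5 * genome:
        raise ConfigError(
            "infeasible gene layout: n_genes * gene_length_mean exceeds 50% of the "
            f"genome ({config.n_genes} * {config.gene_length_mean} > 0.5 * {genome}); "
            "at least half of each chromosome must remain intergenic"
        )
    rng = config.rng("genes")
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1

    min_len = max(200, 10 * (2 * config.exons_per_gene - 1) + 2)
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(config.n_chromosomes):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        lens = np.clip(
            np.rint(rng.normal(config.gene_length_mean, 0.2 * config.gene_length_mean, k)),
            min_len,
            None,
        ).astype(int)
        free = config.chrom_length - int(lens.sum())
        if free < k + 1:
            raise ConfigError(
                f"infeasible gene layout on {chrom}: {k} genes of total length "
                f"{int(lens.sum())} cannot be placed without overlap in {config.chrom_length} bp"
            )
        gaps = rng.multinomial(free - (k + 1), rng.dirichlet(np.ones(k + 1))) + 1
        pos = 0
        for gi in range(k):
            start = pos + int(gaps[gi]) + 1  # 1-based
            end = start + int(lens[gi]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "ncRNA" if rng.random() < config.ncrna_fraction else "coding"
            genes.append(
                _build_gene(f"G{gid:04d}", chrom, start, end, strand, biotype, config, rng)
            )
            pos = end
            gid += 1
    return genes


def _build_gene(gene_id, chrom, start, end, strand, biotype, config: SimConfig, rng) -> GeneModel:
    length = end - start + 1
    k = config.exons_per_gene
    if biotype == "ncRNA" or config.utr_fraction == 0:
        utr5 = utr3 = 0
    else:
        utr5 = max(1, round(length * config.utr_fraction / 2))
        utr3 = max(1, round(length * config.utr_fraction / 2))
    body = length - utr5 - utr3
    blocks = 2 * k - 1  # exon, intron, ..., exon
    sizes = rng.multinomial(body - blocks, rng.dirichlet(np.ones(blocks))) + 1

    kinds: list[str] = []
    if utr5:
        kinds.append("UTR5" if strand == "+" else "UTR3")
    kinds += ["exon_cds" if i % 2 == 0 else "intron" for i in range(blocks)]
    if utr3:
        kinds.append("UTR3" if strand == "+" else "UTR5")
    widths = ([utr5] if utr5 else []) + list(map(int, sizes)) + ([utr3] if utr3 else [])
    # leading width is the genomically-first block regardless of strand
    if strand == "-" and utr5:
        widths = [utr3] + list(map(int, sizes)) + [utr5]

    feats = []
    p = start
    for kind, w in zip(kinds, widths):
        feats.append(GeneFeature(kind, p, p + w - 1))
        p += w
    return GeneModel(gene_id, chrom, start, end, strand, tuple(feats), biotype)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    genes: list[GeneModel],
    config: SimConfig,
    condition: str,
    genotype: str | None = None,
) -> pd.DataFrame:
    """One log-normal FPKM per gene for a condition (and optional genotype).

    Marginally FPKM ~ exp(N(fpkm_log_mean, fpkm_log_sd)); a zero sd collapses
    every gene onto exp(fpkm_log_mean).  The log-variance splits into a
    stable per-gene level plus condition-specific noise of sd
    ``fpkm_condition_sd``, so a gene's expression is correlated across
    conditions while distinct conditions still yield distinct tables.
    """
    if not genes:
        raise RsMutError("generate_expression requires a non-empty gene list")
    level_tokens = ["expr_levels"] + ([genotype] if genotype else [])
    noise_tokens = ["expr", condition] + ([genotype] if genotype else [])
    sd_cond = min(config.fpkm_condition_sd, config.fpkm_log_sd)
    sd_gene = float(np.sqrt(config.fpkm_log_sd**2 - sd_cond**2))
    level = config.rng(*level_tokens).normal(config.fpkm_log_mean, sd_gene, len(genes))
    noise = config.rng(*noise_tokens).normal(0.0, sd_cond, len(genes)) if sd_cond else 0.0
    fpkm = np.exp(level + noise)
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "condition": condition, "fpkm": fpkm}
    )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def sample_vafs(config: SimConfig, genotype: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw latent VAFs from the genotype's Beta mixture."""
    mix = config.resolve_mixture(genotype)
    w = np.array([c[0] for c in mix])
    comp = rng.choice(len(mix), size=n, p=w / w.sum())
    a = np.array([mix[i][1] for i in comp])
    b = np.array([mix[i][2] for i in comp])
    return rng.beta(a, b) if n else np.empty(0)


def mixture_cdf(config: SimConfig, genotype: str):
    """CDF of the genotype's Beta mixture (for calibration checks)."""
    from scipy.stats import beta as beta_dist

    mix = config.resolve_mixture(genotype)

    def cdf(x):
        return sum(w * beta_dist.cdf(x, a, b) for w, a, b in mix)

    return cdf


def simulate_variants(
    genes: list[GeneModel],
    expression: pd.DataFrame,
    config: SimConfig,
    genotype: str,
    condition: str,
    weight_condition: str | None = None,
) -> list[VariantRecord]:
    """Simulate one sample's called variants.

    Total count ~ Poisson(baseline_rate); each mutation falls inside a gene
    with probability ``tier1_fraction``, with genic placement weighted by
    ``(FPKM + 1)^coupling_beta`` and intergenic placement uniform over the
    gene-free space.  Observed read support is depth ~ Poisson(mean_depth)
    (floored at ``min_depth``) and alt_reads ~ Binomial(depth, VAF).

    ``weight_condition`` selects which condition's transcriptional state
    drives the genic placement weights (default: the sampled condition);
    recovery samples use the acute-stress state, where the retained
    mutations were established.
    """
    label = SampleLabel(genotype, condition).validate()
    rate = config.resolve_rate(genotype, condition)
    t1f = config.resolve_tier1_fraction(genotype, condition)
    beta = config.resolve_beta(genotype, condition)

    expr_c = expression[expression["condition"] == (weight_condition or condition)]
    fpkm = expr_c.set_index("gene_id")["fpkm"]
    missing = [g.gene_id for g in genes if g.gene_id not in fpkm.index]
    if missing:
        raise RsMutError(
            f"expression table does not cover condition {(weight_condition or condition)!r} "
            f"for genes {missing[:3]}{'...' if len(missing) > 3 else ''}"
        )

    rng = config.rng("variants", genotype, condition)
    n = int(rng.poisson(rate))
    if n == 0:
        return []

    intervals, iprobs = _intergenic_intervals(genes, config)

    genic = rng.random(n) < t1f if genes else np.zeros(n, dtype=bool)
    latent_vaf = sample_vafs(config, genotype, n, rng)
    is_indel = rng.random(n) < config.indel_fraction

    # vectorized placement: one containing interval (gene span or intergenic
    # gap) per mutation, then a uniform position inside it
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    chroms = np.empty(n, dtype=object)
    if genic.any():
        w = (fpkm.loc[[g.gene_id for g in genes]].to_numpy() + 1.0) ** beta
        gidx = rng.choice(len(genes), size=int(genic.sum()), p=w / w.sum())
        lo[genic] = [genes[i].start for i in gidx]
        hi[genic] = [genes[i].end for i in gidx]
        chroms[genic] = [genes[i].chrom for i in gidx]
    n_inter = int((~genic).sum())
    if n_inter:
        iidx = rng.choice(len(intervals), size=n_inter, p=iprobs)
        lo[~genic] = [intervals[i][1] for i in iidx]
        hi[~genic] = [intervals[i][2] for i in iidx]
        chroms[~genic] = [intervals[i][0] for i in iidx]
    positions = rng.integers(lo, hi + 1)
    depth = np.maximum(rng.poisson(config.mean_depth, n), config.min_depth)
    alt_reads = rng.binomial(depth, latent_vaf)

    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    for i in range(n):
        pos = int(positions[i])
        for _ in range(100):  # resample on (chrom,pos,ref,alt) collision
            ref, alt = _alleles(rng, bool(is_indel[i]))
            pos = min(pos, config.chrom_length - len(ref) + 1)
            key = (str(chroms[i]), pos, ref, alt)
            if key not in seen:
                break
            pos = int(rng.integers(lo[i], hi[i] + 1))
        else:
            raise RsMutError("could not place a unique variant after 100 attempts")
        seen.add(key)
        records.append(
            VariantRecord(key[0], key[1], key[2], key[3], int(depth[i]), int(alt_reads[i]), label)
        )
    records.sort(key=lambda r: r.key)
    return records


def _intergenic_intervals(genes, config: SimConfig):
    """(chrom, start, end) complement of gene spans, with cumulative weights."""
    by_chrom = genes_by_chrom(genes)
    out = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 1
        for g in by_chrom.get(chrom, []):
            if g.start > pos:
                out.append((chrom, pos, g.start - 1))
            pos = g.end + 1
        if pos <= config.chrom_length:
            out.append((chrom, pos, config.chrom_length))
    if not out:
        raise ConfigError("no intergenic space left for tier-2 placement")
    lengths = np.array([e - s + 1 for _, s, e in out], dtype=float)
    return out, lengths / lengths.sum()


def _alleles(rng, indel: bool) -> tuple[str, str]:
    if not indel:
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        return ref, alt
    anchor = str(rng.choice(_BASES))
    ins_len = int(rng.integers(1, _MAX_INDEL + 1))
    tail = "".join(rng.choice(_BASES, ins_len))
    if rng.random() < 0.5:  # insertion
        return anchor, anchor + tail
    return anchor + tail, anchor  # deletion


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig):
    """Simulate the full two-genotype, five-condition design.

    Returns ``(genes, expression, variant_sets)`` where ``expression`` maps
    genotype -> DataFrame over all conditions and ``variant_sets`` maps
    SampleLabel -> VariantSet.
    """
    genes = generate_gene_model(config)
    expression: dict[str, pd.DataFrame] = {}
    variant_sets: dict[SampleLabel, VariantSet] = {}
    for genotype in GENOTYPES:
        tables = [
            generate_expression(genes, config, condition, genotype=genotype)
            for condition in CONDITIONS
        ]
        expression[genotype] = pd.concat(tables, ignore_index=True)
        for condition in CONDITIONS:
            # retained recovery mutations arose in the acute-stress state
            weight_condition = "HU4h" if condition == "Rec72h" else None
            records = simulate_variants(
                genes, expression[genotype], config, genotype, condition,
                weight_condition=weight_condition,
            )
            label = SampleLabel(genotype, condition)
            variant_sets[label] = VariantSet(
                label, records, provenance={"simulated": True, "seed": config.seed}
            )
    return genes, expression, variant_sets
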