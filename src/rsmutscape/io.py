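"""File interchange: VCF 4.x variants, BED6/GFF-like gene models, TSV expression.

Readers lean on pysam (VCF) and pandas (tables).  Writers are deliberately
plain text with a fixed field order so that identical inputs yield
byte-identical files, which the determinism guarantees of the simulator rely
on.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import RsMutError, VcfFieldError
from .model import GeneFeature, GeneModel, SampleLabel, VariantRecord, VariantSet

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(variants: Sequence[VariantRecord], path: str | Path, sample_name: str | None = None) -> None:
    """Write records as a minimal single-sample VCF 4.2 with FORMAT GT:DP:AD.

    AD carries (ref, alt) read counts so the VAF is recomputable on re-ingest.
    Records are sorted by (chrom, pos, ref, alt); an empty list yields a
    valid header-only VCF.
    """
    path = Path(path)
    recs = sorted(variants, key=lambda r: r.key)
    if sample_name is None:
        if recs:
            sample_name = "_".join(recs[0].sample_label)
        else:
            sample_name = "sample"
    contigs = sorted({r.chrom for r in recs})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name,
    ]
    for r in recs:
        sample = f"0/1:{r.depth}:{r.depth - r.alt_reads},{r.alt_reads}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\tGT:DP:AD\t{sample}"
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise RsMutError(f"cannot write VCF to {path}: {exc}") from exc


def read_vcf(path: str | Path, sample_label: SampleLabel | tuple[str, str], min_alt_reads: int = 0) -> VariantSet:
    """Read a VCF into a VariantSet.

    Multi-allelic records are split into one record per ALT allele; depth
    comes from FORMAT/DP (fallback INFO/DP) and alt support from FORMAT/AD
    (fallback INFO/AD).  Records lacking both are a hard error naming the
    locus.  Duplicate (chrom, pos, ref, alt) keys keep the first occurrence.
    """
    path = Path(path)
    label = SampleLabel(*sample_label).validate()
    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            depth, ad = _support_fields(rec)
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                alt_reads = ad[i + 1]
                vr = VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    depth=depth,
                    alt_reads=min(alt_reads, depth),
                    sample_label=label,
                )
                if vr.key in seen:
                    continue
                seen.add(vr.key)
                records.append(vr)
    vs = VariantSet(sample_label=label, records=records, provenance={"source": str(path)})
    if min_alt_reads > 0:
        vs = filter_min_support(vs, min_reads=min_alt_reads)
    return vs


def _support_fields(rec) -> tuple[int, Sequence[int]]:
    locus = f"{rec.chrom}:{rec.pos}"
    ad = None
    depth = None
    if rec.samples:
        fmt = rec.samples[0]
        if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
            ad = list(fmt["AD"])
        if "DP" in fmt and fmt["DP"] is not None:
            depth = int(fmt["DP"])
    if ad is None and "AD" in rec.info:
        ad = list(rec.info["AD"])
    if depth is None and "DP" in rec.info:
        depth = int(rec.info["DP"])
    if ad is None:
        raise VcfFieldError(f"record at {locus} has no AD field; VAF not recoverable")
    if depth is None:
        depth = int(sum(a for a in ad if a is not None))
    if depth <= 0:
        raise VcfFieldError(f"record at {locus} has non-positive depth")
    return depth, ad


def filter_min_support(vs: VariantSet, min_reads: int = 5, on: str = "alt") -> VariantSet:
    """Retain variants supported by at least ``min_reads`` reads.

    ``on="alt"`` (default) counts alt-allele supporting reads, the usual
    somatic-filter reading; ``on="depth"`` applies the threshold to total
    depth instead.  The boundary is inclusive and the operation idempotent.
    """
    if on not in ("alt", "depth"):
        raise RsMutError(f"filter_min_support: on must be 'alt' or 'depth', got {on!r}")
    keep = [
        r
        for r in vs.records
        if (r.alt_reads if on == "alt" else r.depth) >= min_reads
    ]
    prov = dict(vs.provenance)
    prov["min_support"] = {"min_reads": min_reads, "on": on}
    return VariantSet(sample_label=vs.sample_label, records=keep, provenance=prov)


# ---------------------------------------------------------------------------
# Gene model: BED6 spans + GFF3-like feature table
# ---------------------------------------------------------------------------


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    """BED6 of gene spans: 0-based half-open, i.e. (start-1, end)."""
    lines = [
        f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
        for g in genes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_gene_features(genes: Iterable[GeneModel], path: str | Path) -> None:
    """GFF3-like table: one ``gene`` row per gene plus its tiling features.

    Feature types use the internal kinds (UTR5, exon_cds, intron, UTR3) so the
    table round-trips exactly; coordinates are 1-based inclusive as in GFF3.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};biotype={g.biotype}"
        )
        for f in g.features:
            lines.append(
                f"{g.chrom}\tsim\t{f.kind}\t{f.start}\t{f.end}\t.\t{g.strand}\t.\t"
                f"Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read the GFF3-like feature table back into GeneModel objects."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        dtype={"chrom": str},
    )
    attrs = df["attrs"].map(_parse_attrs)
    genes: list[GeneModel] = []
    current: dict | None = None
    for row, a in zip(df.itertuples(index=False), attrs):
        if row.type == "gene":
            if current is not None:
                genes.append(_finish_gene(current))
            current = {
                "gene_id": a["ID"],
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "strand": row.strand,
                "biotype": a.get("biotype", "coding"),
                "features": [],
            }
        else:
            if current is None or a.get("Parent") != current["gene_id"]:
                raise RsMutError(f"feature row with no preceding gene row in {path}")
            current["features"].append(GeneFeature(row.type, int(row.start), int(row.end)))
    if current is not None:
        genes.append(_finish_gene(current))
    return genes


def _parse_attrs(s: str) -> dict[str, str]:
    return dict(kv.split("=", 1) for kv in s.split(";") if "=" in kv)


def _finish_gene(d: dict) -> GeneModel:
    feats = tuple(sorted(d.pop("features"), key=lambda f: f.start))
    return GeneModel(features=feats, **d)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write an expression table (gene_id, condition, fpkm) as TSV."""
    cols = ["gene_id", "condition", "fpkm"]
    missing = set(cols) - set(table.columns)
    if missing:
        raise RsMutError(f"expression table missing columns {sorted(missing)}")
    # default float repr is shortest-round-trip, so read_expression_tsv is exact
    table[cols].to_csv(str(path), sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        str(path), sep="\t", dtype={"gene_id": str, "condition": str},
        float_precision="round_trip",
    )
    if (df["fpkm"] < 0).any():
        raise RsMutError(f"negative FPKM in {path}")
    dup = df.duplicated(["gene_id", "condition"])
    if dup.any():
        raise RsMutError(f"duplicate (gene_id, condition) rows in {path}")
    return df
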