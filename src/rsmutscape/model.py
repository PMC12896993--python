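"""Core in-memory types: variants, variant sets, and gene models.

Coordinates are 1-based inclusive throughout (VCF/GFF convention); the BED
writer converts to 0-based half-open at the file boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import RsMutError

GENOTYPES = ("WT", "K337X")
CONDITIONS = ("T0", "Ctrl4h", "HU4h", "Ctrl72h", "Rec72h")

#: (treated, matched control) pairs used for burden deltas.
CONDITION_PAIRS = {"HU4h": "Ctrl4h", "Rec72h": "Ctrl72h"}

FEATURE_KINDS = ("UTR5", "exon_cds", "intron", "UTR3")


class SampleLabel(NamedTuple):
    genotype: str  # WT | K337X
    condition: str  # T0 | Ctrl4h | HU4h | Ctrl72h | Rec72h

    def validate(self) -> "SampleLabel":
        if self.genotype not in GENOTYPES:
            raise RsMutError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.condition not in CONDITIONS:
            raise RsMutError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        return self


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A called SNV or indel with read support.

    ``vaf`` is derived as ``alt_reads / depth`` so the VAF invariant can
    never drift from the read counts, and records survive file round trips
    bit-for-bit (DP and AD are the serialized truth).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    sample_label: SampleLabel

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.depth):
            raise RsMutError(
                f"alt_reads must satisfy 0 <= alt_reads <= depth, got "
                f"{self.alt_reads}/{self.depth} at {self.chrom}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def variant_type(self) -> str:
        """"SNV" iff both alleles are single bases, else "Indel"."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "Indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    """Variants from one sample plus the provenance that produced them."""

    sample_label: SampleLabel
    records: list[VariantRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise RsMutError("duplicate (chrom, pos, ref, alt) keys in variant set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def vafs(self, variant_type: str | None = None) -> list[float]:
        return [r.vaf for r in self.records if variant_type in (None, r.variant_type)]


@dataclass(frozen=True, slots=True)
class GeneFeature:
    kind: str  # UTR5 | exon_cds | intron | UTR3
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon/UTR substructure tiling [start, end] without gaps."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # + | -
    features: tuple[GeneFeature, ...]
    biotype: str = "coding"  # coding | ncRNA

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RsMutError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise RsMutError(f"{self.gene_id}: bad strand {self.strand!r}")
        pos = self.start
        for f in self.features:
            if f.start != pos:
                raise RsMutError(f"{self.gene_id}: features do not tile the gene span")
            if f.kind not in FEATURE_KINDS:
                raise RsMutError(f"{self.gene_id}: unknown feature kind {f.kind!r}")
            pos = f.end + 1
        if pos != self.end + 1:
            raise RsMutError(f"{self.gene_id}: features do not reach gene end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def feature_at(self, pos: int) -> GeneFeature | None:
        if not (self.start <= pos <= self.end):
            return None
        for f in self.features:
            if f.start <= pos <= f.end:
                return f
        return None  # unreachable for a valid gene


def genes_by_chrom(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: g.start)
    return out
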