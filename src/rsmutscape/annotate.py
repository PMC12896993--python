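"""refGene-style functional annotation of variants against a gene model.

Each variant receives exactly one category by precedence

    exonic > splicing > UTR5 > UTR3 > intronic > ncRNA > upstream >
    downstream > intergenic

and a tier: tier 1 for every gene-associated category, tier 2 for
intergenic.  ``splicing`` means the first ``splice_window`` intronic bases
adjacent to an exon-intron boundary; ``upstream``/``downstream`` mean within
``flank`` bp of the strand-aware gene ends while outside every gene body.
An alternative, narrower tier-1 definition restricted to transcribed
sequence (exonic, UTRs, ncRNA) is available via ``tier1_strict``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import UnknownChromosomeError
from .model import GeneModel, VariantRecord, VariantSet

logger = logging.getLogger(__name__)

CATEGORIES = (
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "intronic",
    "ncRNA",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

#: Narrow tier-1 membership: transcribed sequence only.
TIER1_STRICT = frozenset({"exonic", "UTR5", "UTR3", "ncRNA"})

DEFAULT_FLANK = 1000
DEFAULT_SPLICE_WINDOW = 2


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: VariantRecord
    category: str
    tier: str  # tier1 | tier2
    gene_id: str | None


class GeneIndex:
    """Interval index over gene spans extended by the flank distance."""

    def __init__(self, genes: Iterable[GeneModel], flank: int = DEFAULT_FLANK):
        self.flank = flank
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # half-open interval over [start - flank, end + flank]
            tree.addi(g.start - flank, g.end + flank + 1, g)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def candidates(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def classify_position(
    pos: int,
    gene: GeneModel,
    flank: int = DEFAULT_FLANK,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> str | None:
    """Category of a single base relative to one gene, or None if unrelated."""
    if pos < gene.start:
        if gene.start - pos > flank:
            return None
        return "upstream" if gene.strand == "+" else "downstream"
    if pos > gene.end:
        if pos - gene.end > flank:
            return None
        return "downstream" if gene.strand == "+" else "upstream"
    if gene.biotype == "ncRNA":
        return "ncRNA"
    feat = gene.feature_at(pos)
    if feat.kind == "exon_cds":
        return "exonic"
    if feat.kind in ("UTR5", "UTR3"):
        return feat.kind
    # intron: splice-adjacent bases outrank plain intronic
    if min(pos - feat.start, feat.end - pos) < splice_window:
        return "splicing"
    return "intronic"


def classify_variant(
    v: VariantRecord,
    index: GeneIndex,
    flank: int | None = None,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
    on_unknown_chrom: str = "warn",
) -> tuple[str, str | None]:
    """(category, gene_id) for a variant; gene_id is None iff intergenic.

    Indels are evaluated at every reference base they affect and take the
    highest-precedence category over affected bases and overlapping genes;
    ties across genes break on lexicographic gene_id.
    """
    flank = index.flank if flank is None else flank
    if v.chrom not in index.chroms:
        if on_unknown_chrom == "error":
            raise UnknownChromosomeError(f"chromosome {v.chrom!r} not in gene model")
        logger.warning("chromosome %r not in gene model; classifying as intergenic", v.chrom)
        return "intergenic", None
    positions = range(v.pos, v.pos + max(len(v.ref), 1))
    best: tuple[int, str, str | None] = (_RANK["intergenic"], "", None)
    found = False
    for pos in positions:
        for gene in index.candidates(v.chrom, pos):
            cat = classify_position(pos, gene, flank=flank, splice_window=splice_window)
            if cat is None:
                continue
            cand = (_RANK[cat], gene.gene_id, gene.gene_id)
            if not found or cand < best:
                best, found = cand, True
    if not found:
        return "intergenic", None
    return CATEGORIES[best[0]], best[2]


def assign_tier(category: str, tier1_strict: bool = False) -> str:
    """tier2 for intergenic (plus non-transcribed categories when strict)."""
    if category == "intergenic":
        return "tier2"
    if tier1_strict and category not in TIER1_STRICT:
        return "tier2"
    return "tier1"


def annotate_set(
    vs: VariantSet | Sequence[VariantRecord],
    genes: Sequence[GeneModel] | GeneIndex,
    flank: int = DEFAULT_FLANK,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
    tier1_strict: bool = False,
    on_unknown_chrom: str = "warn",
) -> list[AnnotatedVariant]:
    """Annotate every record; output length always equals input length."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, flank=flank)
    out = []
    for rec in vs:
        cat, gene_id = classify_variant(
            rec, index, flank=flank, splice_window=splice_window,
            on_unknown_chrom=on_unknown_chrom,
        )
        tier = assign_tier(cat, tier1_strict=tier1_strict)
        out.append(AnnotatedVariant(rec, cat, tier, gene_id))
    return out
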