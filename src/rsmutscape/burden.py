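"""Δ mutation burden between a treated and a matched control sample.

Burden tables are tidy DataFrames with one row per
(variant_type, stratum, VAF bin) cell and a ``delta_count`` column equal to
``treated_count - control_count``.  Deltas may be negative (recovery reduces
burden); the positive-only view used for the recovery-by-category summary
clips at zero.
"""
from __future__ import annotations

from bisect import bisect_right
from typing import Sequence

import pandas as pd

from .annotate import CATEGORIES, AnnotatedVariant
from .errors import GenotypeMismatchError, RsMutError

#: Printed VAF strata; bins are left-closed/right-open except the last,
#: which is closed at 1, so a shared endpoint belongs to the upper bin.
VAF_BIN_EDGES = (0.1, 0.4, 0.6, 0.85)
VAF_BIN_LABELS = ("<0.1", "0.1–0.4", "0.4–0.6", "0.6–0.85", ">0.85")

VARIANT_TYPES = ("SNV", "Indel")

#: Categories with HU-dependent changes in the recovered population.
RECOVERY_CATEGORIES = ("downstream", "exonic", "UTR3", "UTR5")


def vaf_bin(vaf: float) -> str:
    """Map a VAF in [0, 1] to its printed stratum label."""
    if not 0.0 <= vaf <= 1.0:
        raise RsMutError(f"VAF must be in [0, 1], got {vaf}")
    return VAF_BIN_LABELS[bisect_right(VAF_BIN_EDGES, vaf)]


def _strata(stratify: str) -> tuple[str, ...]:
    if stratify == "tier":
        return ("tier1", "tier2")
    if stratify == "category":
        return CATEGORIES
    raise RsMutError(f"stratify must be 'tier' or 'category', got {stratify!r}")


def _check_genotypes(treated: Sequence[AnnotatedVariant], control: Sequence[AnnotatedVariant]) -> str:
    gts = {av.variant.sample_label.genotype for av in treated} | {
        av.variant.sample_label.genotype for av in control
    }
    if len(gts) > 1:
        raise GenotypeMismatchError(f"treated and control sets mix genotypes {sorted(gts)}")
    return gts.pop() if gts else "NA"


def _count(annotated: Sequence[AnnotatedVariant], stratify: str, by_vaf_bin: bool) -> dict:
    counts: dict[tuple, int] = {}
    for av in annotated:
        stratum = av.tier if stratify == "tier" else av.category
        b = vaf_bin(av.variant.vaf) if by_vaf_bin else "all"
        key = (av.variant.variant_type, stratum, b)
        counts[key] = counts.get(key, 0) + 1
    return counts


def delta_burden(
    treated: Sequence[AnnotatedVariant],
    control: Sequence[AnnotatedVariant],
    stratify: str = "tier",
    by_vaf_bin: bool = True,
) -> pd.DataFrame:
    """Per-stratum treated/control counts and their (possibly negative) delta.

    Every (variant_type, stratum, bin) cell of the full cross-product is
    present, zero-filled, so marginal sums are straightforward.
    """
    genotype = _check_genotypes(treated, control)
    t_counts = _count(treated, stratify, by_vaf_bin)
    c_counts = _count(control, stratify, by_vaf_bin)
    bins = VAF_BIN_LABELS if by_vaf_bin else ("all",)
    rows = []
    for vt in VARIANT_TYPES:
        for stratum in _strata(stratify):
            for b in bins:
                t = t_counts.get((vt, stratum, b), 0)
                c = c_counts.get((vt, stratum, b), 0)
                rows.append(
                    {
                        "genotype": genotype,
                        "variant_type": vt,
                        "stratum_kind": stratify,
                        "stratum": stratum,
                        "vaf_bin": b,
                        "treated_count": t,
                        "control_count": c,
                        "delta_count": t - c,
                    }
                )
    return pd.DataFrame(rows)


def positive_delta_by_category(
    treated: Sequence[AnnotatedVariant],
    control: Sequence[AnnotatedVariant],
    categories: Sequence[str] = RECOVERY_CATEGORIES,
) -> pd.DataFrame:
    """Recovery-style positive deltas restricted to selected categories.

    Negative deltas are clipped to zero; rows outside ``categories`` are
    dropped entirely.
    """
    table = delta_burden(treated, control, stratify="category", by_vaf_bin=False)
    table = table[table["stratum"].isin(categories)].copy()
    table["delta_count"] = table["delta_count"].clip(lower=0)
    return table.reset_index(drop=True)


def burden_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(str(path), sep="\t", index=False)
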