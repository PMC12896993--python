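"""Expression-mutation coupling: per-gene burdens, quartiles, and Spearman tests.

The headline statistic is the Spearman correlation between
``log10(FPKM + 1)`` and ``log10(mutation count + 1)`` over genes in the top
expression quartile (Q4), optionally restricted to genes gaining at least
``delta_threshold`` mutations over their matched control ("stress-induced
gains").  Because Spearman is a rank statistic the log transforms do not
change rho; they are kept so reported effect sizes stay comparable to
scatter-plot conventions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotatedVariant
from .errors import CouplingFilterError, RsMutError
from .model import GeneModel

QUARTILES = ("Q1", "Q2", "Q3", "Q4")

#: Largest n for which the Spearman p-value is computed by full enumeration
#: of the n! rank permutations (9! = 362,880); above this the t
#: approximation is used.
EXACT_PERM_MAX_N = 9


@dataclass(frozen=True)
class CouplingResult:
    rho: float
    p_value: float
    n_genes: int
    quartile: str | None
    delta_threshold: int | None
    expression_condition: str | None = None
    mutation_baseline_condition: str | None = None
    filters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-gene profiles
# ---------------------------------------------------------------------------


def per_gene_counts(
    annotated: Sequence[AnnotatedVariant],
    gene_universe: Sequence[str] | Sequence[GeneModel] | None = None,
) -> pd.Series:
    """Tier-1 variant counts keyed by host gene.

    With a gene universe, genes without variants appear with count 0; the
    counts always sum to the number of tier-1 variants.
    """
    counts: dict[str, int] = {}
    for av in annotated:
        if av.tier == "tier1" and av.gene_id is not None:
            counts[av.gene_id] = counts.get(av.gene_id, 0) + 1
    s = pd.Series(counts, dtype=int, name="mut_count")
    if gene_universe is not None:
        ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in gene_universe]
        s = s.reindex(ids, fill_value=0).astype(int)
    s.index.name = "gene_id"
    return s


def expression_quartiles(expr: pd.DataFrame, condition: str) -> pd.Series:
    """Quartile label per gene from the FPKM distribution of one condition.

    Boundaries are the linear-interpolation 25/50/75th percentiles over the
    *full* gene universe; a gene whose FPKM equals a boundary falls in the
    lower quartile, so fully tied inputs collapse into Q1.
    """
    sub = expr[expr["condition"] == condition]
    if sub.empty:
        raise RsMutError(f"no expression rows for condition {condition!r}")
    if len(sub) < 4:
        raise RsMutError(f"expression_quartiles needs >= 4 genes, got {len(sub)}")
    fpkm = sub.set_index("gene_id")["fpkm"]
    q25, q50, q75 = np.percentile(fpkm.to_numpy(), [25, 50, 75])
    labels = np.select(
        [fpkm <= q25, fpkm <= q50, fpkm <= q75], ["Q1", "Q2", "Q3"], default="Q4"
    )
    return pd.Series(labels, index=fpkm.index, name="quartile")


def gene_profiles(
    treated: Sequence[AnnotatedVariant],
    control: Sequence[AnnotatedVariant],
    expr: pd.DataFrame,
    expression_condition: str,
    gene_universe: Sequence[GeneModel] | Sequence[str],
) -> pd.DataFrame:
    """Join per-gene counts, deltas, FPKM, and quartiles over a gene universe."""
    ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in gene_universe]
    t = per_gene_counts(treated, ids)
    c = per_gene_counts(control, ids)
    sub = expr[expr["condition"] == expression_condition]
    if sub.empty:
        raise RsMutError(f"expression table has no condition {expression_condition!r}")
    fpkm = sub.set_index("gene_id")["fpkm"].reindex(ids)
    if fpkm.isna().any():
        raise RsMutError(
            f"expression condition {expression_condition!r} does not cover the gene universe"
        )
    quart = expression_quartiles(expr, expression_condition).reindex(ids)
    return pd.DataFrame(
        {
            "gene_id": ids,
            "fpkm": fpkm.to_numpy(),
            "mut_count_treated": t.to_numpy(),
            "mut_count_control": c.to_numpy(),
            "delta": (t - c).to_numpy(),
            "quartile": quart.to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact-permutation p for small n.

    For n <= EXACT_PERM_MAX_N the two-sided p is the fraction of all n!
    pairings whose |rho| reaches the observed |rho|; larger samples use the
    t approximation.  Ties are mid-ranked in both regimes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise RsMutError("spearman requires at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERM_MAX_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, min(p, 1.0)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = math.sqrt(float(rx_c @ rx_c)) * np.sqrt((ry_c**2).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


# ---------------------------------------------------------------------------
# Coupling tests
# ---------------------------------------------------------------------------


def coupling_test(
    profiles: pd.DataFrame,
    quartile: str | None = "Q4",
    delta_threshold: int = 3,
    use_delta_filter: bool = True,
    correlate: str = "treated",
    expression_condition: str | None = None,
    mutation_baseline_condition: str | None = None,
) -> CouplingResult:
    """Spearman test of log10(FPKM+1) against log10(count+1) on filtered genes.

    ``correlate="treated"`` (default) correlates the treated-condition
    counts, the scatter-axis convention; ``correlate="delta"`` uses the
    control-subtracted gains instead.  Control-condition analyses should
    pass ``use_delta_filter=False`` (no stress-induced-gain gate applies).
    """
    if profiles.empty:
        raise CouplingFilterError("empty gene profile table")
    if correlate not in ("treated", "delta"):
        raise RsMutError(f"correlate must be 'treated' or 'delta', got {correlate!r}")
    sub = profiles
    applied: dict = {}
    if quartile is not None:
        if quartile not in QUARTILES:
            raise RsMutError(f"unknown quartile {quartile!r}")
        sub = sub[sub["quartile"] == quartile]
        applied["quartile"] = quartile
        if sub.empty:
            raise CouplingFilterError(f"quartile filter {quartile} left no genes")
    if use_delta_filter:
        sub = sub[sub["delta"] >= delta_threshold]
        applied["delta_threshold"] = delta_threshold
        if len(sub) < 3:
            raise CouplingFilterError(
                f"delta >= {delta_threshold} filter left {len(sub)} genes (< 3)"
            )
    if len(sub) < 3:
        raise CouplingFilterError(f"filters left {len(sub)} genes (< 3)")
    counts = sub["mut_count_treated"] if correlate == "treated" else sub["delta"]
    x = np.log10(sub["fpkm"].to_numpy() + 1.0)
    y = np.log10(np.maximum(counts.to_numpy(), 0) + 1.0)
    rho, p = spearman(x, y)
    applied["correlate"] = correlate
    return CouplingResult(
        rho=rho,
        p_value=p,
        n_genes=int(len(sub)),
        quartile=quartile,
        delta_threshold=delta_threshold if use_delta_filter else None,
        expression_condition=expression_condition,
        mutation_baseline_condition=mutation_baseline_condition,
        filters=applied,
    )


def recovery_coupling(
    variants_recovery: Sequence[AnnotatedVariant],
    variants_control: Sequence[AnnotatedVariant],
    expr: pd.DataFrame,
    genes: Sequence[GeneModel] | Sequence[str],
    expression_condition: str = "HU4h",
    quartile: str = "Q4",
    delta_threshold: int = 3,
    correlate: str = "treated",
) -> CouplingResult:
    """Recovery-condition coupling with cross-referenced inputs.

    Mutation gains are recovery minus matched late control, while the
    expression state (FPKM values and quartile membership) is the one in
    which mutagenesis was established, i.e. the acute-stress transcriptome.
    """
    profiles = gene_profiles(
        variants_recovery, variants_control, expr, expression_condition, genes
    )
    return coupling_test(
        profiles,
        quartile=quartile,
        delta_threshold=delta_threshold,
        use_delta_filter=True,
        correlate=correlate,
        expression_condition=expression_condition,
        mutation_baseline_condition="Ctrl72h",
    )


def expressed_variant_count(
    annotated: Sequence[AnnotatedVariant],
    expr: pd.DataFrame,
    condition: str,
    fpkm_min: float = 1.0,
) -> int:
    """Tier-1 variants whose host gene is expressed (FPKM >= fpkm_min).

    A deliberate gene-overlap proxy for counting variants observable in a
    transcriptome, standing in for RNA-level variant calling.
    """
    sub = expr[expr["condition"] == condition]
    expressed = set(sub.loc[sub["fpkm"] >= fpkm_min, "gene_id"])
    return sum(
        1
        for av in annotated
        if av.tier == "tier1" and av.gene_id in expressed
    )
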