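"""Simulation configuration.

Several generative parameters differ between genotypes and/or treatment
conditions (mutation rate, genic fraction, expression coupling, VAF mixture).
They are therefore stored as mappings and resolved with the most specific
matching key, in order::

    "<genotype>:<condition>"  >  "<genotype>"  >  "<condition>"  >  "default"

A bare scalar (or a single mixture list) is accepted anywhere a mapping is
and applies to every genotype/condition.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError

#: Beta-mixture components (weight, alpha, beta) per genotype.  The WT mixture
#: concentrates VAFs near 0.5 with a clonal high-frequency shoulder at
#: 0.8-1.0; the K337X mixture is broad over 0.2-0.8, reflecting sub-clonal
#: diversification.
DEFAULT_VAF_MIXTURES = {
    "WT": [(0.45, 50.0, 50.0), (0.35, 45.0, 5.0), (0.20, 5.0, 45.0)],
    "K337X": [(0.80, 3.0, 3.0), (0.20, 30.0, 30.0)],
}

#: Expected called variants per sample.  Hydroxyurea exposure roughly doubles
#: the burden at 4 h; after 72 h recovery the excess partially resolves.
DEFAULT_BASELINE_RATE = {"default": 500.0, "HU4h": 1000.0, "Rec72h": 800.0}

#: Probability that a simulated mutation is placed inside a gene.  Under HU
#: the WT excess is genic while the K337X excess is intergenic; in the
#: recovered surviving population mutations are predominantly gene-proximal.
DEFAULT_TIER1_FRACTION = {
    "default": 0.5,
    "WT:HU4h": 0.8,
    "K337X:HU4h": 0.3,
    "WT:Rec72h": 0.9,
    "K337X:Rec72h": 0.9,
}

#: Exponent linking a gene's placement weight to (FPKM + 1).  Zero means
#: placement is independent of expression; TC-NER-deficient cells couple
#: mutation accumulation to transcription under and after stress.
DEFAULT_COUPLING_BETA = {"default": 0.0, "K337X:HU4h": 2.0, "K337X:Rec72h": 2.0}


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 500
    gene_length_mean: int = 8_000
    exons_per_gene: int = 5
    utr_fraction: float = 0.2
    ncrna_fraction: float = 0.1
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 0.9
    #: Portion of fpkm_log_sd that fluctuates between conditions; the rest is
    #: a stable per-gene level, so FPKMs correlate across conditions as real
    #: transcriptomes do.  Clipped to fpkm_log_sd; the marginal distribution
    #: of log FPKM keeps sd = fpkm_log_sd regardless.
    fpkm_condition_sd: float = 0.25
    baseline_rate: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATE)
    )
    tier1_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER1_FRACTION)
    )
    coupling_beta: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_BETA)
    )
    vaf_mixture: Mapping[str, Sequence[tuple[float, float, float]]] | Sequence = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VAF_MIXTURES.items()}
    )
    mean_depth: float = 80.0
    min_depth: int = 10
    indel_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("utr_fraction", "ncrna_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for gt in ("WT", "K337X"):
            mix = self.resolve_mixture(gt)
            w = sum(c[0] for c in mix)
            if abs(w - 1.0) > 1e-9:
                raise ConfigError(f"vaf_mixture weights for {gt} sum to {w}, expected 1")
            if any(c[0] < 0 or c[1] <= 0 or c[2] <= 0 for c in mix):
                raise ConfigError(f"vaf_mixture for {gt} has a non-positive weight or shape")

    # -- parameter resolution -------------------------------------------------

    def _resolve(self, value, genotype: str, condition: str, name: str):
        if not isinstance(value, Mapping):
            return value
        for key in (f"{genotype}:{condition}", genotype, condition, "default"):
            if key in value:
                return value[key]
        raise ConfigError(f"no {name} configured for {genotype}/{condition} and no default")

    def resolve_rate(self, genotype: str, condition: str) -> float:
        r = float(self._resolve(self.baseline_rate, genotype, condition, "baseline_rate"))
        if r < 0:
            raise ConfigError(f"baseline_rate must be >= 0, got {r}")
        return r

    def resolve_tier1_fraction(self, genotype: str, condition: str) -> float:
        f = float(self._resolve(self.tier1_fraction, genotype, condition, "tier1_fraction"))
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"tier1_fraction must be in [0, 1], got {f}")
        return f

    def resolve_beta(self, genotype: str, condition: str) -> float:
        return float(self._resolve(self.coupling_beta, genotype, condition, "coupling_beta"))

    def resolve_mixture(self, genotype: str, condition: str = "default"):
        mix = self._resolve(self.vaf_mixture, genotype, condition, "vaf_mixture")
        return [tuple(float(x) for x in comp) for comp in mix]

    # -- deterministic per-purpose RNG streams --------------------------------

    def rng(self, *tokens: str) -> np.random.Generator:
        """Independent stream keyed by the config seed and string tokens."""
        entropy = [int(self.seed)] + [zlib.crc32(t.encode()) for t in tokens]
        return np.random.default_rng(np.random.SeedSequence(entropy))

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["vaf_mixture"], Mapping):
            d["vaf_mixture"] = {k: [list(c) for c in v] for k, v in d["vaf_mixture"].items()}
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls(**data)
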