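"""Exception hierarchy."""


class RsMutError(Exception):
    """Base class for all package errors."""


class ConfigError(RsMutError):
    """Invalid or infeasible simulation configuration."""


class VcfFieldError(RsMutError):
    """A VCF record lacks the depth/allele-depth fields needed to compute a VAF."""


class GenotypeMismatchError(RsMutError):
    """Treated and control sets do not share a genotype."""


class CouplingFilterError(RsMutError):
    """Too few genes survive the coupling filters to run a correlation."""


class UnknownChromosomeError(RsMutError):
    """A variant's chromosome is absent from the gene model."""
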