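import pytest

from rsmutscape import (
    SampleLabel,
    SimConfig,
    VariantRecord,
    generate_expression,
    generate_gene_model,
)


@pytest.fixture(scope="session")
def toy_config() -> SimConfig:
    """Small, fast geometry: 50 genes on two 300 kb chromosomes."""
    return SimConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=50,
        gene_length_mean=2_000,
        exons_per_gene=3,
        baseline_rate=200.0,
        tier1_fraction=0.5,
        coupling_beta=0.0,
    )


@pytest.fixture(scope="session")
def toy_genes(toy_config):
    return generate_gene_model(toy_config)


@pytest.fixture(scope="session")
def toy_expression(toy_config, toy_genes):
    return generate_expression(toy_genes, toy_config, "HU4h")


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    depth=50,
    alt_reads=20,
    genotype="WT",
    condition="HU4h",
) -> VariantRecord:
    return VariantRecord(
        chrom, pos, ref, alt, depth, alt_reads, SampleLabel(genotype, condition)
    )


@pytest.fixture
def record_factory():
    return make_record
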