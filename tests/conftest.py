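import pytest

from tasiflow import synth


@pytest.fixture(scope="session")
def small_genome() -> synth.AnnotatedGenome:
    """A compact annotated genome shared by read-level tests."""
    spec = synth.GenomeSpec(
        n_chromosomes=2,
        chrom_length=60_000,
        n_features={
            "protein_coding": 10,
            "TE_gene": 3,
            "pseudogene": 2,
            "intergenic_TE": 3,
            "MIRNA": 6,
            "TAS": 3,
            "tRNA": 3,
            "rRNA": 2,
            "snoRNA": 2,
            "snRNA": 2,
        },
        seed=11,
    )
    return synth.generate_genome(spec)


@pytest.fixture(scope="session")
def small_effect_spec() -> synth.SmrnaEffectSpec:
    return synth.SmrnaEffectSpec(depth=3000, seed=5)
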