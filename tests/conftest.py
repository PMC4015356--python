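import pytest

from ideoplot import (
    SyntheticStudySpec,
    builtin_genome,
    generate_synthetic_input,
    parse_input,
    synthetic_genome,
)

EIGHT_PHENOTYPES = [
    "rheumatoid arthritis", "Crohn's disease", "blood pressure",
    "Alzheimer's disease", "breast cancer", "pancreatic cancer",
    "colorectal cancer", "prostate cancer",
]


@pytest.fixture(scope="session")
def hg19():
    return builtin_genome()


@pytest.fixture(scope="session")
def tiny_genome():
    """Two 1 Mb chromosomes; fast to lay out and render."""
    return synthetic_genome(2, 1_000_000, seed=7)


@pytest.fixture(scope="session")
def gwas_like_input(hg19):
    """An eight-phenotype catalog-style study on the full genome."""
    spec = SyntheticStudySpec(
        n_records=120,
        phenotype_labels=EIGHT_PHENOTYPES,
        note_fraction=0.1,
        seed=7,
    )
    return parse_input(generate_synthetic_input(spec, hg19))
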