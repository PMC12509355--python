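import pytest

from organelle_census import NucleusModel, OrganelleModel


@pytest.fixture
def nucleus() -> NucleusModel:
    """Default diploid mESC-like nucleus, 450 µm³."""
    return NucleusModel(nucleus_volume=450.0)


@pytest.fixture
def focus() -> OrganelleModel:
    """A heterochromatin-focus-like organelle class."""
    return OrganelleModel(
        name="focus",
        volume=5.0,
        count_per_nucleus=10,
        rna_enrichment=0.5,
        nucleosome_enrichment=3.0,
        dapi_bias_correction=True,
    )
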