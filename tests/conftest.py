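import numpy as np
import pytest

from haploquant import Individual, Pedigree


@pytest.fixture
def sister_pedigree() -> Pedigree:
    """One founder dam, one haploid sire, two full-sister daughters."""
    return Pedigree(
        [
            Individual("dam", "female", nest="n1"),
            Individual("sire", "male", nest="n1"),
            Individual("d1", "female", dam="dam", sire="sire", nest="n1"),
            Individual("d2", "female", dam="dam", sire="sire", nest="n1"),
        ]
    )


@pytest.fixture
def aunt_niece_pedigree() -> Pedigree:
    """Aunt is the dam's full sister; niece via an unrelated sire."""
    return Pedigree(
        [
            Individual("gran", "female"),
            Individual("gsire", "male"),
            Individual("aunt", "female", dam="gran", sire="gsire"),
            Individual("mom", "female", dam="gran", sire="gsire"),
            Individual("sire2", "male"),
            Individual("niece", "female", dam="mom", sire="sire2"),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
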