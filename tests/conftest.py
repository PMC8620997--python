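import numpy as np
import pytest

from cypmeta.star_alleles import (
    AlleleDefinitionTable,
    StarAlleleDefinition,
    VariantSite,
    builtin_table,
)


@pytest.fixture(scope="session")
def cyp2d6_table() -> AlleleDefinitionTable:
    return builtin_table("CYP2D6")


@pytest.fixture(scope="session")
def cyp2c19_table() -> AlleleDefinitionTable:
    return builtin_table("CYP2C19")


def _site(i: int) -> VariantSite:
    return VariantSite(f"v{i}", "1", 1000 + i, "A", "T")


@pytest.fixture(scope="session")
def toy_table() -> AlleleDefinitionTable:
    """Four-allele toy gene with a nested (subset) allele pair.

    *B's defining variants are a strict superset of *A's, so a haplotype
    carrying v1+v2 matches both and must resolve to *B (most specific).
    """
    return AlleleDefinitionTable(
        gene="CYP2D6",
        alleles=[
            StarAlleleDefinition("*1", "CYP2D6", (), "normal", 1.0),
            StarAlleleDefinition("*A", "CYP2D6", (_site(1),), "decreased", 0.5),
            StarAlleleDefinition("*B", "CYP2D6", (_site(1), _site(2)), "none", 0.0),
            StarAlleleDefinition("*C", "CYP2D6", (_site(3),), "none", 0.0),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
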