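import numpy as np
import pytest

from bruwave import (
    ElongationProfile,
    GeneAnnotation,
    GeneKinetics,
    InitiationProfile,
    SimScenario,
)


@pytest.fixture
def gene_100kb() -> GeneAnnotation:
    return GeneAnnotation("g100", "chr1", 0, 100_000, "+")


@pytest.fixture
def const_elong_100kb() -> ElongationProfile:
    return ElongationProfile.constant(2.0, 100_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_scenario(genes, **kwargs) -> SimScenario:
    return SimScenario(tuple(genes), **kwargs)


def single_gene_scenario(pattern="sustained_up", length=100_000, rate=2.0,
                         baseline=1.0, fold=3.0, strand="+", **kwargs) -> SimScenario:
    gene = GeneAnnotation("g1", "chr1", 0, length, strand)
    if pattern == "constant":
        init = InitiationProfile.constant(baseline)
    else:
        init = InitiationProfile.from_pattern(pattern, baseline, fold=fold)
    elong = ElongationProfile.constant(rate, length)
    return make_scenario([GeneKinetics(gene, init, elong)], **kwargs)
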