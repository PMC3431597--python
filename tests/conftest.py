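import numpy as np
import pytest

from splitrace import (
    ClusterSpec,
    SimParams,
    StrainVariantMap,
    VariantSite,
    synthetic_variant_map,
)
from splitrace.cluster import CONTROL_GENES


@pytest.fixture
def beta_spec() -> ClusterSpec:
    return ClusterSpec.beta()


@pytest.fixture
def beta_variants(beta_spec) -> StrainVariantMap:
    """Variant/polyA map covering the beta cluster plus the two controls."""
    rng = np.random.default_rng(20120831)
    return synthetic_variant_map(tuple(beta_spec.isoform_ids) + CONTROL_GENES, rng)


@pytest.fixture
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture
def single_gene_variants() -> StrainVariantMap:
    """A minimal one-gene map for hand-constructed cells."""
    return StrainVariantMap(
        {"g": (VariantSite(100, "A", "G"), VariantSite(200, "C", "T"))},
        {"g": ()},
        ("B6", "JF1"),
    )


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
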