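from __future__ import annotations

import pytest

from dystmap.simulate import (
    ToyGeneConfig,
    default_cross_spec,
    make_toy_gene_model,
    make_variant_table,
    simulate_cross,
)


@pytest.fixture(scope="session")
def default_gene():
    """(reference region, transcript model, planted variant) with defaults."""
    return make_toy_gene_model(ToyGeneConfig(seed=0))


@pytest.fixture(scope="session")
def nine_variants(default_gene):
    region, transcript, planted = default_gene
    return make_variant_table(region, transcript, planted, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Backcross cohort with full penetrance, enough for 24 affected."""
    spec = default_cross_spec(n_offspring=60, seed=42, penetrance=1.0)
    return simulate_cross(spec)
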