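import numpy as np
import pytest

from panelgwas.io_formats import GenotypeMatrix, MarkerRecord
from panelgwas.synthetic import SimulationConfig, TraitSpec, TranslocationSpec


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small two-subpopulation panel with a translocation block."""
    return SimulationConfig(
        n_accessions=80,
        n_markers=300,
        rng_seed=11,
        ld_block_size=4,
        translocation=TranslocationSpec(n_carriers=15),
        traits=(TraitSpec("t1", causal={5: 0.6}, heritability=0.5),),
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    from panelgwas.synthetic import (
        inject_translocation_missingness,
        simulate_population,
    )

    gm, markers, truth = simulate_population(small_config)
    gm = inject_translocation_missingness(
        gm, markers, small_config.translocation, truth,
        small_config.stream("translocation"),
    )
    return gm, markers, truth


@pytest.fixture()
def tiny_gm() -> GenotypeMatrix:
    calls = np.array([[0, 2, 1], [1, -1, 0], [2, 2, 2]], dtype=np.int8)
    return GenotypeMatrix(["m1", "m2", "m3"], ["a1", "a2", "a3"], calls)


def make_markers(gm: GenotypeMatrix, chrom="1A", spacing=1000):
    return [
        MarkerRecord(id=mid, chrom=chrom, pos=(i + 1) * spacing)
        for i, mid in enumerate(gm.marker_ids)
    ]
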