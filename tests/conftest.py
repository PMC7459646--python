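import numpy as np
import pandas as pd
import pytest

from rrbskit.simulate import SimulationDesign, generate_genome, simulate_methylomes


@pytest.fixture(scope="session")
def toy_design():
    return SimulationDesign(
        seed=11, n_chromosomes=1, chrom_length=60_000, n_genes=10, n_effect_sites=60
    )


@pytest.fixture(scope="session")
def toy_genome(toy_design):
    return generate_genome(toy_design)


@pytest.fixture(scope="session")
def toy_methylomes(toy_design, toy_genome):
    return simulate_methylomes(toy_design, toy_genome.cpg_sites)


@pytest.fixture(scope="session")
def two_group_null():
    """10,000 null CpGs, 4 vs 4 samples, mean coverage 30."""
    design = SimulationDesign(seed=5, groups=("NC", "SS"), n_effect_sites=0)
    cpg = pd.DataFrame({"chrom": "chr1", "pos": np.arange(10_000) * 37})
    return design, simulate_methylomes(design, cpg)
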