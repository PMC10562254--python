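import numpy as np
import pandas as pd
import pytest

from hybridsel import (
    GenotypeMatrix,
    SimulationConfig,
    make_marker_map,
    simulate_founders,
)


@pytest.fixture(scope="session")
def founder_sim():
    """Small two-chromosome founder panels with truth labels."""
    cfg = SimulationConfig(
        n_chromosomes=2, markers_per_chromosome=400, diff_fraction=0.6,
        purity=0.95, seed=1,
    )
    indica, japonica, truth = simulate_founders(cfg)
    return cfg, indica, japonica, truth


@pytest.fixture(scope="session")
def fixed_founder_sim():
    """Founder panels with every differentiated marker fully fixed."""
    cfg = SimulationConfig(
        n_chromosomes=2, markers_per_chromosome=300, diff_fraction=1.0,
        purity=1.0, seed=2,
    )
    indica, japonica, truth = simulate_founders(cfg)
    return cfg, indica, japonica, truth


@pytest.fixture(scope="session")
def small_markers():
    return make_marker_map(
        SimulationConfig(n_chromosomes=2, markers_per_chromosome=100, seed=3)
    )


def toy_genotypes(dosage, chrom="chr1", start=100, spacing=1000):
    """GenotypeMatrix around a literal dosage array (n x m)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    m = dosage.shape[1]
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "cm": np.linspace(0, 1, m),
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(dosage, samples, markers)
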