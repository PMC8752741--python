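import numpy as np
import pandas as pd
import pytest

from uprnet.simulate import (DdegSpec, ModuleSpec, PeakSpec, SimulationConfig,
                             simulate_counts, simulate_genome, simulate_peaks)


def small_config(seed: int = 3) -> SimulationConfig:
    """A reduced study design for fast tests: 300 genes, 2 modules, 2 TFs."""
    return SimulationConfig(
        seed=seed,
        n_genes=300,
        deg_fraction=0.4,
        module_spec=(ModuleSpec("M1", 30, 2.0, 0.3), ModuleSpec("M2", 30, 2.0, 0.3)),
        ddeg_spec=(DdegSpec(0.1, 2.0, "bzip28"), DdegSpec(0.1, 2.0, "bzip60")),
        peak_spec={"bZIP28": PeakSpec(n_specific=10, n_constitutive=8),
                   "bZIP60": PeakSpec(n_specific=10, n_constitutive=8)},
        n_background_network=50,
    )


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def sim_counts(sim_config):
    return simulate_counts(sim_config)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def sim_peaks(sim_config, sim_genome):
    annotation, _, _, truth = sim_genome
    return simulate_peaks(sim_config, annotation, truth=truth)


@pytest.fixture
def toy_counts():
    """2 genotypes × 1 timepoint × 3 replicates, hand-sized counts."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(50)]
    cols = {}
    rows = []
    for genotype in ("Col0", "bzip28"):
        for treatment in ("Tm", "mock"):
            for rep in (1, 2, 3):
                sid = f"{genotype}_0h_{treatment}_r{rep}"
                cols[sid] = rng.poisson(200, len(genes))
                rows.append((sid, genotype, 0, treatment, rep))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "genotype", "timepoint",
                                        "treatment", "replicate"])
    return counts, sheet
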