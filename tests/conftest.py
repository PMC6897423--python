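import pytest

from neoy.config import SimulationConfig, YGroupConfig
from neoy.pipeline import cohort_window_trees
from neoy.simulate import genotype_records, simulate_cohort


def make_config(seed: int = 3, proto: float = 0.5, **kw) -> SimulationConfig:
    """A 1-Mb three-group cohort small enough for per-test simulation."""
    defaults = dict(
        chromosome_length=1_000_000,
        n_genes=8,
        gene_length=900,
        proto_donor_prob=proto,
        y_groups=[
            YGroupConfig("Y1", 2, 106.8, [400_000]),
            YGroupConfig("Y2", 2, 89.6, [200_000, 600_000]),
            YGroupConfig("Y3", 2, 135.2, [400_000]),
        ],
        nasuta_block=(800_000, 1_000_000),
        n_neoX=8,
        n_outgroup=3,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(make_config())


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return genotype_records(small_cohort)


@pytest.fixture(scope="session")
def tree_stage(small_cohort):
    """(window_trees, topologies, tip classes) for the session cohort."""
    return cohort_window_trees(small_cohort)
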