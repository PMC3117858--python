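import numpy as np
import pytest

from rrlchip.pipeline import run_discovery
from rrlchip.rrl_design import SizeWindow
from rrlchip.synthetic_data import PoolSpec, generate_genome, plant_snps


@pytest.fixture(scope="session")
def small_genome():
    """A 120 kb genome: one macro- and one GC-rich micro-chromosome."""
    return generate_genome({"macro": [100_000], "micro": [20_000]}, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return plant_snps(small_genome, density=1 / 300, seed=8)


@pytest.fixture(scope="session")
def small_discovery(small_genome, small_truth):
    """A two-pool error-free discovery run reused across test modules."""
    pools = [PoolSpec("B1", 25, 30.0), PoolSpec("BL", 25, 30.0)]
    return run_discovery(
        small_genome,
        small_truth,
        SizeWindow(125, 200),
        pools,
        error_rate=0.0,
        seed=3,
    )
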