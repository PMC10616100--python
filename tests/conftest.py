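import numpy as np
import pandas as pd
import pytest

from eqtlshare.config import MODULE_CATEGORIES, PipelineConfig, SimulationConfig
from eqtlshare.synth import compute_kinship, plant_sharing_structure, simulate_genotype_panel


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """One gene region, 6 blocks x 5 variants, tight LD."""
    return SimulationConfig(
        n_samples=200,
        n_blocks=6,
        variants_per_block=5,
        within_block_flip_prob=0.02,
        category_counts={"fetal-adult": 1},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_genotype_panel(small_config)


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return compute_kinship(small_panel)


@pytest.fixture(scope="session")
def small_truth(small_config, small_panel):
    return plant_sharing_structure(small_config, small_panel)


@pytest.fixture(scope="session")
def pipe_config() -> PipelineConfig:
    return PipelineConfig()


def association_table(
    p: np.ndarray,
    maf: float | np.ndarray = 0.3,
    n: int = 1000,
    chrom: str = "1",
    start_pos: int = 100,
    beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Helper: build a minimal association table for summary-level tests."""
    p = np.asarray(p, dtype=float)
    m = p.size
    return pd.DataFrame(
        {
            "variant": [f"v{i}" for i in range(m)],
            "chrom": chrom,
            "pos": np.arange(start_pos, start_pos + m),
            "ref": "A",
            "alt": "G",
            "beta": beta if beta is not None else np.ones(m),
            "se": 0.1,
            "p": p,
            "maf": np.broadcast_to(np.asarray(maf, dtype=float), (m,)).copy(),
            "n": n,
        }
    )
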