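import numpy as np
import pandas as pd
import pytest

from modulon import ExpressionCompendium, PipelineConfig


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    """Two projects, each with a 2-replicate reference and one test condition."""
    rows = [
        ("s1", "P1", "ref", True),
        ("s2", "P1", "ref", True),
        ("s3", "P1", "treat", False),
        ("s4", "P2", "ref", True),
        ("s5", "P2", "ref", True),
        ("s6", "P2", "heat", False),
    ]
    return pd.DataFrame(rows, columns=["sample_id", "project", "condition", "reference"])


@pytest.fixture
def small_compendium(small_metadata) -> ExpressionCompendium:
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(5.0, 1.0, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=small_metadata["sample_id"].tolist(),
    )
    return ExpressionCompendium(data)


@pytest.fixture
def fast_config() -> PipelineConfig:
    return PipelineConfig(n_runs=6, random_seed=11)
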