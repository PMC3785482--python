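from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from regks.containers import ExpressionMatrix
from regks.simulate import SimulationConfig, generate_signed_gene_sets, generate_study


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    intensity = pd.DataFrame(
        [[10.0, 20.0], [5.0, 8.0], [100.0, 90.0]],
        index=["ps1", "ps2", "ps3"],
        columns=["s1", "s2"],
    )
    calls = pd.DataFrame(
        [["P", "P"], ["A", "P"], ["P", "A"]],
        index=intensity.index,
        columns=intensity.columns,
    )
    return ExpressionMatrix(intensity, calls)


@pytest.fixture(scope="session")
def strong_study():
    """One simulated study under the documented strong-signal conditions."""
    config = SimulationConfig(seed=7)
    matrix, design, probe_map, truth = generate_study(config)
    collection, set_truth = generate_signed_gene_sets(truth, config)
    return SimpleNamespace(
        config=config,
        matrix=matrix,
        design=design,
        probe_map=probe_map,
        truth=truth,
        collection=collection,
        set_truth=set_truth,
    )


@pytest.fixture(scope="session")
def ranked10():
    """Tiny ranked universe: gene g_i holds rank i in 1..10."""
    from regks.enrichment import RankedProfile

    return RankedProfile(
        pd.Series(np.arange(1, 11), index=[f"g{i}" for i in range(1, 11)])
    )
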