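import numpy as np
import pandas as pd
import pytest

from gfabric import ExpressionTensor, SynthConfig, generate_experiment, ingest_spot_table


def make_tensor(values: dict, region: str = "hippocampus", phenotype: str = "MRL_lpr",
                replicas: int = 4) -> ExpressionTensor:
    """Build a tensor directly from {gene: {spot: [per-replica values]}}."""
    rows, index = [], []
    for gene, spots in values.items():
        for spot, vals in spots.items():
            rows.append(list(map(float, vals)))
            index.append((gene, spot))
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "spot_id"]),
        columns=[f"r{i + 1}" for i in range(replicas)],
    )
    return ExpressionTensor(region, phenotype, frame)


@pytest.fixture(scope="session")
def small_experiment():
    """A clean 100-gene experiment (no corrupted/low spots) plus its tensors."""
    cfg = SynthConfig(
        n_genes=100,
        frac_corrupted_spots=0.0,
        frac_low_signal_spots=0.0,
        seed=11,
    )
    table, truth = generate_experiment(cfg)
    tensors, report = ingest_spot_table(table)
    return cfg, table, truth, tensors, report


@pytest.fixture()
def simple_tensor():
    """One gene, one spot, replicas (8, 10, 10, 12): the REV worked example."""
    return make_tensor({"gA": {"s1": [8, 10, 10, 12]}})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
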