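import numpy as np
import pandas as pd
import pytest

from hilex.io import CountMatrix
from hilex.model import HilExpressionModel
from hilex.simulate import SimConfig, null_config, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """Moderate-size run at the generator's default study conditions."""
    return simulate_experiment(SimConfig(n_genes=3000, seed=7))


@pytest.fixture(scope="session")
def fitted(default_experiment):
    exp = default_experiment
    model = HilExpressionModel(
        exp["refB"], exp["refN"], exp["samples"], exp["annotation"], exp["orthologs"]
    )
    return model.fit()


@pytest.fixture(scope="session")
def recovery_experiment():
    """Strong-effect, low-noise, 5-replicate run used for category recovery."""
    return simulate_experiment(
        SimConfig(
            n_genes=4000,
            effect_size=3.0,
            alpha_range=(0.02, 0.02),
            n_replicates=5,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def recovery_fit(recovery_experiment):
    exp = recovery_experiment
    return HilExpressionModel(
        exp["refB"], exp["refN"], exp["samples"], exp["annotation"], exp["orthologs"]
    ).fit()


@pytest.fixture(scope="session")
def null_experiment():
    """No-divergence run: every architecture collapses to equal means."""
    return simulate_experiment(null_config(seed=11, n_genes=5000))


@pytest.fixture(scope="session")
def null_fit(null_experiment):
    exp = null_experiment
    return HilExpressionModel(
        exp["refB"], exp["refN"], exp["samples"], exp["annotation"], exp["orthologs"]
    ).fit()


def toy_matrix(values, reference_tag="refN", genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        reference_tag,
    )
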