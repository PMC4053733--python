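import numpy as np
import pandas as pd
import pytest

import comethnet as cn


@pytest.fixture(scope="session")
def small_design():
    """Reduced study layout for fast unit tests: 4 datasets x 40 samples
    x 400 probes with the same planted-module kinds as the default."""
    return cn.default_design(
        seed=11,
        n_probes=400,
        n_samples_per_dataset=[40, 40, 40, 40],
        planted_modules=[
            cn.PlantedModule("aging", 60, "consensus_aging", effect_size=0.7),
            cn.PlantedModule("sexX", 40, "sex_X", effect_size=0.9),
            cn.PlantedModule("ds1only", 40, "dataset_specific", home_dataset=0),
        ],
    )


@pytest.fixture(scope="session")
def small_datasets(small_design):
    pairs = cn.generate_consensus_datasets(small_design)
    betas = {n: b for n, (b, _) in zip(small_design.dataset_names, pairs)}
    samples = {n: s for n, (_, s) in zip(small_design.dataset_names, pairs)}
    return betas, samples


@pytest.fixture(scope="session")
def small_run(small_design, small_datasets):
    betas, samples = small_datasets
    return cn.run_consensus(betas, samples, run_qc=False)


def rank1_beta(n_probes=5, n_samples=20, seed=3):
    """Module whose probes are shifted copies of one common profile."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.2, 0.8, size=n_samples)
    rows = [np.clip(v + 0.01 * k, 0, 1) for k in range(n_probes)]
    return pd.DataFrame(
        rows,
        index=[f"p{k}" for k in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
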