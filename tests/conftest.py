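import numpy as np
import pandas as pd
import pytest

from nitrosig import simulate
from nitrosig.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated study shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=400,
        frac_g_effect=0.1,
        frac_e_effect=0.1,
        frac_gei_effect=0.05,
        frac_nitrogen_responsive=0.05,
        missing_rate=0.02,
        seed=11,
    )
    matrix, design, truth = simulate.generate_expression(cfg)
    return cfg, matrix, design, truth


def balanced_design(strains=3, times=3, reps=2, regime="LN"):
    """Replicate-level design frame for hand-built matrices."""
    rows = []
    for s in range(strains):
        for t in range(times):
            for r in range(reps):
                rows.append(
                    {
                        "sample_id": f"s{s}_t{t}_r{r}",
                        "strain": f"S{s}",
                        "regime": regime,
                        "time_h": 12 * (t + 1),
                        "replicate": r + 1,
                    }
                )
    return pd.DataFrame(rows)


def random_matrix(rng, n_genes, design, scale="log2", loc=8.0, sd=1.0):
    vals = rng.normal(loc, sd, (n_genes, len(design)))
    mat = pd.DataFrame(
        vals,
        index=pd.Index([f"gene_{i:05d}" for i in range(n_genes)], name="gene_id"),
        columns=design["sample_id"].to_list(),
    )
    mat.attrs["scale"] = scale
    return mat


@pytest.fixture
def rng():
    return np.random.default_rng(20259)
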