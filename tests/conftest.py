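import numpy as np
import pandas as pd
import pytest

from refstab import CtTable, SimulationSpec, ct_to_quantity


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_ct():
    """Factory: seeded random CT table with independent per-gene noise."""

    def make(k=5, n=8, seed=0, sds=None, baselines=None, loading_sd=0.0):
        r = np.random.default_rng(seed)
        sds = np.asarray(sds if sds is not None else r.uniform(0.2, 1.0, k))
        baselines = np.asarray(
            baselines if baselines is not None else r.uniform(18, 32, k)
        )
        ct = (
            baselines[:, None]
            + r.normal(0.0, 1.0, (k, n)) * sds[:, None]
            + r.normal(0.0, loading_sd, n)[None, :]
        )
        return CtTable(
            pd.DataFrame(
                ct,
                index=[f"g{i}" for i in range(k)],
                columns=[f"s{j}" for j in range(n)],
            )
        )

    return make


@pytest.fixture
def random_quantities(random_ct):
    """Factory: base-2 min-referenced quantity table from a random CT table."""

    def make(k=5, n=8, seed=0, **kw):
        return ct_to_quantity(random_ct(k=k, n=n, seed=seed, **kw))

    return make


@pytest.fixture
def small_sim_spec():
    """8-gene, single-tissue spec with 2 designated stable genes."""

    def make(seed=0):
        genes = [f"g{i}" for i in range(8)]
        noise = {
            "g0": 0.15, "g1": 0.15, "g2": 0.5, "g3": 0.73,
            "g4": 0.97, "g5": 1.2, "g6": 0.3, "g7": 0.3,
        }
        bias = {
            "g6": {"stress=cold": 1.0},
            "g7": {
                "stress=drought&timepoint_h=12": 1.0,
                "stress=drought&timepoint_h=24": 1.0,
            },
        }
        return SimulationSpec(
            gene_ids=genes,
            baseline_ct={g: 20.0 + 1.5 * i for i, g in enumerate(genes)},
            noise_sd=noise,
            loading_sd=0.3,
            condition_bias=bias,
            tissues=["leaf"],
            n_replicates=2,
            seed=seed,
        )

    return make
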