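import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import capconcord as cc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """A desk-scale world with the default error rates and artifacts."""
    cfg = cc.SimConfig(
        n_autosomal_sites=3000, n_x_nonpar_sites=400, n_par_sites=20, seed=42
    )
    truth, arr, seq = cc.simulate_platforms(cfg)
    return cfg, truth, arr, seq


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-error, artifact-free, constant-depth world: platforms == truth."""
    cfg = cc.SimConfig(
        n_autosomal_sites=1500, n_x_nonpar_sites=300, n_par_sites=20, seed=7
    ).clean()
    truth, arr, seq = cc.simulate_platforms(cfg)
    return cfg, truth, arr, seq


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, default_sim):
    """The default world written out as its file bundle."""
    cfg, truth, arr, seq = default_sim
    outdir = tmp_path_factory.mktemp("simfiles")
    paths = cc.write_simulation(truth, arr, seq, outdir)
    return paths


def make_matrix(calls, chrom="1", start_pos=100, samples=None):
    """Small GenotypeMatrix helper: calls is (samples x sites) array-like."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    samples = samples or [f"s{i}" for i in range(m)]
    import pandas as pd

    sites = pd.DataFrame(
        {
            "snp_id": [f"m{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos": np.arange(start_pos, start_pos + n),
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )
    return cc.GenotypeMatrix(samples=samples, sites=sites, calls=calls)
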