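import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150611)


@pytest.fixture
def default_cfg():
    from sh3spot.synthetic_data import GeneratorConfig

    return GeneratorConfig(seed=0)


@pytest.fixture
def small_panel():
    """A quiet 3-class panel: 12 domains, strong gain, little noise."""
    from sh3spot import normalize
    from sh3spot import synthetic_data as sd

    cfg = sd.GeneratorConfig(
        seed=42,
        n_peptides=60,
        n_families=3,
        replicate_noise_sd=0.1,
        membrane_offset_sd=0.2,
        profile_drift_sd=0.0,
    )
    lib, truth = sd.generate_library(cfg)
    expt = sd.generate_spot_experiment(lib, truth, cfg)
    panel = normalize.normalize_experiment(expt, truth.metadata_frame())
    return cfg, lib, truth, panel


def make_experiment(values: dict, probes=None):
    """Hand-build a SpotExperiment from {(domain, replicate): vector}."""
    from sh3spot.normalize import PeptideLibrary, SpotExperiment

    n = len(next(iter(values.values())))
    if probes is None:
        probes = PeptideLibrary(
            pd.Series({f"p{i:03d}": "ARNDEQGHILKMFPS" for i in range(n)})
        )
    df = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in values.items()},
        index=probes.probe_ids,
    )
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["domain", "replicate"])
    return SpotExperiment(probes, df)
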