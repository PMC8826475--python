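import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from evaphysio import ScenarioConfig, generate_campaign, ingest_manifest
from evaphysio.aggregation import aggregate

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def tiny_config(**overrides) -> ScenarioConfig:
    """Two participants, short EVAs: a campaign that generates in well under
    a second but exercises multi-deployment pooling."""
    kwargs = dict(
        n_participants=2,
        deployments_per_participant=(("ID", "HI1"), ("HI1",)),
        evas_per_deployment=1,
        seed=7,
        label_jitter_s=0.0,
        hrv_warmup_s=120,
        dropout_rate=0.05,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def campaign(tmp_path_factory):
    """A small generated campaign on disk plus its ground truth."""
    out = tmp_path_factory.mktemp("campaign")
    config = tiny_config()
    manifest, truth = generate_campaign(config, out)
    return {"config": config, "dir": out, "manifest": manifest, "truth": truth}


@pytest.fixture(scope="session")
def labeled(campaign) -> pd.DataFrame:
    return ingest_manifest(campaign["dir"] / "manifest.csv", 50.0)


@pytest.fixture(scope="session")
def means(labeled) -> pd.DataFrame:
    return aggregate(labeled)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
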