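import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from prolatent.config import validate_config
from prolatent.jtae import JTAEConfig
from prolatent.synthetic import make_family_spec, sample_family

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_jtae_config() -> JTAEConfig:
    """Smallest architecture that still exercises every component."""
    return JTAEConfig(embed_dim=8, model_dim=16, n_heads=2, n_layers=1,
                      latent_dim=8, decoder_layers=2, decoder_channels=8,
                      decoder_hidden=16, regressor_hidden=8)


@pytest.fixture(scope="session")
def family_spec():
    return make_family_spec(seed=11)


@pytest.fixture(scope="session")
def family_dataset(family_spec):
    return sample_family(family_spec, 300, seed=11)


@pytest.fixture(scope="session")
def desk_run():
    return validate_config({"profile": "desk"})


@pytest.fixture(scope="session")
def trained_desk(desk_run, family_spec):
    """The full desk-scale study: train once per session, share everywhere.

    Study conditions: synthetic mutational-scanning-like family, L=30,
    n=2000, 8 fitness bins, fixed seed.
    """
    import prolatent as pl
    from prolatent.seqdata import train_val_split

    dataset = sample_family(family_spec, 2000, seed=11)
    train_set, val_set = train_val_split(dataset, 0.1, seed=11)
    cfg = dataclasses.replace(desk_run.train, seed=11, val_fraction=0.0)
    ckpt = pl.train(train_set, desk_run.jtae, desk_run.diffusion, cfg)
    return {"ckpt": ckpt, "spec": family_spec, "train": train_set,
            "val": val_set, "dataset": dataset}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
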