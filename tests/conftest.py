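"""Shared expensive fixtures: trained networks and fitted ensembles.

Everything is generated programmatically at session start with fixed
seeds; the trained network and its latent-circuit ensemble are shared by
the acceptance tests to keep the suite within a desk-scale budget.
"""

import numpy as np
import pytest

from latentcircuit import rnn, task
from latentcircuit.circuit import FitConfig, fit_ensemble

TRAIN_SEED = 11
TRAIN_EPOCHS = 700
EXTRA_EPOCHS = 600
FIT_EPOCHS = 400
N_INITS = 12
TOP_K = 10


@pytest.fixture(scope="session")
def trained_rnn():
    """A 50-unit network trained on the context-dependent task."""
    p = rnn.init_rnn(50, seed=TRAIN_SEED)
    cfg = rnn.TrainConfig(
        seed=TRAIN_SEED, max_epochs=TRAIN_EPOCHS, improvement=1e-9, patience=10**9
    )
    p, trace = rnn.train_rnn(p, cfg)
    return p


@pytest.fixture(scope="session")
def rnn_responses(trained_rnn):
    """Trial batch, responses and outputs used for latent circuit fitting."""
    p = trained_rnn
    batch = task.make_batch(task.enumerate_conditions(), 8, seed=42, alpha=p.alpha)
    y = rnn.simulate_rnn(p, batch, seed=43)
    z = rnn.outputs(p, y)
    return batch, y, z


@pytest.fixture(scope="session")
def latent_ensemble(trained_rnn, rnn_responses):
    """Top fits from an ensemble of latent circuits on the trained network."""
    p = trained_rnn
    batch, y, z = rnn_responses
    cfg = FitConfig(
        seed=5, max_epochs=FIT_EPOCHS, lr_min=1e-3, patience=10**9, improvement=1e-12
    )
    return fit_ensemble(
        y, z, batch, n_inits=N_INITS, top_k=TOP_K, cfg=cfg,
        alpha=p.alpha, sigma_rec=p.sigma_rec,
    )


@pytest.fixture(scope="session")
def extra_rnns():
    """Two further independently initialized trained networks."""
    nets = []
    for seed in (21, 31):
        p = rnn.init_rnn(50, seed=seed)
        cfg = rnn.TrainConfig(
            seed=seed, max_epochs=EXTRA_EPOCHS, improvement=1e-9, patience=10**9
        )
        p, _ = rnn.train_rnn(p, cfg)
        nets.append(p)
    return nets
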