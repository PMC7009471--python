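"""Shared fixtures: one small synthetic session reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from burstdecode import preprocess as pp
from burstdecode import synthdata as sd


@pytest.fixture(scope="session")
def small_session():
    """A compact fixed-limb session: 6 trials/class, 60 s rest."""
    cfg = sd.GeneratorConfig(seed=11, n_trials_per_class=6, rest_duration=60.0)
    rec, events, gt = sd.generate_session(cfg)
    return cfg, rec, events, gt


@pytest.fixture(scope="session")
def conditioned_small(small_session):
    cfg, rec, events, gt = small_session
    return cfg, pp.condition_signal(rec), events, gt


def make_trialset(epochs, fs=2048.0, pre_s=1.0, post_s=1.0, pad_s=0.5,
                  baseline=(-0.9, -0.4)):
    """Wrap a raw (n_ep, n_ch, n_t) array as a TrialSet for TF tests."""
    epochs = np.asarray(epochs)
    return pp.TrialSet(
        epochs=epochs, fs=fs,
        contact_labels=[f"c{i + 2}" for i in range(epochs.shape[1])],
        pre_s=pre_s, post_s=post_s, pad_s=pad_s,
        meta=pd.DataFrame({"trial": np.arange(epochs.shape[0]),
                           "limb": [""] * epochs.shape[0]}),
        baseline=baseline,
    )
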