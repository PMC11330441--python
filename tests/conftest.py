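import numpy as np
import pytest

from ehrsynth.generator import GenConfig, Synthesizer
from ehrsynth.preprocess import consolidate, select_cohort, split_T_H
from ehrsynth.sim import SimConfig, generate_cohort

CENSOR = "2021-07-31"


@pytest.fixture(scope="session")
def small_cohort():
    """Clean 400-patient simulated cohort (no injected inconsistencies)."""
    return generate_cohort(SimConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return consolidate(select_cohort(small_cohort).cohort, censor_date=CENSOR)


@pytest.fixture(scope="session")
def medium_dataset():
    """Larger cohort for classifier / survival metrics (1200 patients)."""
    cohort = generate_cohort(SimConfig(n_patients=1200, seed=21))
    return consolidate(select_cohort(cohort).cohort, censor_date=CENSOR)


@pytest.fixture(scope="session")
def split_medium(medium_dataset):
    return split_T_H(medium_dataset, 0.6, seed=5)


@pytest.fixture(scope="session")
def trained_synth(small_dataset):
    """Reduced-scale trained generator shared across generator/fidelity tests."""
    cfg = GenConfig(
        latent_dim=16,
        hidden_dim=96,
        ae_epochs=120,
        gan_epochs=20,
        batch_size=64,
        seed=0,
    )
    return Synthesizer(cfg).fit(small_dataset)


@pytest.fixture(scope="session")
def synth_sample(trained_synth):
    return trained_synth.sample(400, seed=11)


def toy_dataset(n=20, seed=0, n_events=3):
    """Tiny hand-inspectable dataset used by metric unit tests."""
    cohort = generate_cohort(SimConfig(n_patients=n, seed=seed, max_events_per_patient=n_events))
    return consolidate(select_cohort(cohort).cohort, censor_date=CENSOR)
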