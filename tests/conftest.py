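import numpy as np
import pytest

import preictal as p


@pytest.fixture(scope="session")
def planted_templates():
    rng = np.random.default_rng(11)
    return p.make_templates(19, 4, rng=rng)


@pytest.fixture(scope="session")
def clean_recording(planted_templates):
    """2 minutes of noiseless, background-free synthetic EEG with known labels."""
    spec = p.SyntheticSpec(seed=11, snr_db=np.inf, oscillations=(),
                           templates=planted_templates)
    labels, _ = p.simulate_sequence(spec, 120.0)
    rec = p.render_eeg(labels, spec)
    return rec, labels, spec


@pytest.fixture(scope="session")
def noisy_recording(planted_templates):
    """2 minutes at 20 dB SNR, no oscillatory background."""
    spec = p.SyntheticSpec(seed=12, snr_db=20.0, oscillations=(),
                           templates=planted_templates)
    labels, _ = p.simulate_sequence(spec, 120.0)
    rec = p.render_eeg(labels, spec)
    return rec, labels, spec


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 30/30-epoch two-class dataset with strong planted effects."""
    spec = p.SyntheticSpec(seed=21, class_effects=p.strong_effects())
    return p.generate_dataset(spec, 30)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    epochs, _truth = small_dataset
    templates = p.fit_templates_from_epochs(epochs, k=4, max_maps=2000,
                                            random_state=0)
    return p.extract_features(epochs, templates), templates
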