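import numpy as np
import pandas as pd
import pytest

from trialcv import FeatureTable, SessionConfig, gain_profile


@pytest.fixture
def tiny_config():
    """1 min/class of 5-s trials, 2 channels: 12 trials/class, 24 epochs."""
    return SessionConfig(
        minutes_per_class=1.0,
        trial_duration_s=5.0,
        n_channels=2,
        class_gain=gain_profile(0.3, 2),
        trial_gain_sd=0.3,
    )


def make_table(
    n_trials_per_class: int = 4,
    epochs_per_trial: int = 3,
    n_features: int = 4,
    separation: float = 0.0,
    trial_effect: float = 0.0,
    seed: int = 0,
) -> FeatureTable:
    """Small synthetic feature table with optional class and trial effects."""
    rng = np.random.default_rng(seed)
    rows = []
    feats = []
    for c in (0, 1):
        for t in range(n_trials_per_class):
            trial_id = f"c{c}t{t:02d}"
            shift = trial_effect * rng.standard_normal(n_features)
            for e in range(epochs_per_trial):
                rows.append(
                    {
                        "sample_id": f"{trial_id}e{e}",
                        "trial_id": trial_id,
                        "class_label": c,
                        "epoch_index": e,
                    }
                )
                feats.append(rng.standard_normal(n_features) + separation * c + shift)
    names = [f"f{j}" for j in range(n_features)]
    frame = pd.concat([pd.DataFrame(rows), pd.DataFrame(feats, columns=names)], axis=1)
    return FeatureTable(frame, names)


@pytest.fixture
def toy_table():
    return make_table()
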