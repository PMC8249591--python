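import numpy as np
import pytest

from periphnn.architecture import desk_scale_specs
from periphnn.datasets import build_training_set
from periphnn.reference import IHCTeacher
from periphnn.stimuli import speech_like_corpus
from periphnn.training import TrainConfig, train_surrogate

#: CFs used for desk-scale IHC training and evaluation.
TRAIN_CFS = np.array([250.0, 1000.0, 2000.0])


@pytest.fixture(scope="session")
def ihc_teacher():
    return IHCTeacher(TRAIN_CFS)


@pytest.fixture(scope="session")
def desk_ihc_spec():
    return desk_scale_specs()["ihc_small"]


@pytest.fixture(scope="session")
def desk_window_set(ihc_teacher, desk_ihc_spec):
    """Training windows from the seeded synthetic corpus through the IHC chain."""
    corpus = speech_like_corpus(4, 0.25, seed=42)
    return build_training_set(corpus, ihc_teacher, desk_ihc_spec, "ihc", seed=42)


@pytest.fixture(scope="session")
def trained_ihc(ihc_teacher, desk_ihc_spec, desk_window_set):
    """Desk-scale IHC surrogate trained against the analytical stand-in.

    Shared session-wide: surrogate-recovery, windowing-consistency and
    stimulus-restoration tests all reuse this one training run.
    """
    config = TrainConfig(learning_rate=2e-3, epochs=60, batch_size=16, seed=1,
                         patience=60)
    model, history = train_surrogate(desk_ihc_spec, desk_window_set, config)
    return model, history
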