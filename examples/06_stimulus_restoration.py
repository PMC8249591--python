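"""Backprop application: restore a deafferented periphery's output.

A normal periphery (surrogate output x10 fibers) is compared with a
pathological one (x8 fibers, 20% deafferentation).  Because the surrogate is
differentiable, a small preprocessor network can be trained by
backpropagating through the frozen pathological model so that its processed
input reproduces the normal model's output (L1 in time + magnitude spectrum).
"""

import numpy as np

from periphnn.architecture import desk_scale_specs
from periphnn.datasets import build_training_set
from periphnn.reference import IHCTeacher
from periphnn.stimuli import sam_tone, speech_like_corpus
from periphnn.training import (TrainConfig, PopulationModel,
                               optimize_stimulus_preprocessor, train_surrogate)

spec = desk_scale_specs()["ihc_small"]
teacher = IHCTeacher(np.array([1000.0, 4000.0]))
corpus = speech_like_corpus(4, 0.25, seed=42)
windows = build_training_set(corpus, teacher, spec, "ihc", seed=42)
net, _ = train_surrogate(spec, windows,
                         TrainConfig(learning_rate=2e-3, epochs=30, batch_size=16,
                                     seed=1, patience=30))

rng = np.random.default_rng(0)
fs = 20e3
tones = []
for _ in range(8):
    s = sam_tone(4e3, 100.0, rng.uniform(0.3, 1.0), rng.uniform(55, 75),
                 spec.L_c / fs, fs)
    x = s.samples[: spec.L_c]
    tones.append(0.5 * x / np.max(np.abs(x)))

normal = PopulationModel(net, 10)       # 10 innervating fibers
pathological = PopulationModel(net, 8)  # 20% deafferentation
pre, report = optimize_stimulus_preprocessor(
    normal, pathological, np.stack(tones),
    TrainConfig(learning_rate=1e-3, epochs=40, batch_size=4, seed=0))
print(f"unprocessed-input loss: {report['baseline_loss']:.4f}")
print(f"after preprocessor training: {report['final_loss']:.4f}")
print("the preprocessor reshapes the stimulus so the 8-fiber periphery's"
      " response approaches the 10-fiber response.")
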