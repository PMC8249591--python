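# periphnn

Convolutional encoder–decoder surrogates of auditory-periphery neuron and
synapse models — inner-hair-cell (IHC) transduction, the auditory-nerve-fiber
(ANF) synapse, and the classic Hodgkin–Huxley axon — with the stimulus
generators, dataset conventions, training loop and experimental-neuroscience
evaluation suite needed to build and validate them end to end.

Mechanistic descriptions of sensory cells are coupled nonlinear ODEs: slow to
solve and not differentiable, which blocks their use inside larger trainable
systems (hearing-aid signal paths, brainstem back-ends, closed-loop
experiments).  The approach here replaces each stage with a convolutional
encoder–decoder trained on the analytical model's own simulations.  The
surrogate is fast, fully convolutional (any input length, any number of
cochlear channels), and differentiable — so one can backpropagate *through
the ear*, e.g. to find a stimulus transformation that restores a damaged
periphery's output.  The package is aimed at auditory modellers and
neural-network researchers who want a desk-scale, fully inspectable version
of this workflow.

## The core ideas

**Architecture.** A surrogate maps `L_c = L_l + L + L_r` input samples
(window `L` plus left/right context) through `N` stride-2 convolutions to a
bottleneck and back through `N` stride-2 transposed convolutions, with skip
connections concatenating encoder outputs onto the decoder and a final
context-cropping layer.  The trainable-parameter count is available in
closed form and reproduces the published full-scale architectures exactly
(IHC 1,317,505; ANF 1,248,449 / 1,250,177; merged complex 5,066,308).

**Receptive-field design rule.** One bottleneck unit sees
`r_N = (k−1)(2^N − 1) + 1` input samples (kernel `k`, stride 2).  A
surrogate can only capture adaptation shorter than its receptive field, so
the teacher's adaptation time sets the minimal encoder depth: a synapse
whose firing rate needs a 16,384-sample window demands 12 encoder layers at
`k = 8`, while a 750-sample adaptation needs 6 layers at `k = 16` or 3 at
`k = 128`.

**Teachers.** Bundled analytical stand-ins provide the training signal: a
tonotopic cochlear filterbank with compressive tip and level-dominant tail
(basal-ward excitation shift), a Boltzmann-plus-low-pass IHC stage (AC/DC
decline above ~700 Hz), a three-store diffusion synapse (spontaneous rates
68.5/10/1 spikes/s, onset adaptation, slow recovery), and the standard
Hodgkin–Huxley squid axon.  See `docs/methods.md` for every equation and
constant.

**Evaluation.** Six metrics shared by teachers and surrogates: excitation
patterns, AC/DC ratio, potential-level growth, firing-rate traces,
rate-level curves, and synchrony-level curves (vector strength
`|F(f_m)|/|F(0)|`), plus RMSE in the units of the compared quantity.

## Worked example

`examples/04_train_ihc_surrogate.py` trains a reduced IHC surrogate (window
512, contexts 64, 6 layers, 32 filters) against the analytical chain on a
seeded 70/130-dB speech-like corpus, then probes it with held-out tones:

```
full-scale ihc: 1,317,505 trainable parameters
full-scale anf_h: 1,250,177 trainable parameters
full-scale anf_m: 1,250,177 trainable parameters
full-scale anf_l: 1,248,449 trainable parameters
desk-scale spec: L_c=640, 6 layers, 83,617 parameters
training windows: 216 of 640 samples
trained 60 epochs; best validation L1 = 0.0097 (scaled units)
held-out 80-dB tone at 250 Hz: relative RMSE 2.94%
held-out 80-dB tone at 1000 Hz: relative RMSE 3.02%
held-out 80-dB tone at 2000 Hz: relative RMSE 2.97%
teacher AC/DC: [3.898 2.222 1.256]
surrogate AC/DC: [3.737 2.77  2.028]
```

The surrogate reproduces held-out receptor potentials within ~3% relative
RMSE and inherits the teacher's declining AC/DC ratio — the signature of the
IHC membrane low-pass — on stimuli it never saw in training.  The other
examples cover calibrated stimulus generation (`01`), the receptive-field
design table (`02`, also `periphnn design --adaptation-ms 37.5`), the
teacher models (`03`), the metric suite (`05`), and backprop stimulus
restoration for a 20%-deafferented periphery (`06`).

A thin CLI wraps the same library calls:
`periphnn design | dataset | train | evaluate | demo-backprop`.

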