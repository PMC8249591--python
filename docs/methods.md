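# Methods

`periphnn` converts analytical models of the auditory periphery — and, as a
structural demonstration, the classic squid-axon membrane model — into
trainable convolutional encoder–decoder surrogates, and evaluates both the
analytical "teachers" and the trained surrogates with a common suite of
experimental-neuroscience metrics.  This note records the models, the
conventions, and the design decisions, in enough detail to re-derive every
constant in the code.

## 1. Surrogate architecture

Each surrogate maps an input window of `L_c = L_l + L + L_r` samples (output
window `L`, left/right context `L_l`/`L_r`) to an output window of the same
length, after which the context is cropped.  The encoder is `N = n_total/2`
one-dimensional convolutions with stride 2 (halving time per layer, so `L_c`
must be divisible by `2^N`); the decoder is `N` transposed convolutions with
stride 2 (doubling time per layer).  Convolutions use "same"-style zero
padding of `k - 2` samples (split evenly) so the length relations are exact;
a transposed convolution is defined as the exact linear adjoint of the
corresponding strided convolution, which makes the backward pass of each the
forward pass of the other and is verified by an inner-product identity in the
tests.

Skip connections concatenate encoder outputs (post-activation) onto decoder
inputs at matching temporal resolution: decoder layer 1 takes the bottleneck
alone (`F -> F` channels), decoder layers `2..N-1` take
`concat(previous decoder, encoder N-j+1)` (`2F -> F`), and the final decoder
layer takes a skip as well and maps `2F -> out_channels` with **no**
activation.  Every conv layer has a bias; PReLU activations carry one
learnable slope per filter channel, shared over time.  This wiring is pinned
down by the closed-form trainable-parameter count

```
encoder: (k·1·F + F) + (N−1)(k·F² + F)
decoder: (k·F² + F) + (N−2)(k·2F·F + F) + (k·2F·out + out)
PReLU:   +F per activated layer using PReLU  (2N−1 layers when both sides use it)
```

which reproduces the published counts of the full-scale presets exactly
(IHC 1,317,505; low-SR ANF 1,248,449; high/medium-SR ANF 1,250,177 with
27·64 = 1,728 PReLU slopes; merged complex 5,066,308) and equals
built-network introspection for arbitrary valid specs.  Whether skips are
taken pre- or post-activation cannot be distinguished by parameter counts;
post-activation was chosen.

The receptive field of one bottleneck unit is
`r_N = Σ_{n=1..N} (k−1)·s^(n−1) + 1`, i.e. `(k−1)(2^N−1)+1` for stride 2.
`min_encoder_layers` returns the smallest `N` with `r_N` **strictly** greater
than the target window ("larger than" read as strict inequality: 11 layers
give 14,330 ≤ 16,384 while 12 give 28,666).  `advise_architecture` turns an
adaptation time `t` into a target `ceil(t·fs)` samples and recommends, per
kernel, the minimal depth plus the smallest window `L` divisible by `2^N`
that covers the target.  A brute-force autodiff oracle (gradient support of a
bottleneck unit w.r.t. the input) equals the closed form for `N ≤ 4`.

The conv engine itself (`periphnn.nn`) is a deliberately small float64 numpy
implementation — strided conv, its adjoint, tanh/sigmoid/PReLU, Adam — with
analytic gradients checked against finite differences.  Weight
initialisation is uniform with fan-in scaling, seeded.

## 2. Analytical teacher models

The teachers are documented desk-scale stand-ins for the cochlear, IHC and
ANF stages, plus the standard Hodgkin–Huxley axon.  They are this package's
own models: simple enough to audit, rich enough to exhibit the response
repertoire the surrogates must learn.  All are integrated deterministically
at `SOLVE_FS = 100 kHz` and their outputs downsampled to the
`MODEL_FS = 20 kHz` working rate.

### 2.1 Cochlear drive (`CochlearStandin`)

Each characteristic-frequency (CF) channel maps sound pressure [Pa] to a
displacement-like drive [m] through two pathways:

* **tip**: a 2nd-order Butterworth band-pass at CF (edges `CF·2^{±1/6}`),
  gain `g_tip = 3.5e-6 m/Pa`, followed by a broken-stick compressor
  (linear below `knee = 1e-8 m`, exponent 0.3 above);
* **tail**: a 2nd-order band-pass half an octave *below* CF (edges
  `2^{±0.45}` about the centre), gain `g_tail = 2e-7 m/Pa`, with a later,
  gentler compressor (knee `1e-7 m`, exponent 0.5).

At low levels the compressive tip dominates, so a tone excites the channel
whose CF matches it; at high levels the tail overtakes, so the excitation
maximum moves to channels about half an octave *above* the tone frequency
(basal-ward), as in mammalian cochleae.  The two compressors also keep drive
amplitudes of order 1 µm at 130 dB SPL, which after the ×10⁶ training scaling
gives network inputs of order one.

### 2.2 IHC transduction (`IHCStandin`)

Mechano-electrical transduction is an asymmetric Boltzmann conductance
followed by a first-order membrane low-pass:

```
g(u)  = G_max · [ σ((u − u0)/s_u) − σ(−u0/s_u) ]      σ = logistic
V(t)  = V_rest + LP1[g(u)](t)                          (one-pole, f_c = 650 Hz)
```

with `V_rest = −57 mV`, `G_max = 60 mV`, `u0 = 50 nm`, `s_u = 40 nm`.  The
offset `u0` makes depolarisation dominate, producing the DC receptor
potential; the 650-Hz pole makes the AC/DC ratio decline for stimulus
frequencies above ~600–700 Hz and removes fine structure by 4 kHz (the loss
of phase-locking the ANF metrics probe).  The stage is memoryless apart from
the pole, so its own adaptation time is negligible — by design, the slow
adaptation in the chain belongs to the synapse.

### 2.3 ANF synapse (`ANFStandin`)

A three-store transmitter model.  Release is driven by a Boltzmann function
of the receptor potential, `k(V) = k_max / (1 + exp(−(V − V_half)/s_v))`
[1/s].  The immediate store `q` (capacity `q_max = 1`) releases at `k(V)·q`
and is refilled from a reservoir `w` at `x·w·(1 − q/q_max)` — gated by free
capacity, so the steady-state driven rate saturates in `k` like a
Michaelis–Menten law instead of being purely flow-limited (a purely linear
transfer would make the steady rate independent of `k`, i.e. flat rate-level
curves).  The reservoir is refilled from the factory at `y·(w_max − w)` and
receives a recycled fraction `ρ = 0.4` of released transmitter:

```
dq/dt = x·w·(1 − q/q_max) − k(V)·q
dw/dt = y·(w_max − w) − x·w·(1 − q/q_max) + ρ·k(V)·q
rate  = A · k(V) · q
```

Presets (chosen so spontaneous release sits well below the replenishment
ceiling `y·w_max/(1−ρ)`, leaving headroom for driven rates):

| preset | SR target | recovery level | k_max | V_half | s_v | x | y |
|--------|-----------|----------------|-------|--------|-----|---|---|
| hsr | 68.5 /s | 60 dB SPL | 1500 | −45 mV | 2.0 mV | 60 | 10 |
| msr | 10 /s | 65 dB SPL | 2000 | −40 mV | 2.2 mV | 15 | 5 |
| lsr | 1 /s | 75 dB SPL | 3000 | −34 mV | 2.5 mV | 4 | 2 |

The silent steady state `(q_rest, w_rest)` is solved in closed form at
construction (Brent root-finding on the reservoir balance) and the rate
scale `A` set so the silent rate equals the SR target exactly; simulations
start from that steady state, so a silent input holds the spontaneous rate
to machine precision.  Integration is explicit Euler at 100 kHz (the fastest
time constant, `1/(k_max + x)`, is ≥ 0.3 ms, 30 steps per constant), inner
loop numba-compiled with a pure-python fallback; the per-step store budget
closes to better than 1e−8 of the content by construction, which the tests
verify from the recorded trajectories.

The release threshold (`V_half` well above rest) and slope produce the
classic repertoire: sharp saturation with a small dynamic range for the
high-SR preset, sloping/non-saturating growth for the low-SR preset, onset
peaks followed by adaptation (immediate-store depletion, fast) riding on a
slow reservoir drain, and recovery of the onset peak after prior
stimulation with a time constant ≈ `1/y` (0.1 s high-SR … 0.5 s low-SR), so
the onset-recovery curve rises monotonically over interstimulus intervals of
0.1–1.9 s.  `recovery_level_dB` (60/65/75 dB SPL) is the *presentation*
level of the recovery metric — the fiber's threshold plus 40 dB already
applied.

These stand-ins are calibrated to directions, not to any published cochlear
model's numbers; quantities such as the percent-of-steady-state reached at
0.4 s are meaningful here only as orderings between fiber types.

### 2.4 Hodgkin–Huxley axon (`simulate_hh`)

The standard squid-axon description: `C_m dV/dt = I − g_Na m³h(V−E_Na) −
g_K n⁴(V−E_K) − g_L(V−E_L)` with the classic rate functions (resting
potential −65 mV; `g_Na, g_K, g_L = 120, 36, 0.3 mS/cm²`; `E_Na, E_K, E_L =
50, −77, −54.387 mV`).  Integration is fixed-step exponential Euler on both
the gates and the voltage (0.01 ms at the 100-kHz solver rate); a test
cross-checks the spike count against an independent adaptive Runge–Kutta
integration of the same equations.  Step currents of 10 µA/cm² fire
repetitively (~70 Hz); currents ≥ 7.5 µA/cm² sustain a non-decaying train,
while 5 µA/cm² produces only an onset spike.

### 2.5 Adaptation and recovery characterisation

* `estimate_adaptation_time`: steady state is the mean of the final 10% of
  the stimulated segment; the adaptation time runs from the envelope peak to
  the first sample after which the envelope stays within ±5% of steady
  state.  Oscillatory responses (receptor potentials) use the Hilbert
  envelope; rates are used raw, optionally smoothed (strongly phase-locked
  rates ripple).  No peak above the band → 0 with a warning.
* `steady_state_fraction`: the fraction of the onset decay completed by the
  probe time, `(r_peak − r_probe)/(r_peak − r_ref)` on 10-ms-smoothed rates.
  A plain probe/reference ratio is ≥ 1 for a decaying rate and orders the
  fiber types backwards relative to the printed percent-of-steady-state
  figures this quantity mirrors; the decay-completion form is ≤ 1, returns
  1 for a constant rate, is analytic for an exponential, and gives the
  expected fast-to-slow ordering (high-SR closest to 1).

## 3. Stimuli

All acoustic stimuli are pressure waveforms calibrated against
`p0 = 2×10⁻⁵ Pa`.  Pure tones use the closed-form amplitude
`p0·√2·10^{L/20}` (RMS equals the target level analytically) and are ramped
**after** calibration with raised-cosine ("Hanning-shaped") on/off ramps —
no re-normalisation, so a ramped tone's RMS is slightly below nominal.  SAM
tones `[1 + m·cos(2π f_m t + π)]·sin(2π f_c t)` are globally rescaled to the
target RMS after envelope construction, then ramped; the +π modulator phase
puts an envelope zero at onset for full modulation.  Metric-specific ramp
durations: 5 ms (Metrics 1–3), 7.8 ms (SAM, Metrics 4/6), 2.5 ms
(Metric 5).

The synthetic speech-like corpus is seeded pink-weighted noise in 8
log-spaced bands (100 Hz–8 kHz), each band modulated by an independent
2–10 Hz raised-sine envelope, summed and RMS-calibrated — half the items to
70 dB SPL, half to 130 dB SPL (odd counts put the extra item at the lower
level).  It reproduces the broadband, slow-envelope, two-level statistics a
periphery surrogate needs to learn compression and saturation.  It is **not**
speech: no phonetic structure, no harmonic voicing, no sentence-level level
distribution; passing tests therefore demonstrate the pipeline on
speech-*like* statistics, not speech itself.

## 4. Data conventions

* **Resampling** 100 kHz ↔ 20 kHz: polyphase FIR, Kaiser β = 10
  (~100 dB stopband), cutoff at 95% of the narrower Nyquist,
  `128·max(up,down)+1` taps, linear edge extension (so constant resting
  potentials survive without boundary ringing).  Aliased components land
  below −100 dB; passband loss < 0.001 dB.
* **Scaling** into training units: ×10⁶ (BM drive, → µm), ×10 (receptor
  potential, → dV), ×10⁻² (firing rate, → hundreds of spikes/s); inverses
  exact.
* **Windowing**: 50% overlap (`hop = L/2`), left/right context zero-filled
  beyond the signal edges (consistent with responses that start from
  silence); window count `floor((len−L)/hop)+1`; a sequence shorter than `L`
  yields one zero-padded window with a warning.
* **Silence padding** for the ANF stage: 0.5 s before and 1 s after each
  corpus item, applied to the *stimulus before simulation* (the response to
  silence is the spontaneous rate, not zero), so training windows carry
  adaptation and recovery behaviour.  The IHC stage is windowed without
  added silence.
* **CF flattening**: the IHC/ANF stages are assumed CF-independent, so each
  CF channel of each item becomes an independent single-channel training
  sequence (`n_items × n_cf` sequences; 2310 × 201 = 464,310 at full scale).
* **Greenwood CF axis**: CFs uniform in the place coordinate of
  `f(x) = 165.4·(10^{2.1x} − 0.88)` Hz (human constants), endpoints snapped
  to the requested 112 Hz and 12 kHz.

## 5. Training

L1 (mean absolute error) on the cropped output window, Adam (default
learning rate 1e-4; the desk-scale runs use 2e-3, see below), seeded 90/10
train/validation split, early stopping on validation L1 with configurable
patience, best-checkpoint restoration, CSV logging.  Divergence (non-finite
loss) aborts and restores the last finite checkpoint.  Two runs with the
same seed are bitwise identical.

Desk-scale problem sizes (the package's own choice of a size that a single
CPU handles in minutes while leaving the pipeline end-to-end real): the
reduced IHC geometry is `L = 512`, contexts 64/64, 6 layers, 32 filters,
kernel 16 (83,617 parameters); training data are 4 corpus items × 0.25 s ×
3 CFs → 216 windows; 60 epochs at learning rate 2e-3.  This reaches ~3%
relative RMSE on held-out 80-dB tones and reproduces the teacher's AC/DC
decline.  The full-scale presets build and count correctly and can be
trained with the same code.

Windowed inference of a trained model is checked for context sufficiency:
outputs of hop-shifted windows agree on their overlap within 10% of the
output standard deviation (documented tolerance; the desk-scale receptive
field of 106 samples exceeds the 64-sample context, so exact agreement is
not expected).

### Stimulus restoration (backprop application)

`optimize_stimulus_preprocessor` trains a small encoder–decoder preprocessor
`x → x̂` through two *frozen* periphery models: a normal model (surrogate
output × 10 fibers) and a pathological one (× 8 fibers, 20%
deafferentation).  The loss is time-domain L1 plus the L1 between magnitude
spectra of the outputs; the spectral gradient is computed analytically via
the DFT adjoint (`Re(FFT(w·conj(X)/|X|))`) and verified against finite
differences.  "Frequency representation" is the magnitude DFT of the full
output window (no framing).  With identical models the unprocessed baseline
loss is zero and training drives the preprocessor toward the identity; with
the ×10/×8 mismatch the trained preprocessor reduces the loss well below
the unprocessed baseline.

## 6. Evaluation metrics

All metrics are pure functions of (model, stimulus configuration) and apply
identically to teachers and surrogates (any object with
`respond(stimulus) -> ResponseField`).  Stimuli carry leading silence of at
least 20 ms plus the model's left context; windows are measured relative to
stimulus onset.

1. **Excitation patterns**: mean receptor potential re rest per CF for tones
   of 0.5/1/2 kHz at 10–90 dB SPL; the tone fills the evaluation window
   after the leading silence (its duration is otherwise unspecified — a
   documented choice).
2. **AC/DC ratio**: 80-ms, 80-dB tones at the probed CF; AC = RMS of the
   mean-subtracted 50–70-ms steady-state segment, DC = steady-state mean
   minus the resting mean measured 15–5 ms before onset; the "RMS of the AC
   component" convention (amplitude vs RMS is ambiguous) is fixed as the RMS
   of the mean-subtracted steady segment and used identically for both
   models, so ratios remain comparable.  DC = 0 reports NaN.
3. **Potential-level growth**: 4-kHz tones, 0–100 dB; DC here means the
   steady-state mean (not the resting potential); subtract it, keep the
   positive part, RMS over the steady window.
4. **Firing-rate traces**: 70-dB tones and SAM tones at 1 and 4 kHz; the
   1-kHz rate carries fine structure at the stimulus frequency, the 4-kHz
   rate follows the envelope.
5. **Rate-level curves**: 50-ms tones (2.5-ms ramps) at 1007 / 3972.7 Hz,
   0–100 dB; mean rate 10–40 ms after onset.
6. **Synchrony-level curves**: fully modulated 400-ms SAM tones
   (`f_m = 100 Hz`); vector strength `|F(f_m)|/|F(0)|` of the rate, computed
   on the steady-state portion only (from 100 ms after onset, an integer
   number of modulation periods) to avoid onset bias.

`rmse` has the units of the compared quantity; `evaluate_surrogate` runs the
stage-appropriate metrics for one or more (surrogate, teacher) pairs and
returns all curves plus an RMSE table.  A teacher evaluated against itself
scores zero on every metric.

## 7. Known limitations

* The cochlear/IHC/ANF teachers are stand-ins, not re-implementations of any
  published transmission-line or conductance model; published figures tied
  to such models (timing tables, specific percent-recovery values) are out
  of reach and only their qualitative directions are asserted.
* Firing rates are mean rates; no stochastic vesicle release, spike
  generation or PSTHs.
* The full-scale 201-CF, multi-day trainings are supported by the code but
  not exercised; tests and examples run desk-scale reductions.
* Transposed-conv padding and skip wiring follow one consistent convention;
  alternatives (pre-activation skips) would change nothing observable in the
  parameter counts but are not implemented.
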