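"""Receptive-field arithmetic: choose encoder depth from an adaptation time.

A strided convolutional encoder can only capture temporal dependencies within
its receptive field r_N = (k-1)(2^N - 1) + 1 (kernel k, N stride-2 layers).
The adaptation time of the dynamical model to approximate, times the sampling
rate, sets the window the encoder must cover.
"""

from periphnn.rf import advise_architecture, min_encoder_layers, receptive_field

print("Slow synapse adaptation spanning a 16384-sample window (k=8):",
      min_encoder_layers(16384, 8), "encoder layers needed")
print("37.5-ms adaptation at 20 kHz -> 750 samples:")
for row in advise_architecture(37.5e-3, 20e3, [16, 128]):
    print(f"  kernel {row['kernel']:>3}: {row['n_layers']} layers, "
          f"RF {row['rf_samples']} samples ({row['rf_ms']:.1f} ms), "
          f"window L = {row['window_L']}")
rf = receptive_field(3, 16)
print(f"A 3-layer, 16-tap encoder sees only {rf} samples "
      f"({1e3 * rf / 20e3:.1f} ms at 20 kHz) - too short for that synapse.")
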