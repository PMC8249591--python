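"""Generate calibrated tones, SAM tones and the synthetic speech-like corpus.

Every acoustic stimulus is a pressure waveform in pascal calibrated against
p0 = 20 uPa, so "70 dB SPL" means the RMS pressure is 10^3.5 times p0.
"""

import numpy as np

from periphnn.stimuli import pure_tone, sam_tone, speech_like_corpus, spl

tone = pure_tone(1e3, 70.0, duration=0.1, fs=20e3, ramp_dur=0.0)
print(f"1-kHz tone at 70 dB SPL: rms = {np.sqrt(np.mean(tone.samples**2)):.7f} Pa "
      f"(closed form 2e-5*10^3.5 = {2e-5 * 10**3.5:.7f})")

ramped = pure_tone(1e3, 70.0, duration=0.1, fs=20e3, ramp_dur=5e-3)
print(f"with 5-ms raised-cosine ramps: level = {spl(ramped.samples):.3f} dB SPL "
      "(ramping is applied after calibration, so the level drops slightly)")

sam = sam_tone(4e3, fm=100.0, m=1.0, level_dB=70.0, duration=0.4, ramp_dur=0.0)
print(f"fully modulated SAM tone (unramped): level = {spl(sam.samples):.6f} dB SPL "
      "(rescaled to the target after envelope construction)")

corpus = speech_like_corpus(6, dur=0.3, seed=0)
levels = [f"{spl(it.samples):.1f}" for it in corpus]
print(f"speech-like corpus levels (dB SPL): {levels}")
print("half the items are calibrated to 70 dB and half to 130 dB, spanning the"
      " dynamic range a surrogate must learn.")
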