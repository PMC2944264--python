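"""Estimate heart rate from the first derivative of the ECG.

Pulse trains with a programmed number of beats are fed to the
derivative-rectify-smooth-threshold peak picker; the recovered count N_p
should match exactly, and HR = N_p * 60 / L_e converts it to beats per
minute. 24 beats in 8 s (180 bpm) is the shockable-VT border.
"""

from vfseq import SynthSpec, heart_rate, synth

for n_beats in (15, 17, 24, 28):
    rate = n_beats * 60.0 / 8.0
    episode, truth = synth(SynthSpec(kind="pulse_train", rate=rate, seed=3))
    res = heart_rate(episode)
    print(f"programmed {truth.beat_count:2d} beats -> detected N_p = "
          f"{res.np_peaks:2d}, HR = {res.hr:5.1f} bpm "
          f"({'shockable range' if res.hr > 180 else 'below border'})")
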