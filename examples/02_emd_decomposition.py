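"""Decompose a two-tone signal with EMD and inspect the mode split.

A 2 Hz + 20 Hz mixture separates into a fast first IMF (the 20 Hz tone)
and a slow second IMF (the 2 Hz tone); the printed correlations confirm
which oscillation each mode carries, and the reconstruction error shows
the decomposition is complete (IMFs + residue give back the signal).
"""

import numpy as np

from vfseq import emd

fs = 250.0
t = np.arange(int(8 * fs)) / fs
slow = np.sin(2 * np.pi * 2 * t)
fast = 0.8 * np.sin(2 * np.pi * 20 * t)
x = slow + fast

out = emd(x)
interior = slice(len(t) // 10, -len(t) // 10)
print(f"{len(out.imfs)} IMFs extracted, sift counts = {out.sift_counts}")
for i, c in enumerate(out.imfs[:2], start=1):
    r_fast = np.corrcoef(c[interior], fast[interior])[0, 1]
    r_slow = np.corrcoef(c[interior], slow[interior])[0, 1]
    print(f"imf{i}: corr with 20 Hz tone = {r_fast:+.3f}, "
          f"with 2 Hz tone = {r_slow:+.3f}")
err = np.max(np.abs(x - out.reconstruct()))
print(f"max reconstruction error = {err:.2e} (completeness)")
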