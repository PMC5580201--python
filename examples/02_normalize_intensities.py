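"""Normalize a tiny hand-made intensity table and show every step.

For each marker: T = A + B per sample, M = median of T across samples,
normalized value = log2(T / M).  A sample sitting at the median gets 0;
one octave above gets +1.
"""

import numpy as np

from snpscan import RawIntensitySet, normalize_intensities

raw = RawIntensitySet(
    samples=["S1", "S2", "S3"],
    snps=["M1", "M2"],
    a=np.array([[1.0, 2.0, 4.0], [10.0, 10.0, 10.0]]),
    b=np.array([[1.0, 2.0, 4.0], [30.0, 30.0, 30.0]]),
)
norm = normalize_intensities(raw)

for i, marker in enumerate(norm.snps):
    totals = raw.a[i] + raw.b[i]
    print(f"{marker}: T = {totals.tolist()}, M = {norm.reference[i]:g}, "
          f"log2(T/M) = {np.round(norm.value[i], 3).tolist()}")
# M1 doubles sample to sample, so its ratios are (-1, 0, +1); M2 is flat,
# so every ratio is exactly 0.
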