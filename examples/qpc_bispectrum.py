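"""Detect quadratic phase coupling with the block-averaged bispectrum.

Builds single-channel test signals containing cosines at f1, f2 and f1+f2 —
with the third phase either locked to the sum of the first two (coupled) or
drawn independently — and compares bispectrum magnitudes at the bifrequency
(f1, f2).  Averaging over independent segments is what kills the uncoupled
peak: each segment's triple product has a random phase, so the complex mean
cancels, while coupled segments add coherently.
"""

import numpy as np

from bispeeg import Segment, estimate_bispectrum, generate_qpc_segment

FS = 500.0
F1, F2 = 36 * FS / 512, 41 * FS / 512  # on-bin for the 512-point FFT
N_SEGMENTS = 30


def mean_bispectrum_peak(coupled: bool) -> tuple[float, float]:
    acc = None
    for s in range(N_SEGMENTS):
        x = generate_qpc_segment([(F1, F2)], coupled, n_samples=5519, fs=FS,
                                 snr_db=10.0, seed=1000 * coupled + s)
        bis = estimate_bispectrum(Segment(samples=x, fs=FS, subject_id="demo",
                                          channel="c1", offset=0))
        acc = bis.values if acc is None else acc + bis.values
        valid = bis.valid_mask()
    mean = np.abs(acc / N_SEGMENTS)
    return mean[36, 41], float(np.median(mean[valid]))


peak_c, bg_c = mean_bispectrum_peak(True)
peak_u, bg_u = mean_bispectrum_peak(False)
print(f"coupled   |B({F1:.1f}, {F2:.1f})| = {peak_c:10.1f}   "
      f"median background = {bg_c:7.2f}   ratio = {peak_c / bg_c:9.1f}")
print(f"uncoupled |B({F1:.1f}, {F2:.1f})| = {peak_u:10.1f}   "
      f"median background = {bg_u:7.2f}   ratio = {peak_u / bg_u:9.1f}")
print(f"\ncoupled / uncoupled peak magnitude: {peak_c / peak_u:.1f}x")
print("Both signal families have identical power spectra; only the phase")
print("relation distinguishes them, and only the bispectrum sees it.")
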