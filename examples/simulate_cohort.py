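"""Generate and persist a labelled two-class synthetic EEG cohort.

The two groups (37 controls, 40 cases) share amplitudes and spectra; they
differ only in the probability that oscillatory triplets are quadratically
phase coupled.  The cohort is written as one NPZ bundle plus a CSV label
manifest, the on-disk format the rest of the pipeline reads.
"""

import tempfile
from pathlib import Path

from bispeeg import SynthConfig, generate_cohort, read_cohort, write_cohort

cfg = SynthConfig(
    n_normal=37, n_asd=40, n_channels=4, duration_s=12.0,
    coupling_strength_normal=0.1, coupling_strength_asd=0.9,
    snr_db=10.0, seed=0,
)
records = generate_cohort(cfg)
out = Path(tempfile.mkdtemp(prefix="bispeeg_cohort_"))
npz, manifest = write_cohort(records, out)

back = read_cohort(npz, manifest)
n_asd = sum(r.class_label == "asd" for r in back)
print(f"wrote {npz}")
print(f"subjects: {len(back)} ({n_asd} asd, {len(back) - n_asd} normal)")
r = back[0]
print(f"first record: {r.subject_id}, {r.n_channels} channels x "
      f"{r.n_samples} samples @ {r.fs:.0f} Hz")
print()
print("Coupling probabilities 0.1 vs 0.9 are invisible to channel variance or")
print("power spectra; only phase-sensitive statistics separate the groups.")
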