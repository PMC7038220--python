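"""Run the whole chain on a desk-scale synthetic cohort and print the report.

preprocess (0.3-40 Hz, 5519-sample segments) -> bispectrum -> texture
features -> per-subject aggregation -> LSDA + Welch t selection (fitted
inside each training fold) -> PNN, evaluated by stratified 10-fold CV.
Takes a few minutes; shrink n_channels / duration_s for a faster demo.
"""

from bispeeg import SynthConfig
from bispeeg.pipeline import PipelineConfig, run_pipeline

synth = SynthConfig(
    n_normal=37, n_asd=40, n_channels=8, duration_s=24.0,
    coupling_strength_normal=0.1, coupling_strength_asd=0.9,
    snr_db=10.0, seed=1,
)
report = run_pipeline(PipelineConfig(synth=synth, seed=17))

print("stages:", report["stages"])
print("selected components:", report["selected_features"])
cv = report["cv"]
print(f"confusion (positive = {cv['positive_label']}): "
      f"TP={cv['TP']} FN={cv['FN']} TN={cv['TN']} FP={cv['FP']}")
for metric in ("accuracy", "sensitivity", "specificity", "ppv"):
    print(f"  {metric:12s} {cv[metric]:6.2f} %")
print()
print("Accuracy well above the 51.9% majority rate shows the bispectral")
print("texture chain recovers the phase-coupling contrast between classes.")
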