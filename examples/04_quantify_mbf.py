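"""Myocardial blood flow from the full pipeline.

Runs simulate -> pass-1 reconstruction -> Dixon -> rigid motion correction
-> pass-2 reconstruction -> non-rigid refinement -> AIF extraction with T2*
correction -> pixel-wise two-compartment-exchange fitting, and prints the
AHA segment table next to the phantom's programmed flow.
"""

from fosters import run_pipeline
from fosters.config import PipelineConfig

result = run_pipeline(PipelineConfig(seed=7))

print("per-segment MBF (mL/min/g), estimated vs programmed:")
print(result.segments[["segment", "mbf_mean", "mbf_truth", "n_pixels"]]
      .round(2).to_string(index=False))
m = result.report.metrics
print(f"\nmotion residual: {m['motion_residual_px']['value']:.2f} px RMS")
print(f"defect sector mean: {m['defect_mean']['value']:.2f} "
      f"vs remote {m['remote_mean']['value']:.2f} mL/min/g "
      "(the hypoperfused sector must read lower)")
print(f"estimated AIF peak: {max(result.aif.concentration):.2f} mM "
      "(programmed 5.0 mM)")
print(f"config hash (reproducibility): {result.report.config_hash}")
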