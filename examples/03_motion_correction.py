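"""Estimate breathing motion from fat images and correct the raw k-space.

The pass-1 reconstruction only needs to be good enough for registration
(10 iterations); translations are estimated on the contrast-stable fat
images with normalized gradient fields and applied to the raw samples as
linear k-space phase shifts — an exact, interpolation-free correction.
"""

import numpy as np

from fosters import dixon, motion, phantom, recon, sampling
from fosters.config import PhantomConfig, ReconConfig

cfg = PhantomConfig(seed=7)
pattern = sampling.generate_kt_mask(*cfg.grid_size, cfg.n_frames, R=8,
                                    center_fraction=0.04, seed=7)
truth, kt = phantom.simulate_acquisition(cfg, pattern)

pass1 = recon.solve_lrs(kt, ReconConfig(n_iter=10))
pair = dixon.separate_water_fat(pass1, kt.acq)
trace = motion.estimate_motion(pair.fat, pair.water)
kt_corrected = motion.correct_kt(kt, trace)

true_rel = truth.motion_trace.re_referenced(trace.reference_frame)
rms = np.sqrt(np.mean((trace.dy - true_rel.dy) ** 2
                      + (trace.dx - true_rel.dx) ** 2))
print(f"reference frame: {trace.reference_frame} "
      "(superior-inferior position closest to the mean)")
print(f"programmed amplitude: {np.abs(true_rel.dy).max():.1f} px; "
      f"residual after estimation: {rms:.2f} px RMS")
print("k-space energy conserved by the phase-shift correction: "
      f"{np.allclose(np.abs(kt_corrected.samples).sum(), np.abs(kt.samples).sum())}")
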